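# Methods

This note documents the models, parameters and design choices behind
`pseudoct`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic cohorts do and do not emulate.

## Image model and coordinate conventions

All volumes are axis-aligned grids with voxel-centred, 0-based indices and
`world = origin + index·spacing` (mm). Oblique NIfTI affines are rejected
rather than silently reinterpreted. CT values are clamped at −1024 HU
(scanner floor convention). Resampling that reaches outside the source
grid does not silently fill: it returns an explicit FOV-validity mask
alongside the fill value (−1000 HU for CT, 0 otherwise). That mask is the
load-bearing object of the whole package — it is what the similarity and
fusion stages consume to keep no-data regions from contaminating the
synthesis.

## ROI-LNCC

The local normalised correlation coefficient between two images under a
Gaussian window of scale σ is computed with separable convolutions. The
irregular-ROI extension replaces every smoothed sum by a masked ratio:

    mean(x)  = G_σ∗(m·f)(x) / G_σ∗m(x)
    var(x)   = G_σ∗(m·f²)(x) / G_σ∗m(x) − mean(x)²
    cov(x)   = G_σ∗(m·f·g)(x) / G_σ∗m(x) − mean_f(x)·mean_g(x)

with `m` the indicator of the joint ROI (target FOV ∩ propagated atlas
FOV). Convolutions use zero padding, so the grid border behaves exactly
like a FOV border. Interpretation choice: both images' moments are taken
under the *joint* ROI (rather than each under its own), which makes the
statistic symmetric and keeps the correlation a true masked Pearson
coefficient; this is the declared reading of the construction.

Numerical guards:

* **Support threshold** (default 0.5 on `G_σ∗m`): below it the local
  moments are ratios of vanishing quantities and the voxel is marked
  invalid. This is precisely the FOV-border failure mode the ROI variant
  exists to fix.
* **Variance floor** (default 1e−6 of the global in-ROI variance of each
  image): voxels where either image is locally constant carry no
  correlation information.
* Invalid voxels take the neutral value 0 — "no evidence", not "strong
  evidence" — and are excluded from fusion weight mass.

`σ` defaults to 3 mm. It is a tunable locality/robustness trade-off, not
a value inherited from elsewhere: smaller σ tracks anatomy more tightly
but is noisier; larger σ approaches a global correlation.

The multivariate similarity over MRI contrasts is the unweighted sum of
per-channel ROI-LNCC values, with validity the intersection of channel
validities. A constant (information-free) channel is invalid everywhere
by the variance floor, so the multivariate mode degrades gracefully to
the single-channel behaviour.

A "legacy" mode computes LNCC with full-grid moments, ignoring validity,
in both similarity and fusion. It exists solely as the comparison
baseline: it reproduces the failure where fill values in no-data regions
are averaged into the pseudo-CT.

## Ranking and fusion

At each voxel the valid atlases are ranked by similarity (1 = best, ties
broken by database order for determinism) and converted to weights
`w = exp(−(rank−1)/β)` over the top K atlases, normalised to sum to one.
Defaults: β = 0.5, K = all atlases. β controls how sharply the best
atlases dominate; K = 1 reduces to best-atlas selection. Both are
declared tunables exposed in the config and the provenance log.

Voxels where no atlas is valid fall back to −1000 HU outside the head
mask and to the nearest valid fused value inside it, so the output CT is
defined everywhere on the grid (an uncorrected gap would otherwise
propagate as a severe μ underestimation).

## Registration contract

The pipeline needs, per atlas: a mapping from the target grid into the
atlas, plus FOV-mask propagation. Production registration engines can be
swapped in by supplying precomputed transforms (4×4 world-mm affine +
dense mm displacement field on the target grid; the displacement maps
target points to moving-image world points). The built-in baseline is
deliberately simple but deterministic:

* a multiresolution translation search (Powell) over NCC or NMI, summed
  over channels for multi-contrast pairs;
* a multiresolution Gaussian-regularised dense force-field refinement:
  demons-style first-order updates `δu = (f−w)∇w/(|∇w|²+(f−w)²/s²)`,
  fluid-smoothed per update (σ = 6 mm) with light elastic smoothing of
  the accumulated field (σ = 1 mm), driven by all channels, evaluated
  only over valid voxels, with best-metric tracking and a divergence
  bail-out.

A dense regularised field was chosen over a coarse B-spline grid for the
non-rigid stage: with gradient-flow optimisation the dense field is both
simpler and better conditioned at phantom scale, and the transform
container is agnostic to how the field was produced. NMI uses 32 bins per
channel with a plain joint histogram. The baseline makes no claim of
equivalence to any production engine; its parameters (levels, iteration
budget, smoothing scales) are declared configuration.

## Phantom cohorts

The generator emulates the statistical structure the method needs, not MR
physics. A base anatomy of nested ellipsoids provides: soft-tissue head,
closed bone shell, an air sinus pocket directly against bone (the classic
bone/air ambiguity), a CSF space, and two reference regions — a central
pseudo-pons and a pseudo-cerebellar region deliberately placed within 10%
of the inferior CT FOV border, where synthesis is hardest and where SUVR
normalisation makes errors global. Class means: CT air −1000, soft tissue
40, bone 1000, CSF 15 HU; T1 and T2 are distinct class-intensity maps
(CSF dark on T1, bright on T2) with Gaussian noise (SD 4) and smooth
multiplicative bias (5%, 40 mm scale); PET activity is nonnegative and
zero outside the head.

Inter-subject variability: each subject warps the base labels with a
smooth random B-spline displacement field (control spacing 40 mm,
amplitude scaled so the maximum displacement is 4 mm, boundary control
points zeroed), checked for folding via the Jacobian determinant and
regenerated at half amplitude on failure (3 attempts). Intensities are
re-rendered per subject with fresh noise, so atlases differ in both
anatomy and appearance.

FOV mismatch: the MRI covers the full grid; the CT keeps only the
superior ⌊fraction·n_z⌋ slices (default 0.75), with a per-subject jitter
of ±0.04 on the fraction emulating positioning differences. The jitter is
what makes the FOV problem three-dimensional across a cohort: near the
border some atlases are valid and some are not, exactly the regime that
separates ROI-aware from legacy similarity.

What the phantoms do **not** emulate: MR sequence physics and artefacts,
partial-volume effects beyond interpolation, lesions or abnormal
anatomy, continuous HU heterogeneity within a tissue class, and
inter-subject topology changes. Passing tests on phantoms therefore show
the pipeline's mechanics and orderings are right, not that clinical error
magnitudes transfer.

## Attenuation conversion

HU → μ at 511 keV is a piecewise-linear table, data not code: default
breakpoints (−1000, 0), (0, 0.096), (3000, 0.249) cm⁻¹, i.e. an
air–water segment and a shallower water–bone segment (slope 5.1×10⁻⁵
cm⁻¹/HU, conventional for ~120 kVp acquisitions). The table must be
non-decreasing and continuous; values above the last breakpoint
extrapolate with the final slope, output clamps at 0. The μ-map is
smoothed with an isotropic Gaussian of σ = 2 voxels (PET PSF surrogate)
*before* resampling to the PET grid.

Note on the PSF-smoothing invariant: total attenuation mass is conserved
to <0.5% on phantoms, and deep-interior means are stable to <1%, but the
head-mask mean is *not* stable at coarse phantom resolution (σ = 2 voxels
is 5–6 mm there, vs ~2.3 mm clinically), because boundary leakage at the
scalp scales with σ relative to head size.

## PET harness

A 2-D parallel-beam geometry applied slice by slice stands in for the
scanner. The system matrix holds length-weighted line integrals (sampled
at half-pixel steps, 3 sub-rays per radial bin to suppress bin/pixel
aliasing) and is built sparse, so forward projection and backprojection
are an exactly adjoint pair by construction. Attenuation-correction
factors are `exp(∫μ dl)` (lengths in cm), ≥ 1 everywhere.

Simulation follows the measurement chain: attenuated trues
(`P(activity)/acf`), plus a surrogate scatter term — radially smoothed
trues scaled so scatter/(trues+scatter) equals the configured scatter
fraction (default 0.2). A physically modelled scatter sinogram can be
supplied instead. Poisson noise is off by default (the comparison design
is noiseless) and requires an explicit seed when enabled.

OSEM uses angle-interleaved subsets and the attenuated system model with
scatter in the forward projection of the update denominator;
nonnegativity and zero-sensitivity support are preserved. Defaults are 3
iterations; 21 subsets for scanner-sized angle counts, 8 subsets on the
64-angle phantom geometry (divisibility). Neither a PSF model nor a
randoms term exists in the configuration, matching the harness's
noiseless, randoms-free comparison design. Because the harness compares
reconstructions that differ only in the μ-map, its 2-D geometry preserves
the *relative* ordering of μ-maps even though absolute scanner effects
are out of scope.

## Cohort evaluation protocol

Leave-one-out over a phantom cohort: each subject in turn is the target,
the rest form the atlas database. Registrations are computed once per
(target, atlas, driver-channel set) and shared across method variants
using the same driver. Per variant: synthesise the pseudo-CT, mask it to
the target's CT FOV (the reference μ-map exists only there, so the
comparison is made on common support), convert to μ, reconstruct the
simulated non-corrected sinogram with reference and candidate μ-maps, and
report (a) CT MAE/ME on the head mask within the CT FOV, (b) PET rMAE/rME
in the reference region before normalisation, and (c) PET rMAE/rME in the
brain after SUVR normalisation to the border-adjacent reference region.
Summary statistics (mean/SD/min/max) recompute exactly from the
per-subject rows; the paired one-tailed Wilcoxon signed-rank test is
available through the standard SciPy routine for method comparisons.

Problem sizes: tests and the acceptance script run 6-subject cohorts on
48³ grids at 3 mm spacing with 3 independent repeats, 64 projection
angles and 3×8 OSEM; these sizes were chosen as the smallest at which all
anatomical features (bone shell, sinus, reference regions, FOV border)
remain resolved.

## Known limitations

* The baseline registration is adequate for smooth phantom warps only;
  real cohorts need a production engine via the precomputed-transform
  path.
* The scatter surrogate reproduces the magnitude and smoothness of
  scatter, not its physics.
* The bilinear HU→μ table is a single-kVp convention; energy-dependent
  or vendor-calibrated tables should be supplied as data when available.
* Phantom error magnitudes (e.g. head MAE ≈ 55–75 HU) are not comparable
  to clinical values; only orderings and mechanisms transfer.
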