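"""Synthetic head-phantom cohorts for developing and testing the synthesis
pipeline.

Each phantom is a labelled head built from nested ellipsoids: a soft-tissue
head with a closed bone shell, an air-filled sinus pocket directly adjacent
to bone (the hard bone/air discrimination case), a central CSF space and
two labelled reference regions — a central pseudo-pons and a pseudo-
cerebellar region placed close to the inferior border of the CT field of
view, where synthesis is hardest.  From the labels the generator renders:

* a CT in Hounsfield units (air -1000, soft tissue 40, bone 1000, ...),
* two MRI contrasts with distinct class-intensity mappings (CSF dark on the
  T1-like image, bright on the T2-like image) so the channels carry
  complementary information,
* a PET activity map, nonnegative and zero outside the head,

each with optional Gaussian noise and a smooth multiplicative bias field.
Inter-subject anatomy is emulated by warping the base labels with smooth
random B-spline displacement fields (checked for folding via the Jacobian
determinant).  The CT field of view is cropped inferiorly relative to the
MRI field of view, reproducing the head-only CT vs head-and-neck MRI
mismatch that the ROI-aware similarity is designed to handle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_model import (
    CT_AIR_HU,
    AtlasDatabase,
    AtlasEntry,
    MaskKind,
    Modality,
    ROIMask,
    Volume,
)

# label ids
AIR, SOFT, BONE, SINUS, CSF, REF_A, REF_B = range(7)

CLASS_NAMES = {
    AIR: "air",
    SOFT: "soft_tissue",
    BONE: "bone",
    SINUS: "sinus_air",
    CSF: "csf",
    REF_A: "ref_region_A",
    REF_B: "ref_region_B",
}

# per-class mean intensities; CT in HU, MRI in arbitrary units, PET activity
DEFAULT_CT_MEANS = {AIR: -1000.0, SOFT: 40.0, BONE: 1000.0, SINUS: -1000.0,
                    CSF: 15.0, REF_A: 40.0, REF_B: 40.0}
DEFAULT_T1_MEANS = {AIR: 5.0, SOFT: 100.0, BONE: 30.0, SINUS: 5.0,
                    CSF: 35.0, REF_A: 95.0, REF_B: 90.0}
DEFAULT_T2_MEANS = {AIR: 5.0, SOFT: 80.0, BONE: 20.0, SINUS: 5.0,
                    CSF: 180.0, REF_A: 85.0, REF_B: 95.0}
DEFAULT_ACTIVITY_MEANS = {AIR: 0.0, SOFT: 100.0, BONE: 5.0, SINUS: 0.0,
                          CSF: 10.0, REF_A: 100.0, REF_B: 100.0}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    ct_means: dict = field(default_factory=lambda: dict(DEFAULT_CT_MEANS))
    t1_means: dict = field(default_factory=lambda: dict(DEFAULT_T1_MEANS))
    t2_means: dict = field(default_factory=lambda: dict(DEFAULT_T2_MEANS))
    activity_means: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_MEANS))
    noise_sd_ct: float = 20.0
    noise_sd_mri: float = 4.0
    bias_amplitude: float = 0.05  # multiplicative, MRI only
    bias_sigma_mm: float = 40.0
    deformation_amplitude_mm: float = 4.0
    deformation_control_spacing_mm: float = 40.0
    ct_z_keep_fraction: float = 0.75
    #: per-subject uniform jitter of the CT crop fraction, emulating
    #: subject-to-subject scanner positioning differences
    ct_z_keep_jitter: float = 0.04

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise ValueError("phantom grid must be at least 8 voxels on every axis")
        if not 0.0 < self.ct_z_keep_fraction <= 1.0:
            raise ValueError("ct_z_keep_fraction must be in (0, 1]")
        for name in ("noise_sd_ct", "noise_sd_mri", "bias_amplitude",
                     "deformation_amplitude_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PhantomSubject:
    labels: Volume  # Modality.LABEL
    ct: Volume
    t1: Volume
    t2: Volume
    activity: Volume
    fov_mask_mri: ROIMask
    fov_mask_ct: ROIMask

    def head_mask(self) -> ROIMask:
        """Ground-truth head: everything inside the outer skin surface."""
        lab = self.labels.values
        head = lab != AIR
        head = ndimage.binary_fill_holes(head)  # sinus pockets belong to the head
        return ROIMask(head, self.labels.spacing, self.labels.origin, MaskKind.ANATOMY)

    def region_mask(self, label_id: int) -> ROIMask:
        return ROIMask(self.labels.values == label_id, self.labels.spacing,
                       self.labels.origin, MaskKind.ANATOMY)

    def brain_mask(self) -> ROIMask:
        """Soft tissue + CSF + reference regions (inside the skull)."""
        lab = self.labels.values
        m = np.isin(lab, (SOFT, CSF, REF_A, REF_B))
        return ROIMask(m, self.labels.spacing, self.labels.origin, MaskKind.ANATOMY)

    def atlas_entry(self, channels: str = "t1t2") -> AtlasEntry:
        chans = {"t1": [self.t1], "t2": [self.t2], "t1t2": [self.t1, self.t2]}[channels]
        return AtlasEntry(mri_channels=chans, ct=self.ct, fov_mask=self.fov_mask_ct)


# ---------------------------------------------------------------------------
# geometry


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return ((x - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2 + (
        (z - center[2]) / radii[2]
    ) ** 2 <= 1.0


def _sphere(coords, center, radius) -> np.ndarray:
    x, y, z = coords
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def base_labels(cfg: PhantomConfig) -> Volume:
    """Deterministic base anatomy label volume (world coordinates in mm)."""
    shape = cfg.shape
    sp = cfg.spacing
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    extent = [n * s for n, s in zip(shape, sp)]
    cx, cy = extent[0] / 2, extent[1] / 2
    cz = extent[2] * 0.525
    center = (cx, cy, cz)
    # scale radii with the grid extent so small grids still hold a full head
    f = min(extent) / 160.0
    outer = (55 * f, 65 * f, 70 * f)
    bone_outer = tuple(r - 6 * f for r in outer)
    bone_inner = tuple(r - 11 * f for r in outer)

    lab = np.zeros(shape, dtype=np.int16)
    head = _ellipsoid(grids, center, outer)
    lab[head] = SOFT
    shell = _ellipsoid(grids, center, bone_outer) & ~_ellipsoid(grids, center, bone_inner)
    lab[shell] = BONE
    inner = _ellipsoid(grids, center, bone_inner)
    # CSF space at the centre
    lab[inner & _ellipsoid(grids, (cx, cy - 5 * f, cz + 8 * f), (10 * f, 18 * f, 10 * f))] = CSF
    # sinus pocket straddling the inner bone surface (air adjacent to bone)
    sinus = _sphere(grids, (cx, cy - bone_inner[1] + 4 * f, cz - 6 * f), 8 * f)
    lab[inner & sinus] = SINUS
    # pseudo-pons: central, mid-inferior
    lab[inner & _sphere(grids, (cx, cy, cz - 28 * f), 9 * f)] = REF_A
    # pseudo-cerebellum: posterior, within 10% of the inferior CT FOV border
    nz = shape[2]
    z_lo_idx = nz - int(np.floor(cfg.ct_z_keep_fraction * nz))
    z_lo = z_lo_idx * sp[2]
    z_ref_b = z_lo + 0.05 * (extent[2] - z_lo)
    ref_b = _sphere(grids, (cx, cy + 25 * f, z_ref_b + 9 * f), 9.5 * f)
    lab[inner & ref_b] = REF_B
    return Volume(lab.astype(np.float64), sp, (0.0, 0.0, 0.0), Modality.LABEL)


# ---------------------------------------------------------------------------
# rendering


def _class_image(labels: np.ndarray, means: dict) -> np.ndarray:
    lut = np.zeros(max(means) + 1)
    for k, v in means.items():
        lut[k] = v
    return lut[labels.astype(np.intp)]


def _bias_field(shape, spacing, amplitude, sigma_mm, rng) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    sig = [sigma_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sig, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return 1.0 + amplitude * smooth


def render_subject(cfg: PhantomConfig, labels: Volume, rng: np.random.Generator) -> PhantomSubject:
    """Render CT/T1/T2/activity volumes from a label map with noise and bias."""
    lab = labels.values.astype(np.int16)
    sp, org = labels.spacing, labels.origin
    shape = lab.shape

    ct = _class_image(lab, cfg.ct_means)
    if cfg.noise_sd_ct > 0:
        ct = ct + cfg.noise_sd_ct * rng.standard_normal(shape)
    t1 = _class_image(lab, cfg.t1_means)
    t2 = _class_image(lab, cfg.t2_means)
    b1 = _bias_field(shape, sp, cfg.bias_amplitude, cfg.bias_sigma_mm, rng)
    b2 = _bias_field(shape, sp, cfg.bias_amplitude, cfg.bias_sigma_mm, rng)
    t1 = t1 * b1
    t2 = t2 * b2
    if cfg.noise_sd_mri > 0:
        t1 = t1 + cfg.noise_sd_mri * rng.standard_normal(shape)
        t2 = t2 + cfg.noise_sd_mri * rng.standard_normal(shape)

    activity = _class_image(lab, cfg.activity_means)
    head = ndimage.binary_fill_holes(lab != AIR)
    activity[~head] = 0.0
    np.clip(activity, 0.0, None, out=activity)

    keep = cfg.ct_z_keep_fraction
    if cfg.ct_z_keep_jitter > 0:
        keep = float(np.clip(keep + rng.uniform(-cfg.ct_z_keep_jitter,
                                                cfg.ct_z_keep_jitter), 0.05, 1.0))
    ct_vol = Volume(ct, sp, org, Modality.CT_HU)
    ct_crop, fov_ct = crop_fov(ct_vol, keep)
    fov_mri = ROIMask(np.ones(shape, dtype=bool), sp, org, MaskKind.FOV_VALIDITY)
    return PhantomSubject(
        labels=labels,
        ct=ct_crop,
        t1=Volume(t1, sp, org, Modality.MRI),
        t2=Volume(t2, sp, org, Modality.MRI),
        activity=Volume(activity, sp, org, Modality.PET),
        fov_mask_mri=fov_mri,
        fov_mask_ct=fov_ct,
    )


def make_head_phantom(cfg: PhantomConfig, seed: int) -> PhantomSubject:
    """Deterministic base phantom for a given (cfg, seed)."""
    rng = np.random.default_rng(seed)
    return render_subject(cfg, base_labels(cfg), rng)


# ---------------------------------------------------------------------------
# FOV cropping


def crop_fov(vol: Volume, z_keep_fraction: float,
             fill_value: float | None = None) -> tuple[Volume, ROIMask]:
    """Crop the inferior z-range of a volume, emulating a head-only FOV.

    Keeps the superior ``floor(fraction * n_z)`` slices; inferior slices are
    set to the fill value and marked invalid in the returned mask.
    """
    if not 0.0 < z_keep_fraction <= 1.0:
        raise ValueError("z_keep_fraction must be in (0, 1]")
    if fill_value is None:
        fill_value = CT_AIR_HU if vol.modality is Modality.CT_HU else 0.0
    nz = vol.values.shape[2]
    n_keep = int(np.floor(z_keep_fraction * nz))
    z_lo = nz - n_keep
    out = vol.values.copy()
    out[:, :, :z_lo] = fill_value
    mask = np.ones(vol.values.shape, dtype=bool)
    mask[:, :, :z_lo] = False
    return replace(vol, values=out), ROIMask(mask, vol.spacing, vol.origin,
                                             MaskKind.FOV_VALIDITY)


# ---------------------------------------------------------------------------
# inter-subject deformation


def bspline_displacement(shape, spacing, amplitude_mm, control_spacing_mm,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement field (mm), shape (3, *shape).

    Random displacements on a coarse control grid are upsampled with a cubic
    spline; the field is scaled so its largest magnitude equals
    ``amplitude_mm``.  Boundary control points are zeroed so the warp decays
    near the volume edges.
    """
    if amplitude_mm == 0:
        return np.zeros((3,) + tuple(shape))
    n_ctrl = [max(4, int(np.ceil(n * s / control_spacing_mm)) + 3)
              for n, s in zip(shape, spacing)]
    disp = []
    coeff = rng.standard_normal((3, *n_ctrl))
    coeff[:, 0, :, :] = coeff[:, -1, :, :] = 0
    coeff[:, :, 0, :] = coeff[:, :, -1, :] = 0
    coeff[:, :, :, 0] = coeff[:, :, :, -1] = 0
    for ax in range(3):
        up = ndimage.zoom(coeff[ax], [n / c for n, c in zip(shape, n_ctrl)],
                          order=3, mode="nearest", grid_mode=True)
        disp.append(up)
    disp = np.stack(disp)
    mag = np.sqrt((disp**2).sum(axis=0)).max()
    if mag > 0:
        disp *= amplitude_mm / mag
    return disp


def jacobian_min_det(disp: np.ndarray, spacing) -> float:
    """Minimum Jacobian determinant of the mapping x -> x + u(x)."""
    grads = np.empty((3, 3) + disp.shape[1:])
    for i in range(3):
        for j in range(3):
            grads[i, j] = np.gradient(disp[i], spacing[j], axis=j)
        grads[i, i] += 1.0
    det = (
        grads[0, 0] * (grads[1, 1] * grads[2, 2] - grads[1, 2] * grads[2, 1])
        - grads[0, 1] * (grads[1, 0] * grads[2, 2] - grads[1, 2] * grads[2, 0])
        + grads[0, 2] * (grads[1, 0] * grads[2, 1] - grads[1, 1] * grads[2, 0])
    )
    return float(det.min())


def warp_labels(labels: Volume, disp: np.ndarray) -> Volume:
    """Pull-back warp of a label volume: out(x) = labels(x + u(x)), nearest."""
    if not disp.any():
        return replace(labels, values=labels.values.copy())
    shape = labels.values.shape
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = [idx[ax] + disp[ax] / labels.spacing[ax] for ax in range(3)]
    out = ndimage.map_coordinates(labels.values, np.stack(coords), order=0,
                                  mode="constant", cval=AIR)
    return replace(labels, values=out)


def _subject_displacement(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    amplitude = cfg.deformation_amplitude_mm
    for attempt in range(3):
        disp = bspline_displacement(cfg.shape, cfg.spacing, amplitude,
                                    cfg.deformation_control_spacing_mm, rng)
        if amplitude == 0 or jacobian_min_det(disp, cfg.spacing) > 0:
            return disp
        amplitude /= 2.0
        warnings.warn(
            f"deformation field folded; retrying with amplitude {amplitude} mm"
        )
    raise RuntimeError("could not generate a fold-free deformation in 3 attempts")


def make_atlas_population(
    cfg: PhantomConfig, n: int, seed: int, channels: str = "t1t2"
) -> tuple[AtlasDatabase, PhantomSubject]:
    """Generate ``n`` atlas subjects plus one held-out target.

    All n+1 subjects are independent smooth warps of one base anatomy, each
    rendered with its own noise and bias realisation.
    """
    if n < 2:
        raise ValueError("need at least 2 atlas subjects")
    subjects = make_cohort(cfg, n + 1, seed)
    target = subjects[-1]
    entries = [s.atlas_entry(channels) for s in subjects[:-1]]
    return AtlasDatabase(entries=entries), target


def make_cohort(cfg: PhantomConfig, n_subjects: int, seed: int) -> list[PhantomSubject]:
    """Generate ``n_subjects`` independently warped phantom subjects."""
    base = base_labels(cfg)
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        disp = _subject_displacement(cfg, rng)
        labels = warp_labels(base, disp)
        subjects.append(render_subject(cfg, labels, rng))
    return subjects
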