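"""Projection/reconstruction harness for evaluating attenuation maps.

A 2-D parallel-beam geometry applied slice-by-slice stands in for the
scanner: per slice, a sparse system matrix of length-weighted line
integrals (built once per geometry and cached) provides an exactly
adjoint projector/backprojector pair.  Attenuation-correction factors are
Beer-Lambert line integrals of the mu-map, ``acf = exp(int mu dl)``.
Simulation mirrors the measurement chain: project the activity, divide by
the ACFs of the reference mu-map, add a surrogate scatter term (radially
smoothed trues scaled to a configured scatter fraction), optionally apply
Poisson noise.  Reconstruction is OSEM with angle-interleaved subsets and
the attenuated system model; neither a point-spread function nor a
randoms term is modelled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .image_model import Modality, Volume


class SinogramKind(enum.Enum):
    EMISSION = "emission"
    ACF = "acf"
    SCATTER = "scatter"


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam slice geometry: uniform angles on [0, pi)."""

    n_angles: int = 64
    n_radial: int = 96
    radial_spacing_mm: float = 2.5
    image_shape: tuple[int, int] = (64, 64)  # in-plane (x, y)
    image_spacing_mm: tuple[float, float] = (2.5, 2.5)

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial < 1:
            raise ValueError("geometry requires at least one angle and one bin")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_offsets_mm(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_spacing_mm


@dataclass
class Sinogram:
    """(slice, angle, radial) projection data with its geometry."""

    values: np.ndarray
    kind: SinogramKind
    geometry: ScannerGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("sinogram must be (slice, angle, radial)")
        if self.values.shape[1:] != (self.geometry.n_angles, self.geometry.n_radial):
            raise ValueError("sinogram shape does not match geometry")
        if self.kind in (SinogramKind.EMISSION, SinogramKind.SCATTER):
            if np.any(self.values < 0):
                raise ValueError("emission/scatter sinograms must be nonnegative")


@dataclass
class ReconConfig:
    n_iterations: int = 3
    n_subsets: int = 21
    scatter_fraction: float = 0.0
    scatter_sigma_bins: float = 6.0
    poisson_noise: bool = False
    counts_scale: float = 1.0  # total-count scaling before Poisson sampling
    nonneg_floor: float = 0.0


_MATRIX_CACHE: dict = {}


def system_matrix(geom: ScannerGeometry) -> sparse.csr_matrix:
    """Sparse (n_angles*n_radial, nx*ny) matrix of line integrals (mm).

    Rays are sampled at half-pixel steps and deposit bilinearly weighted
    path length into the pixels they traverse; forward projection is ``A @ x``
    and the exactly adjoint backprojection is ``A.T @ y``.
    """
    key = geom
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    nx, ny = geom.image_shape
    sx, sy = geom.image_spacing_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    diag = np.hypot(nx * sx, ny * sy)
    step = 0.5 * min(sx, sy)
    n_steps = int(np.ceil(diag / step)) + 1
    t = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step
    # each radial bin is a strip: average 3 sub-rays across the bin width to
    # suppress aliasing between the bin grid and the pixel grid
    n_sub = 3
    sub = (np.arange(n_sub) - (n_sub - 1) / 2.0) / n_sub * geom.radial_spacing_mm

    rows, cols, vals = [], [], []
    offsets = geom.radial_offsets_mm
    for ia, theta in enumerate(geom.angles):
        ct, st = np.cos(theta), np.sin(theta)
        for ds in sub:
            # ray: p(t) = (s+ds)*(ct, st) + t*(-st, ct), s = radial offset
            s_grid, t_grid = np.meshgrid(offsets + ds, t, indexing="ij")
            px = s_grid * ct - t_grid * st
            py = s_grid * st + t_grid * ct
            fx = px / sx + cx
            fy = py / sy + cy
            ix = np.floor(fx).astype(np.int64)
            iy = np.floor(fy).astype(np.int64)
            wx = fx - ix
            wy = fy - iy
            ray_idx = np.broadcast_to(np.arange(geom.n_radial)[:, None], fx.shape)
            for dx, dy in ((0, 0), (0, 1), (1, 0), (1, 1)):
                jx = ix + dx
                jy = iy + dy
                w = ((1 - wx) if dx == 0 else wx) * ((1 - wy) if dy == 0 else wy)
                ok = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny) & (w > 0)
                rows.append(ia * geom.n_radial + ray_idx[ok])
                cols.append(jx[ok] * ny + jy[ok])
                vals.append(w[ok] * step / n_sub)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * geom.n_radial, nx * ny),
    ).tocsr()
    _MATRIX_CACHE[key] = A
    return A


def _check_grid(img: Volume, geom: ScannerGeometry) -> None:
    if img.values.shape[:2] != geom.image_shape or not np.allclose(
        img.spacing[:2], geom.image_spacing_mm
    ):
        raise ValueError("image grid does not match scanner geometry")


def _project_slices(vals: np.ndarray, geom: ScannerGeometry) -> np.ndarray:
    A = system_matrix(geom)
    nx, ny = geom.image_shape
    nz = vals.shape[2]
    flat = vals.reshape(nx * ny, nz)
    sino = (A @ flat).reshape(geom.n_angles, geom.n_radial, nz)
    return np.moveaxis(sino, 2, 0)


def forward_project(img: Volume, geom: ScannerGeometry) -> Sinogram:
    """Length-weighted line integrals of a volume, slice by slice (mm units)."""
    _check_grid(img, geom)
    return Sinogram(_project_slices(img.values, geom), SinogramKind.EMISSION, geom)


def back_project(sino: Sinogram, geom: ScannerGeometry) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`; returns (nx, ny, nz) array."""
    A = system_matrix(geom)
    nx, ny = geom.image_shape
    vals = np.moveaxis(sino.values, 0, 2).reshape(geom.n_angles * geom.n_radial, -1)
    return (A.T @ vals).reshape(nx, ny, sino.values.shape[0])


def attenuation_factors(mu: Volume, geom: ScannerGeometry) -> Sinogram:
    """Beer-Lambert attenuation-correction factors: exp(+int mu dl).

    ``mu`` is in cm^-1 on a grid with mm spacing; path lengths are converted
    to cm.  Emission data divided by the ACF is attenuated; multiplied by
    the ACF it is corrected.
    """
    if mu.modality is not Modality.MU:
        raise ValueError("attenuation_factors requires a MU volume")
    if np.any(mu.values < 0):
        raise ValueError("mu must be nonnegative")
    _check_grid(mu, geom)
    line_int = _project_slices(mu.values, geom) / 10.0  # mm -> cm
    return Sinogram(np.exp(line_int), SinogramKind.ACF, geom)


def scatter_surrogate(trues: Sinogram, cfg: ReconConfig) -> Sinogram:
    """Surrogate scatter: radially smoothed trues scaled to the configured
    scatter fraction (scatter / total = scatter_fraction).

    Stands in for a physical single-scatter simulation; any externally
    computed scatter sinogram can be supplied to the reconstruction instead.
    """
    sf = cfg.scatter_fraction
    if not 0.0 <= sf < 1.0:
        raise ValueError("scatter_fraction must be in [0, 1)")
    if sf == 0.0:
        return Sinogram(np.zeros_like(trues.values), SinogramKind.SCATTER, trues.geometry)
    smooth = ndimage.gaussian_filter1d(trues.values, cfg.scatter_sigma_bins,
                                       axis=2, mode="nearest")
    total_trues = trues.values.sum()
    target = sf / (1.0 - sf) * total_trues
    ssum = smooth.sum()
    scale = target / ssum if ssum > 0 else 0.0
    return Sinogram(smooth * scale, SinogramKind.SCATTER, trues.geometry)


def simulate_noncorrected_sinogram(
    activity: Volume,
    mu_ref: Volume,
    geom: ScannerGeometry,
    cfg: ReconConfig | None = None,
    seed: int | None = None,
) -> tuple[Sinogram, Sinogram]:
    """Simulate the non-corrected sinogram a scanner would acquire.

    Trues are the attenuated forward projection of the activity through the
    reference mu-map; the scatter surrogate is added on top.  Poisson noise
    is optional (off by default, matching a noiseless comparison design) and
    requires an explicit seed.
    """
    cfg = cfg or ReconConfig()
    if np.any(activity.values < 0):
        raise ValueError("activity must be nonnegative")
    trues_vals = forward_project(activity, geom).values / attenuation_factors(
        mu_ref, geom
    ).values
    trues = Sinogram(trues_vals, SinogramKind.EMISSION, geom)
    scatter = scatter_surrogate(trues, cfg)
    noncorr = trues.values + scatter.values
    if cfg.poisson_noise:
        if seed is None:
            raise ValueError("Poisson noise requires an explicit seed")
        rng = np.random.default_rng(seed)
        noncorr = rng.poisson(noncorr * cfg.counts_scale).astype(np.float64) / cfg.counts_scale
    return Sinogram(noncorr, SinogramKind.EMISSION, geom), scatter


def _subset_indices(n_angles: int, n_subsets: int) -> list[np.ndarray]:
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


def osem_reconstruct(
    noncorr: Sinogram,
    mu: Volume,
    scatter: Sinogram,
    geom: ScannerGeometry,
    cfg: ReconConfig | None = None,
) -> Volume:
    """OSEM reconstruction with attenuation and scatter in the system model.

    Update per angle-interleaved subset s:

        x <- x * P'_s^T [ y_s / (P'_s x + scatter_s) ] / P'_s^T 1

    with ``P' = diag(1/acf) P``.  Nonnegativity is preserved; voxels with
    zero subset sensitivity stay at zero.
    """
    cfg = cfg or ReconConfig()
    n_subsets = cfg.n_subsets
    if geom.n_angles % n_subsets != 0:
        adjusted = int(np.gcd(geom.n_angles, n_subsets))
        import warnings

        warnings.warn(
            f"n_subsets {n_subsets} does not divide n_angles {geom.n_angles}; "
            f"using {adjusted}"
        )
        n_subsets = adjusted
    acf = attenuation_factors(mu, geom).values  # (nz, n_angles, n_radial)
    A = system_matrix(geom)
    nx, ny = geom.image_shape
    nz = noncorr.values.shape[0]
    att = 1.0 / acf  # attenuation survival per LOR

    y = np.moveaxis(noncorr.values, 0, 2).reshape(-1, nz)
    s_term = np.moveaxis(scatter.values, 0, 2).reshape(-1, nz)
    att_flat = np.moveaxis(att, 0, 2).reshape(-1, nz)

    subsets = _subset_indices(geom.n_angles, n_subsets)
    sub_rows = [
        (idx[:, None] * geom.n_radial + np.arange(geom.n_radial)[None, :]).ravel()
        for idx in subsets
    ]
    A_subs = [A[r] for r in sub_rows]
    sens = []
    for A_s, r in zip(A_subs, sub_rows):
        sens.append(A_s.T @ att_flat[r])  # (npix, nz) subset sensitivity
    x = np.ones((nx * ny, nz))
    support = np.zeros((nx * ny, nz), dtype=bool)
    for s in sens:
        support |= s > 0
    x[~support] = 0.0

    for _ in range(cfg.n_iterations):
        for A_s, r, sen in zip(A_subs, sub_rows, sens):
            proj = att_flat[r] * (A_s @ x) + s_term[r]
            ratio = np.divide(y[r], proj, out=np.zeros_like(proj), where=proj > 0)
            update = A_s.T @ (att_flat[r] * ratio)
            x *= np.divide(update, sen, out=np.zeros_like(update), where=sen > 0)
            if cfg.nonneg_floor > 0:
                np.clip(x, cfg.nonneg_floor, None, out=x)
    img = x.reshape(nx, ny, nz)
    if not np.any(img > 0):
        raise RuntimeError("reconstruction has zero sensitivity everywhere")
    return Volume(img, mu.spacing, mu.origin, Modality.PET)
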