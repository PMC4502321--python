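"""Inter-subject registration contract: affine followed by non-rigid.

The synthesis pipeline only requires a mapping from the target grid into
each atlas, together with propagation of the atlas field-of-view mask.
This module provides:

* a :class:`Transform` container (4x4 world-mm affine plus an optional
  dense displacement field on the target grid, in mm), serialisable so
  transforms computed by an external registration engine can be supplied
  precomputed;
* a built-in baseline adequate for phantom cohorts: a deterministic
  multiresolution translation/affine search over a configurable metric
  (NCC or NMI, summed over channels for multi-contrast pairs), followed by
  a Gaussian-regularised dense force-field refinement (demons-style
  gradient flow on the intensity mismatch), again driven by all channels.

Convention: the displacement field maps target-grid points to moving-image
world points, ``p_moving(y) = A @ y + u(y)``; resampling pulls moving-image
values back onto the target grid at those points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image_model import GridSpec, MaskKind, Modality, ROIMask, Volume


@dataclass
class Transform:
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    displacement: np.ndarray | None = None  # (3, *target_shape), mm
    target_grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.displacement is not None and not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")

    @classmethod
    def identity(cls) -> "Transform":
        return cls()

    @classmethod
    def translation(cls, t_mm) -> "Transform":
        a = np.eye(4)
        a[:3, 3] = t_mm
        return cls(affine=a)


@dataclass
class RegistrationConfig:
    metric: str = "NCC"  # NCC | NMI (multichannel = per-channel sum)
    levels: int = 2
    affine_mode: str = "translation"  # translation | rigid-free baseline
    nonrigid: bool = True
    smooth_sigma_mm: float = 6.0  # fluid smoothing of each update
    elastic_sigma_mm: float = 1.0  # light smoothing of the total field
    max_iterations: int = 30
    step_mm: float = 1.5
    tol: float = 1e-5
    nmi_bins: int = 32

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.metric not in ("NCC", "NMI"):
            raise ValueError(f"unknown metric {self.metric!r}")


def save_transform(t: Transform, prefix) -> None:
    """Write a transform as ``<prefix>_affine.txt`` (4x4 text matrix) and,
    when present, ``<prefix>_disp.nii.gz`` (3-component displacement, mm)."""
    import nibabel as nib

    prefix = str(prefix)
    np.savetxt(prefix + "_affine.txt", t.affine)
    if t.displacement is not None:
        grid = t.target_grid
        aff = np.eye(4)
        if grid is not None:
            aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
            aff[:3, 3] = grid.origin
        data = np.moveaxis(t.displacement, 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(data, aff), prefix + "_disp.nii.gz")


def load_transform(prefix) -> Transform:
    """Read a transform written by :func:`save_transform`."""
    import os

    import nibabel as nib

    prefix = str(prefix)
    affine = np.loadtxt(prefix + "_affine.txt")
    disp_path = prefix + "_disp.nii.gz"
    disp = None
    grid = None
    if os.path.exists(disp_path):
        img = nib.load(disp_path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        disp = np.moveaxis(data, -1, 0)
        spacing = tuple(float(img.affine[i, i]) for i in range(3))
        origin = tuple(float(v) for v in img.affine[:3, 3])
        grid = GridSpec(disp.shape[1:], spacing, origin)
    return Transform(affine=affine, displacement=disp, target_grid=grid)


# ---------------------------------------------------------------------------
# metrics


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Global normalised cross-correlation over a mask."""
    av, bv = a[mask], b[mask]
    if av.size < 2:
        return 0.0
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def nmi(a: np.ndarray, b: np.ndarray, mask: np.ndarray, bins: int = 32) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B) over a mask."""
    av, bv = a[mask], b[mask]
    if av.size < 2:
        return 0.0
    h, _, _ = np.histogram2d(av, bv, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = -np.nansum(px * np.log(px, where=px > 0))
        hy = -np.nansum(py * np.log(py, where=py > 0))
        hxy = -np.nansum(p * np.log(p, where=p > 0))
    return float((hx + hy) / hxy) if hxy > 0 else 0.0


def _metric_value(cfg: RegistrationConfig, fixed, warped, mask) -> float:
    f = ncc if cfg.metric == "NCC" else (lambda a, b, m: nmi(a, b, m, cfg.nmi_bins))
    return sum(f(fw, ww, mask) for fw, ww in zip(fixed, warped))


# ---------------------------------------------------------------------------
# resampling under a transform


def _sample(vol: Volume, coords_vox: np.ndarray, order: int, cval: float) -> np.ndarray:
    return ndimage.map_coordinates(vol.values, coords_vox, order=order,
                                   mode="constant", cval=cval)


def _target_world(grid: GridSpec) -> list[np.ndarray]:
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid.shape],
                      indexing="ij")
    return [grid.origin[ax] + idx[ax] * grid.spacing[ax] for ax in range(3)]


def _moving_coords(t: Transform, grid: GridSpec) -> np.ndarray:
    world = _target_world(grid)
    A = t.affine
    pts = [A[ax, 0] * world[0] + A[ax, 1] * world[1] + A[ax, 2] * world[2] + A[ax, 3]
           for ax in range(3)]
    if t.displacement is not None:
        for ax in range(3):
            pts[ax] = pts[ax] + t.displacement[ax]
    return np.stack(pts)


def apply_transform(
    vol: Volume,
    t: Transform,
    target_grid: GridSpec,
    interp: str = "linear",
    moving_fov: ROIMask | None = None,
    fill_value: float | None = None,
) -> tuple[Volume, ROIMask]:
    """Pull ``vol`` back onto ``target_grid`` through transform ``t``.

    The returned FOV_VALIDITY mask is true only where the pulled-back
    sample point lies inside the moving grid (and inside ``moving_fov``
    when given) — validity can only be lost under composition, never
    invented.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.modality is Modality.LABEL and interp != "nearest":
        raise ValueError("LABEL volumes require nearest-neighbour interpolation")
    if fill_value is None:
        fill_value = -1000.0 if vol.modality is Modality.CT_HU else 0.0
    pts = _moving_coords(t, target_grid)
    coords = np.empty_like(pts)
    inside = np.ones(target_grid.shape, dtype=bool)
    for ax in range(3):
        coords[ax] = (pts[ax] - vol.origin[ax]) / vol.spacing[ax]
        n = vol.values.shape[ax]
        inside &= (coords[ax] >= -1e-9) & (coords[ax] <= n - 1 + 1e-9)
    order = 1 if interp == "linear" else 0
    out = _sample(vol, coords, order, fill_value)
    out[~inside] = fill_value
    valid = inside
    if moving_fov is not None:
        fov = ndimage.map_coordinates(moving_fov.values.astype(np.float64), coords,
                                      order=0, mode="constant", cval=0.0)
        valid = valid & (fov > 0.5)
        out[~valid] = fill_value
    res = Volume(out, target_grid.spacing, target_grid.origin, vol.modality)
    return res, ROIMask(valid, target_grid.spacing, target_grid.origin,
                        MaskKind.FOV_VALIDITY)


# ---------------------------------------------------------------------------
# baseline registration


def _downsample(vals: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vals
    sig = 0.5 * factor
    sm = ndimage.gaussian_filter(vals, sig, mode="nearest")
    return sm[::factor, ::factor, ::factor]


def _normalize(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = vals[mask]
    sd = v.std()
    return (vals - v.mean()) / sd if sd > 0 else vals * 0.0


def _affine_stage(moving, fixed, m_fov, f_fov, cfg: RegistrationConfig) -> np.ndarray:
    """Multiresolution translation search (deterministic Powell)."""
    best = np.zeros(3)
    factors = [2 ** (cfg.levels - 1 - i) * 2 for i in range(cfg.levels)]
    for factor in factors:
        fx = [_downsample(f.values, factor) for f in fixed]
        mv = [_downsample(m.values, factor) for m in moving]
        fmask = _downsample(f_fov.values.astype(float), factor) > 0.5
        spacing = [s * factor for s in fixed[0].spacing]
        grid_pts = np.meshgrid(*[np.arange(n) * sp for n, sp in
                                 zip(fx[0].shape, spacing)], indexing="ij")

        def neg_metric(t):
            coords = np.stack([(grid_pts[ax] + t[ax]) / spacing[ax] for ax in range(3)])
            warped = []
            inside = np.ones(fx[0].shape, dtype=bool)
            for ax in range(3):
                inside &= (coords[ax] >= 0) & (coords[ax] <= mv[0].shape[ax] - 1)
            m = fmask & inside
            if m.sum() < 8:
                return 1.0
            for arr in mv:
                warped.append(ndimage.map_coordinates(arr, coords, order=1,
                                                      mode="nearest"))
            return -_metric_value(cfg, fx, warped, m)

        res = optimize.minimize(neg_metric, best, method="Powell",
                                options={"xtol": 0.05 * min(spacing),
                                         "ftol": 1e-6, "maxiter": 50})
        best = res.x
    a = np.eye(4)
    a[:3, 3] = best
    return a


def _demons_level(fx, mvols, f_mask, m_fov, affine, u, cfg: RegistrationConfig,
                  grid: GridSpec, n_iter: int) -> tuple[np.ndarray, float, bool]:
    """Run demons-style iterations on one resolution level."""
    spacing = np.array(grid.spacing)
    sig_vox = [cfg.smooth_sigma_mm / s for s in spacing]

    def warp_all(disp):
        t = Transform(affine=affine, displacement=disp)
        ws, valid = [], None
        for m in mvols:
            w, msk = apply_transform(m, t, grid, interp="linear", moving_fov=m_fov)
            ws.append(w.values)
            valid = msk.values if valid is None else (valid & msk.values)
        return ws, valid & f_mask

    warped, mask = warp_all(u)
    best_metric = _metric_value(cfg, fx, warped, mask)
    best_u = u.copy()
    diverged = False
    for _ in range(n_iter):
        force = np.zeros_like(u)
        for fw, ww in zip(fx, warped):
            diff = fw - ww
            grads = np.gradient(ww, *spacing)
            g2 = sum(g**2 for g in grads)
            denom = g2 + (diff**2) / (cfg.step_mm**2)
            scale = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 1e-12)
            scale *= mask
            for ax in range(3):
                # first-order step: move the sample point along the warped
                # gradient so the warped intensity approaches the fixed one
                force[ax] += scale * grads[ax]
        el_vox = [cfg.elastic_sigma_mm / s for s in spacing]
        for ax in range(3):
            # fluid smoothing of the update, light elastic smoothing of the field
            upd = ndimage.gaussian_filter(force[ax], sig_vox, mode="nearest")
            u[ax] = ndimage.gaussian_filter(u[ax] + upd, el_vox, mode="nearest")
        warped, mask = warp_all(u)
        metric = _metric_value(cfg, fx, warped, mask)
        if metric > best_metric + cfg.tol:
            best_metric = metric
            best_u = u.copy()
        elif metric < best_metric - 0.05:
            diverged = True
            break
    return best_u, best_metric, diverged


def _downsample_volume(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    vals = _downsample(vol.values, factor)
    return Volume(vals, tuple(s * factor for s in vol.spacing), vol.origin)


def _demons_stage(moving, fixed, m_fov, f_fov, affine, cfg: RegistrationConfig,
                  grid: GridSpec) -> tuple[np.ndarray, dict]:
    """Multiresolution Gaussian-regularised force-field refinement.

    Coarse levels absorb the bulk of the displacement cheaply; the final
    level polishes at full resolution.  The displacement field is in mm, so
    upsampling between levels only resamples it spatially.
    """
    f_mask_full = f_fov.values
    fx_full = [_normalize(f.values, f_mask_full) for f in fixed]
    mv_full = [Volume(_normalize(m.values, m_fov.values), m.spacing, m.origin)
               for m in moving]
    factors = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    iters = _split_iterations(cfg.max_iterations, cfg.levels)
    u = None
    diag: dict = {}
    for factor, n_iter in zip(factors, iters):
        fx = [_downsample(f, factor) for f in fx_full]
        mvols = [_downsample_volume(m, factor) for m in mv_full]
        fmask = _downsample(f_mask_full.astype(float), factor) > 0.5
        mfov = ROIMask(_downsample(m_fov.values.astype(float), factor) > 0.5,
                       mvols[0].spacing, mvols[0].origin, MaskKind.FOV_VALIDITY)
        lgrid = GridSpec(fx[0].shape,
                         tuple(s * factor for s in grid.spacing), grid.origin)
        if u is None:
            u = np.zeros((3,) + fx[0].shape)
        else:
            u = np.stack([
                ndimage.zoom(u[ax], [n / c for n, c in zip(fx[0].shape, u.shape[1:])],
                             order=1, mode="nearest", grid_mode=True)
                for ax in range(3)
            ])
        u, metric, diverged = _demons_level(fx, mvols, fmask, mfov, affine, u,
                                            cfg, lgrid, n_iter)
        diag = {"final_metric": metric, "diverged": diverged}
    if u.shape[1:] != tuple(grid.shape):
        u = np.stack([
            ndimage.zoom(u[ax], [n / c for n, c in zip(grid.shape, u.shape[1:])],
                         order=1, mode="nearest", grid_mode=True)
            for ax in range(3)
        ])
    return u, diag


def _split_iterations(total: int, levels: int) -> list[int]:
    # most iterations on the coarsest (cheapest) level
    if levels == 1:
        return [total]
    coarse = max(1, int(round(total * 0.75)))
    rest = max(1, total - coarse)
    out = [coarse] + [max(1, rest // (levels - 1))] * (levels - 1)
    return out


def register(
    moving: list[Volume],
    fixed: list[Volume],
    cfg: RegistrationConfig | None = None,
    moving_fov: ROIMask | None = None,
    fixed_fov: ROIMask | None = None,
) -> tuple[Transform, dict]:
    """Register moving channels onto fixed channels (affine then non-rigid).

    The metric is evaluated over valid voxels only (intersection of the FOV
    masks); the multichannel metric is the unweighted per-channel sum.
    Deterministic: identity initialisation, no stochastic optimisation.
    """
    cfg = cfg or RegistrationConfig()
    if len(moving) != len(fixed):
        raise ValueError("moving and fixed channel counts must match")
    grid = fixed[0].grid
    if moving_fov is None:
        moving_fov = ROIMask(np.ones(moving[0].values.shape, dtype=bool),
                             moving[0].spacing, moving[0].origin, MaskKind.FOV_VALIDITY)
    if fixed_fov is None:
        fixed_fov = ROIMask(np.ones(fixed[0].values.shape, dtype=bool),
                            fixed[0].spacing, fixed[0].origin, MaskKind.FOV_VALIDITY)
    if fixed_fov.n_true == 0 or moving_fov.n_true == 0:
        raise ValueError("registration domain is empty")

    affine = _affine_stage(moving, fixed, moving_fov, fixed_fov, cfg)
    diag: dict = {"translation_mm": affine[:3, 3].tolist()}
    if cfg.nonrigid:
        u, ddiag = _demons_stage(moving, fixed, moving_fov, fixed_fov, affine, cfg, grid)
        diag.update(ddiag)
        if np.abs(u).max() == 0:
            return Transform(affine=affine, target_grid=grid), diag
        return Transform(affine=affine, displacement=u, target_grid=grid), diag
    return Transform(affine=affine, target_grid=grid), diag
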