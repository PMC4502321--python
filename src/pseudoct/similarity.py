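"""Convolution-based local normalised cross-correlation with irregular ROIs.

LNCC computes, at every voxel, the Pearson correlation between two images
under a Gaussian window, evaluated efficiently with separable convolutions.
When the images carry field-of-view gaps (e.g. a CT that covers only the
head propagated into an MRI grid that covers head and neck), the plain
convolutional estimator mixes no-data regions into the local statistics.
The ROI extension computes every moment under a joint validity mask:

    mean(x) = G_s*(m.f)(x) / G_s*m(x)
    var(x)  = G_s*(m.f^2)(x) / G_s*m(x) - mean(x)^2

so that voxels outside the mask contribute nothing, and LNCC values are
only trusted where the smoothed mask support is above a threshold.

The multivariate variant sums the per-channel ROI-LNCC maps, letting two
MRI contrasts contribute complementary evidence to atlas ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import MaskKind, ROIMask, Volume

#: minimum smoothed-mask support before a local moment is trusted
DEFAULT_SUPPORT_THRESHOLD = 0.5
#: variance floor, relative to the global (in-ROI) image variance
DEFAULT_VAR_FLOOR_REL = 1e-6
#: value assigned to invalid voxels ("no evidence", neutral for ranking)
NEUTRAL_FILL = 0.0


@dataclass
class LocalMoments:
    """Gaussian-window masked local statistics of one image."""

    mean: np.ndarray
    var: np.ndarray
    support: np.ndarray  # G_sigma * roi, in [0, 1]
    sigma_vox: tuple[float, float, float]


def _sigma_vox(sigma_mm: float, spacing) -> tuple[float, float, float]:
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    return tuple(sigma_mm / s for s in spacing)


def _smooth(arr: np.ndarray, sigma_vox) -> np.ndarray:
    # constant zero padding: outside-grid voxels behave exactly like
    # masked-out voxels, so FOV borders and grid borders are treated alike
    return ndimage.gaussian_filter(arr.astype(np.float64), sigma_vox, mode="constant", cval=0.0)


def local_moments(img: Volume, roi: ROIMask, sigma_mm: float) -> LocalMoments:
    """Masked local mean/variance of ``img`` under a Gaussian window.

    Moments are exact ratios of smoothed masked sums, so voxels outside
    ``roi`` have no influence on interior values.
    """
    if roi.n_true == 0:
        raise ValueError("ROI is empty")
    sig = _sigma_vox(sigma_mm, img.spacing)
    m = roi.values.astype(np.float64)
    f = img.values * m
    support = _smooth(m, sig)
    denom = np.where(support > 0, support, 1.0)
    mean = _smooth(f, sig) / denom
    var = _smooth(f * img.values, sig) / denom - mean**2
    np.clip(var, 0.0, None, out=var)
    mean[support <= 0] = 0.0
    var[support <= 0] = 0.0
    return LocalMoments(mean=mean, var=var, support=support, sigma_vox=sig)


def roi_lncc(
    target: Volume,
    atlas: Volume,
    roi_t: ROIMask,
    roi_a: ROIMask,
    sigma_mm: float,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    var_floor_rel: float = DEFAULT_VAR_FLOOR_REL,
) -> tuple[np.ndarray, ROIMask]:
    """Per-voxel LNCC of two images under their joint validity ROI.

    All moments (means, variances, covariance) are computed under the joint
    ROI ``roi_t & roi_a``.  Voxels where the smoothed support falls below
    ``support_threshold``, or where either local variance vanishes, are
    marked invalid and assigned the neutral value 0.

    Returns the LNCC grid (clipped to [-1, 1]) and the validity mask.
    """
    if not target.same_grid(atlas):
        raise ValueError("target and atlas must share one grid")
    joint = roi_t.values & roi_a.values
    if not joint.any():
        raise ValueError("joint ROI is empty")
    sig = _sigma_vox(sigma_mm, target.spacing)

    m = joint.astype(np.float64)
    support = _smooth(m, sig)
    denom = np.where(support > 0, support, 1.0)
    t = target.values
    a = atlas.values
    mean_t = _smooth(t * m, sig) / denom
    mean_a = _smooth(a * m, sig) / denom
    var_t = np.clip(_smooth(t * t * m, sig) / denom - mean_t**2, 0.0, None)
    var_a = np.clip(_smooth(a * a * m, sig) / denom - mean_a**2, 0.0, None)
    cov = _smooth(t * a * m, sig) / denom - mean_t * mean_a

    eps_t = var_floor_rel * max(float(t[joint].var()), np.finfo(float).tiny)
    eps_a = var_floor_rel * max(float(a[joint].var()), np.finfo(float).tiny)
    valid = (support >= support_threshold) & (var_t > eps_t) & (var_a > eps_a)

    lncc = np.full(t.shape, NEUTRAL_FILL)
    np.divide(cov, np.sqrt(var_t * var_a), out=lncc, where=valid)
    np.clip(lncc, -1.0, 1.0, out=lncc)
    lncc[~valid] = NEUTRAL_FILL
    mask = ROIMask(valid, target.spacing, target.origin, MaskKind.FOV_VALIDITY)
    return lncc, mask


def mv_roi_lncc(
    channel_pairs: list[tuple[Volume, Volume]],
    roi_t: ROIMask,
    rois_a: list[ROIMask] | ROIMask,
    sigma_mm: float,
    **kwargs,
) -> tuple[np.ndarray, ROIMask]:
    """Multivariate ROI-LNCC: the sum of the per-channel ROI-LNCC maps.

    ``channel_pairs`` is a list of (target channel, atlas channel) pairs on a
    common grid.  A voxel is valid where at least one channel is valid;
    invalid channels contribute the neutral value 0 there, so an
    information-free channel (e.g. locally constant) degrades the statistic
    gracefully to the remaining channels instead of vetoing them.  The
    result ranges in [-C, C] for C channels.
    """
    if not channel_pairs:
        raise ValueError("at least one channel pair required")
    if isinstance(rois_a, ROIMask):
        rois_a = [rois_a] * len(channel_pairs)
    if len(rois_a) != len(channel_pairs):
        raise ValueError("one atlas ROI per channel pair required")
    total = None
    valid = None
    for (t, a), ra in zip(channel_pairs, rois_a):
        val, mask = roi_lncc(t, a, roi_t, ra, sigma_mm, **kwargs)
        total = val if total is None else total + val
        valid = mask.values if valid is None else (valid | mask.values)
    total[~valid] = NEUTRAL_FILL
    t0 = channel_pairs[0][0]
    return total, ROIMask(valid, t0.spacing, t0.origin, MaskKind.FOV_VALIDITY)


def plain_lncc(
    target: Volume, atlas: Volume, sigma_mm: float, **kwargs
) -> tuple[np.ndarray, ROIMask]:
    """Legacy LNCC ignoring FOV validity: full-grid moments.

    Retained solely to reproduce the behaviour of ranking without ROI
    handling, where no-data fill values contaminate the local statistics.
    """
    full = ROIMask(
        np.ones(target.values.shape, dtype=bool),
        target.spacing,
        target.origin,
        MaskKind.FOV_VALIDITY,
    )
    return roi_lncc(target, atlas, full, full, sigma_mm, **kwargs)
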