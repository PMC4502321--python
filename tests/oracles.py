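"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths under test: windowed explicit sums
for the Gaussian-weighted masked moments, per-voxel Python sorting for
ranks, and two-pass loops for the error metrics.
"""

import numpy as np


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian sampled at integers, matching ndimage's kernel."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    return phi / phi.sum()


def masked_moments_bruteforce(img, roi, sigma_vox, truncate=4.0):
    """Per-voxel Gaussian-weighted masked mean/variance by explicit sums.

    Zero-padding outside the grid, i.e. out-of-grid voxels count as
    masked-out, matching the constant-mode convolution convention.
    """
    kernels = [gaussian_kernel_1d(s, truncate) for s in sigma_vox]
    radii = [(len(k) - 1) // 2 for k in kernels]
    shape = img.shape
    pad = [(r, r) for r in radii]
    img_p = np.pad(img, pad)
    roi_p = np.pad(roi.astype(float), pad)
    k3 = kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    mean = np.zeros(shape)
    var = np.zeros(shape)
    support = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                wi = img_p[i : i + 2 * radii[0] + 1,
                           j : j + 2 * radii[1] + 1,
                           k : k + 2 * radii[2] + 1]
                wm = roi_p[i : i + 2 * radii[0] + 1,
                           j : j + 2 * radii[1] + 1,
                           k : k + 2 * radii[2] + 1]
                w = k3 * wm
                sw = w.sum()
                support[i, j, k] = sw
                if sw > 0:
                    m = (w * wi).sum() / sw
                    mean[i, j, k] = m
                    var[i, j, k] = max((w * wi * wi).sum() / sw - m * m, 0.0)
    return mean, var, support


def masked_lncc_bruteforce(t, a, roi, sigma_vox, truncate=4.0):
    """Per-voxel Gaussian-weighted masked correlation by explicit sums."""
    kernels = [gaussian_kernel_1d(s, truncate) for s in sigma_vox]
    radii = [(len(k) - 1) // 2 for k in kernels]
    shape = t.shape
    pad = [(r, r) for r in radii]
    t_p = np.pad(t, pad)
    a_p = np.pad(a, pad)
    roi_p = np.pad(roi.astype(float), pad)
    k3 = kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    lncc = np.zeros(shape)
    support = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                sl = (slice(i, i + 2 * radii[0] + 1),
                      slice(j, j + 2 * radii[1] + 1),
                      slice(k, k + 2 * radii[2] + 1))
                w = k3 * roi_p[sl]
                sw = w.sum()
                support[i, j, k] = sw
                if sw <= 0:
                    continue
                wt, wa = t_p[sl], a_p[sl]
                mt = (w * wt).sum() / sw
                ma = (w * wa).sum() / sw
                vt = (w * wt * wt).sum() / sw - mt * mt
                va = (w * wa * wa).sum() / sw - ma * ma
                cov = (w * wt * wa).sum() / sw - mt * ma
                if vt > 0 and va > 0:
                    lncc[i, j, k] = cov / np.sqrt(vt * va)
    return np.clip(lncc, -1.0, 1.0), support
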