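"""Quantitative endpoints: MAE/ME on CT, relative MAE/ME on PET, SUVR
normalisation, difference-map projections and cohort-level reporting.

For a test image I and reference R over a region V of N_V voxels:

    MAE  = (1/N_V) sum_v |I_v - R_v|        ME  = (1/N_V) sum_v (I_v - R_v)
    rMAE = 100 * sum_v |I_v - R_v| / sum_v R_v
    rME  = 100 * sum_v (I_v - R_v) / sum_v R_v

The sign convention is test minus reference throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_model import ROIMask, Volume


@dataclass
class RegionStats:
    region: str
    mae: float
    me: float
    rmae: float | None = None
    rme: float | None = None
    n_voxels: int = 0


def mae_me(I: Volume, R: Volume, roi: ROIMask) -> tuple[float, float]:
    """Mean absolute error and mean (signed) error of I vs R over roi."""
    if not I.same_grid(R):
        raise ValueError("images must share one grid")
    if roi.n_true == 0:
        raise ValueError("empty ROI")
    d = I.values[roi.values] - R.values[roi.values]
    return float(np.abs(d).mean()), float(d.mean())


def rmae_rme(I: Volume, R: Volume, roi: ROIMask) -> tuple[float, float]:
    """Relative MAE and ME (percent of the reference sum) over roi."""
    if not I.same_grid(R):
        raise ValueError("images must share one grid")
    if roi.n_true == 0:
        raise ValueError("empty ROI")
    r = R.values[roi.values]
    denom = r.sum()
    if denom <= 0:
        raise ValueError("reference sum over the ROI must be positive")
    d = I.values[roi.values] - r
    return float(100.0 * np.abs(d).sum() / denom), float(100.0 * d.sum() / denom)


def normalize_suvr(pet: Volume, ref: ROIMask) -> tuple[Volume, float]:
    """Normalise a PET image by its mean uptake in a reference region.

    Returns the normalised image (mean over ``ref`` is exactly 1) and the
    reference mean, which is reported alongside because errors *in* the
    reference region propagate into every normalised value.
    """
    if ref.n_true == 0:
        raise ValueError("empty reference region")
    mean = float(pet.values[ref.values].mean())
    if mean <= 0:
        raise ValueError("reference-region mean must be positive")
    return pet.with_values(pet.values / mean), mean


def difference_map_summary(
    diffs: list[Volume], axis: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject mean and SD of difference maps, projected along an axis.

    Voxelwise mean and SD are taken across subjects, then each is collapsed
    to 2-D by a mean-intensity projection (the mean value along each
    projection line).
    """
    if len(diffs) < 2:
        raise ValueError("need at least two volumes for an SD map")
    ref = diffs[0]
    for d in diffs[1:]:
        if not d.same_grid(ref):
            raise ValueError("difference maps must share one grid")
    stack = np.stack([d.values for d in diffs])
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=0)
    return mean_map.mean(axis=axis), sd_map.mean(axis=axis)


def stats_for_regions(
    I: Volume, R: Volume, regions: dict[str, ROIMask], relative: bool = True
) -> list[RegionStats]:
    out = []
    for name, roi in regions.items():
        mae, me = mae_me(I, R, roi)
        rmae = rme = None
        if relative:
            rmae, rme = rmae_rme(I, R, roi)
        out.append(RegionStats(name, mae, me, rmae, rme, roi.n_true))
    return out


def report_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-(subject, method, region) rows into a tidy report."""
    return pd.DataFrame(rows)


def summarize_report(df: pd.DataFrame, value_cols=("mae", "me", "rmae", "rme")) -> pd.DataFrame:
    """Mean/SD/min/max across subjects per (method, region)."""
    cols = [c for c in value_cols if c in df.columns]
    g = df.groupby(["method", "region"])[cols]
    out = g.agg(["mean", "std", "min", "max"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def paired_wilcoxon(df: pd.DataFrame, value_col: str, method_a: str, method_b: str,
                    region: str) -> float:
    """One-tailed Wilcoxon signed-rank p-value that method_a < method_b."""
    from scipy.stats import wilcoxon

    sub = df[df["region"] == region].pivot(index="subject", columns="method",
                                           values=value_col)
    a, b = sub[method_a].to_numpy(), sub[method_b].to_numpy()
    if np.allclose(a, b):
        return 1.0
    return float(wilcoxon(a, b, alternative="less").pvalue)
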