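"""Rank-based voxel-wise atlas fusion.

At every voxel the atlases are ranked by local similarity (best = rank 1);
ranks are converted to weights with an exponential decay
``w = exp(-(rank-1)/beta)`` over the top ``K`` atlases, normalised to sum
to one, and the pseudo-CT is the spatially varying weighted average of the
propagated atlas CTs.  Voxels where no atlas carries valid evidence fall
back to a configurable default (air outside the head, nearest valid
neighbour inside it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import (
    CT_AIR_HU,
    AtlasDatabase,
    MaskKind,
    Modality,
    ROIMask,
    Volume,
)
from . import similarity as sim

RANK_INVALID = np.iinfo(np.int32).max


@dataclass
class SimilarityStack:
    """Per-atlas, per-voxel similarity values with their joint validity."""

    values: np.ndarray  # (n_atlases, *shape)
    valid: np.ndarray  # bool, same shape
    sigma_mm: float

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")

    @property
    def n_atlases(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightMap:
    weights: np.ndarray  # (n_atlases, *shape), nonnegative, sums to 1 where valid
    valid: np.ndarray  # bool, (*shape,): at least one valid atlas
    beta: float
    K: int


@dataclass
class SynthesisConfig:
    """Configuration of one pseudo-CT synthesis variant."""

    sigma_mm: float = 3.0
    beta: float = 0.5
    K: int | None = None  # None = all atlases
    channel_mode: str = "t1"  # "t1" | "t2" | "t1t2"
    legacy_lncc: bool = False  # plain LNCC ignoring FOV validity
    support_threshold: float = sim.DEFAULT_SUPPORT_THRESHOLD

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.channel_mode not in ("t1", "t2", "t1t2"):
            raise ValueError(f"unknown channel mode {self.channel_mode!r}")

    def to_dict(self) -> dict:
        return {
            "sigma_mm": self.sigma_mm,
            "beta": self.beta,
            "K": self.K,
            "channel_mode": self.channel_mode,
            "legacy_lncc": self.legacy_lncc,
            "support_threshold": self.support_threshold,
        }


def rank_similarities(stack: SimilarityStack) -> np.ndarray:
    """Rank atlases at each voxel: 1 = most similar valid atlas.

    Invalid atlas voxels receive ``RANK_INVALID`` and are excluded from
    weighting.  Ties are broken by atlas database order (stable sort).
    """
    if stack.n_atlases < 1:
        raise ValueError("at least one atlas required")
    vals = np.where(stack.valid, stack.values, -np.inf)
    # stable argsort of descending similarity; negate and use stable kind
    order = np.argsort(-vals, axis=0, kind="stable")
    ranks = np.empty(vals.shape, dtype=np.int32)
    np.put_along_axis(ranks, order, np.arange(1, stack.n_atlases + 1, dtype=np.int32).reshape(
        (-1,) + (1,) * (vals.ndim - 1)), axis=0)
    ranks[~stack.valid] = RANK_INVALID
    return ranks


def ranks_to_weights(ranks: np.ndarray, beta: float, K: int | None = None) -> WeightMap:
    """Exponential-decay weights ``exp(-(rank-1)/beta)`` over the top K atlases."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    n = ranks.shape[0]
    K = n if K is None else int(K)
    if not 1 <= K <= n:
        raise ValueError("K must satisfy 1 <= K <= n_atlases")
    usable = (ranks != RANK_INVALID) & (ranks <= K)
    with np.errstate(over="ignore"):
        w = np.where(usable, np.exp(-(np.where(usable, ranks, 1) - 1.0) / beta), 0.0)
    total = w.sum(axis=0)
    valid = total > 0
    w = np.divide(w, total, out=np.zeros_like(w), where=valid)
    return WeightMap(weights=w, valid=valid, beta=beta, K=K)


def fuse_cts(
    propagated_cts: list[Volume],
    weights: WeightMap,
    fallback: Volume | None = None,
    head_mask: ROIMask | None = None,
) -> Volume:
    """Weighted voxel-wise average of propagated CTs.

    Where no atlas carries evidence, the voxel takes ``fallback`` if given;
    otherwise air (-1000 HU) outside ``head_mask`` and the nearest valid
    fused value inside it.
    """
    ref = propagated_cts[0]
    cts = np.stack([c.values for c in propagated_cts])
    if cts.shape != weights.weights.shape:
        raise ValueError("CT stack and weight map shapes differ")
    sums = weights.weights.sum(axis=0)
    if np.any(np.abs(sums[weights.valid] - 1.0) > 1e-10):
        raise AssertionError("weight rows at valid voxels must sum to 1")
    fused = (weights.weights * cts).sum(axis=0)
    invalid = ~weights.valid
    if invalid.any():
        if fallback is not None:
            fused[invalid] = fallback.values[invalid]
        else:
            fused[invalid] = CT_AIR_HU
            if head_mask is not None:
                gap = invalid & head_mask.values
                if gap.any() and weights.valid.any():
                    # nearest-valid-neighbour fill inside the head
                    _, idx = ndimage.distance_transform_edt(
                        invalid, sampling=ref.spacing, return_indices=True
                    )
                    fused[gap] = fused[tuple(i[gap] for i in idx)]
    return Volume(fused, ref.spacing, ref.origin, Modality.CT_HU)


def build_similarity_stack(
    target_channels: list[Volume],
    target_fov: ROIMask,
    propagated: list[dict],
    cfg: SynthesisConfig,
) -> SimilarityStack:
    """Compute the per-atlas similarity stack for the configured variant.

    ``propagated`` holds, per atlas, ``{"channels": [Volume...], "fov": ROIMask}``
    already resampled onto the target grid.
    """
    values, valids = [], []
    full = ROIMask(
        np.ones(target_channels[0].values.shape, dtype=bool),
        target_channels[0].spacing,
        target_channels[0].origin,
        MaskKind.FOV_VALIDITY,
    )
    for entry in propagated:
        chans = entry["channels"]
        if cfg.legacy_lncc:
            roi_t, roi_a = full, full
        else:
            roi_t, roi_a = target_fov, entry["fov"]
        pairs = list(zip(target_channels, chans))
        if len(pairs) == 1:
            val, mask = sim.roi_lncc(
                pairs[0][0], pairs[0][1], roi_t, roi_a, cfg.sigma_mm,
                support_threshold=cfg.support_threshold,
            )
        else:
            val, mask = sim.mv_roi_lncc(
                pairs, roi_t, roi_a, cfg.sigma_mm,
                support_threshold=cfg.support_threshold,
            )
        values.append(val)
        valids.append(mask.values)
    return SimilarityStack(np.stack(values), np.stack(valids), cfg.sigma_mm)


def synthesize_pct(
    target_channels: list[Volume],
    db: AtlasDatabase,
    cfg: SynthesisConfig,
    target_fov: ROIMask | None = None,
    transforms: list | None = None,
    registration_config=None,
    head_mask: ROIMask | None = None,
) -> tuple[Volume, ROIMask, dict]:
    """Full pseudo-CT synthesis: register, propagate, rank and fuse.

    ``transforms`` may supply precomputed per-atlas transforms (e.g. from an
    external registration engine); otherwise the built-in baseline registers
    each atlas's MRI channels to the target channels.

    Returns the fused pseudo-CT, the voxel validity mask (where at least one
    atlas contributed evidence) and a provenance log.
    """
    from . import registration as reg  # local import to avoid cycle

    def pick(n_avail: int) -> list[int]:
        # single-contrast modes accept either a matching single channel or a
        # (T1, T2) pair from which the requested contrast is selected
        if cfg.channel_mode == "t1t2":
            if n_avail < 2:
                raise ValueError("channel mode 't1t2' needs two channels")
            return [0, 1]
        if n_avail == 1:
            return [0]
        return [{"t1": 0, "t2": 1}[cfg.channel_mode]]

    tgt_idx = pick(len(target_channels))
    db_idx = pick(db.n_channels)
    tgt = [target_channels[i] for i in tgt_idx]
    grid = tgt[0].grid
    if target_fov is None:
        target_fov = ROIMask(
            np.ones(tgt[0].values.shape, dtype=bool),
            tgt[0].spacing, tgt[0].origin, MaskKind.FOV_VALIDITY,
        )

    log: dict = {"config": cfg.to_dict(), "atlases": []}
    propagated = []
    prop_cts = []
    for i, entry in enumerate(db.entries):
        mov = [entry.mri_channels[j] for j in db_idx]
        if transforms is not None:
            t = transforms[i]
            diag = {"source": "precomputed"}
        else:
            # the MRI channels drive registration over their full FOV
            t, diag = reg.register(mov, tgt, registration_config,
                                   fixed_fov=target_fov)
        chans, fovs = [], None
        for c in mov:
            v, m = reg.apply_transform(c, t, grid, interp="linear")
            chans.append(v)
            fovs = m if fovs is None else fovs.intersect(m)
        # entry.fov_mask marks where the (MRI, CT) pair is valid; the
        # propagated CT carries fill values outside it
        ct_v, ct_m = reg.apply_transform(entry.ct, t, grid, interp="linear",
                                         moving_fov=entry.fov_mask)
        fovs = fovs.intersect(ct_m)
        propagated.append({"channels": chans, "fov": fovs})
        prop_cts.append(ct_v)
        log["atlases"].append({"index": i, "registration": diag,
                               "valid_fraction": float(fovs.values.mean())})

    stack = build_similarity_stack(tgt, target_fov, propagated, cfg)
    ranks = rank_similarities(stack)
    wmap = ranks_to_weights(ranks, cfg.beta, cfg.K)
    pct = fuse_cts(prop_cts, wmap, head_mask=head_mask)
    valid_mask = ROIMask(wmap.valid, grid.spacing, grid.origin, MaskKind.FOV_VALIDITY)
    log["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    return pct, valid_mask, log
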