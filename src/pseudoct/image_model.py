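"""Core volume/mask data model, NIfTI I/O, resampling and CT-based head masking.

All volumes live on axis-aligned grids: voxel-centred, 0-based indices, with
``world = origin + index * spacing`` (mm).  Oblique affines are rejected at
load time; the package fixes one coordinate convention and uses it everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

CT_AIR_HU = -1000.0
CT_FLOOR_HU = -1024.0  # scanner-convention clamp


class Modality(enum.Enum):
    CT_HU = "CT_HU"
    MRI = "MRI"
    PET = "PET"
    MU = "MU"
    LABEL = "LABEL"


class MaskKind(enum.Enum):
    FOV_VALIDITY = "FOV_VALIDITY"
    ANATOMY = "ANATOMY"


@dataclass
class GridSpec:
    """Target grid for resampling: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec requires 3-D shape, spacing and origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape must be at least 1 on all axes")

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d.get("origin", (0, 0, 0))))


@dataclass
class Volume:
    """A 3-D scalar grid with physical spacing/origin and a modality tag."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.MRI

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"Volume must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")
        if self.modality is Modality.CT_HU:
            np.clip(self.values, CT_FLOOR_HU, None, out=self.values)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.spacing, self.origin)

    def same_grid(self, other: "Volume | ROIMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, modality: Modality | None = None) -> "Volume":
        return Volume(values, self.spacing, self.origin, modality or self.modality)


@dataclass
class ROIMask:
    """Binary mask congruent with an associated Volume grid.

    ``FOV_VALIDITY`` masks mark where data are valid (inside the imaged
    field of view); ``ANATOMY`` masks define regions such as the head or a
    reference region.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: MaskKind = MaskKind.ANATOMY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("ROIMask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.spacing, self.origin)

    def intersect(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.values & other.values, self.spacing, self.origin, self.kind)


@dataclass
class AtlasEntry:
    """One co-registered (MRI channels, CT) atlas pair with its FOV mask."""

    mri_channels: list[Volume]
    ct: Volume
    fov_mask: ROIMask

    def __post_init__(self) -> None:
        if not 1 <= len(self.mri_channels) <= 2:
            raise ValueError("AtlasEntry requires 1 or 2 MRI channels")
        for ch in self.mri_channels:
            if not ch.same_grid(self.ct):
                raise ValueError("atlas members must share one grid")
        if self.fov_mask.n_true == 0:
            raise ValueError("atlas FOV mask must be nonempty")

    @property
    def n_channels(self) -> int:
        return len(self.mri_channels)


@dataclass
class AtlasDatabase:
    """Ordered set of co-registered MRI/CT atlas entries."""

    entries: list[AtlasEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entries:
            n = self.entries[0].n_channels
            if any(e.n_channels != n for e in self.entries):
                raise ValueError("all atlas entries must have the same channel count")

    @property
    def n_channels(self) -> int:
        return self.entries[0].n_channels if self.entries else 0

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _check_axis_aligned(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    # Only diagonal (possibly RAS-flipped-free) affines are supported.
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-6 * max(spacing.max(), 1.0)):
        raise ValueError("oblique NIfTI affines are not supported; expected axis-aligned spacing+origin")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError("negative/zero axis scalings are not supported; expected positive diagonal affine")
    return diag, affine[:3, 3]


def load_volume(path, modality: Modality = Modality.MRI) -> Volume:
    """Load an axis-aligned 3-D NIfTI-1 file as a :class:`Volume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got {data.ndim}-D")
    spacing, origin = _check_axis_aligned(img.affine)
    return Volume(np.asarray(data, dtype=np.float64), tuple(spacing), tuple(origin), modality)


def save_volume(vol: Volume, path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def load_mask(path, kind: MaskKind = MaskKind.ANATOMY) -> ROIMask:
    vol = load_volume(path, Modality.LABEL)
    return ROIMask(vol.values > 0.5, vol.spacing, vol.origin, kind)


def save_mask(mask: ROIMask, path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = mask.spacing
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Resampling


def _default_fill(modality: Modality) -> float:
    return CT_AIR_HU if modality is Modality.CT_HU else 0.0


def resample(
    vol: Volume,
    target: GridSpec,
    interp: str = "linear",
    fill_value: float | None = None,
) -> tuple[Volume, ROIMask]:
    """Resample ``vol`` onto ``target``.

    Returns the resampled volume together with a FOV_VALIDITY mask that is
    False wherever the sample point falls outside the source grid; those
    voxels take ``fill_value`` (−1000 for CT, 0 otherwise by default).
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if vol.modality is Modality.LABEL and interp != "nearest":
        raise ValueError("LABEL volumes require nearest-neighbour interpolation")
    if fill_value is None:
        fill_value = _default_fill(vol.modality)

    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in target.shape], indexing="ij")
    coords = []
    inside = np.ones(target.shape, dtype=bool)
    for ax in range(3):
        world = target.origin[ax] + idx[ax] * target.spacing[ax]
        src = (world - vol.origin[ax]) / vol.spacing[ax]
        coords.append(src)
        n = vol.values.shape[ax]
        inside &= (src >= -1e-9) & (src <= n - 1 + 1e-9)

    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(
        vol.values, np.stack(coords), order=order, mode="constant", cval=fill_value
    )
    out[~inside] = fill_value
    res = Volume(out, target.spacing, target.origin, vol.modality)
    validity = ROIMask(inside, target.spacing, target.origin, MaskKind.FOV_VALIDITY)
    return res, validity


# ---------------------------------------------------------------------------
# Head masking


def head_mask_from_ct(
    ct: Volume, threshold_hu: float = -500.0, closing_radius: int = 2
) -> ROIMask:
    """Segment the head from background on a CT volume.

    Threshold at ``threshold_hu``, keep the largest connected component and
    close small gaps (air sinuses, noise) with a morphological closing of the
    configured radius.
    """
    if ct.modality is not Modality.CT_HU:
        raise ValueError("head_mask_from_ct requires a CT_HU volume")
    fg = ct.values > threshold_hu
    if not fg.any():
        raise ValueError("empty head mask: volume contains only air")
    labels, n = ndimage.label(fg)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    if closing_radius > 0:
        struct = _ball(closing_radius)
        fg = ndimage.binary_closing(fg, structure=struct)
        fg = ndimage.binary_fill_holes(fg)
    return ROIMask(fg, ct.spacing, ct.origin, MaskKind.ANATOMY)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (x**2 + y**2 + z**2) <= r**2


def apply_mask(vol: Volume, mask: ROIMask, fill_value: float | None = None) -> Volume:
    if fill_value is None:
        fill_value = _default_fill(vol.modality)
    out = vol.values.copy()
    out[~mask.values] = fill_value
    return replace(vol, values=out)
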