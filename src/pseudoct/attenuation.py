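"""CT (HU) to 511 keV attenuation-map (cm^-1) conversion.

A piecewise-linear table maps Hounsfield units to linear attenuation
coefficients; the default is the conventional bilinear curve with a break
at water (0 HU): an air-to-water segment and a shallower water-to-bone
segment reflecting the different energy scaling of bone at a 120 kVp
acquisition.  The mu-map is then smoothed with a Gaussian approximating the
PET scanner point spread function (sigma 2 voxels by default) and resampled
onto the PET grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import GridSpec, Modality, Volume, resample

#: water at 511 keV, cm^-1
MU_WATER = 0.096
#: default bone slope above water for a 120 kVp acquisition, cm^-1 per HU
BONE_SLOPE = 5.1e-5

DEFAULT_BREAKPOINTS = (
    (-1000.0, 0.0),
    (0.0, MU_WATER),
    (3000.0, MU_WATER + 3000.0 * BONE_SLOPE),
)


@dataclass
class HUToMuTable:
    """Piecewise-linear HU -> mu mapping defined by (HU, mu) breakpoints.

    Continuous by construction, must be non-decreasing, and anchored so that
    air (-1000 HU) maps to 0.  HU beyond the last breakpoint extrapolates
    with the final slope; output is clamped at 0 below.
    """

    breakpoints: tuple = DEFAULT_BREAKPOINTS

    def __post_init__(self) -> None:
        pts = sorted((float(h), float(m)) for h, m in self.breakpoints)
        if len(pts) < 2:
            raise ValueError("need at least two breakpoints")
        hu = np.array([p[0] for p in pts])
        mu = np.array([p[1] for p in pts])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("breakpoint HU values must be strictly ascending")
        if np.any(np.diff(mu) < 0):
            raise ValueError("HU->mu table must be non-decreasing")
        self._hu = hu
        self._mu = mu
        self._last_slope = (mu[-1] - mu[-2]) / (hu[-1] - hu[-2])
        self._first_slope = (mu[1] - mu[0]) / (hu[1] - hu[0])

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=np.float64)
        mu = np.interp(hu, self._hu, self._mu)
        above = hu > self._hu[-1]
        if np.any(above):
            mu = np.where(above, self._mu[-1] + (hu - self._hu[-1]) * self._last_slope, mu)
        below = hu < self._hu[0]
        if np.any(below):
            mu = np.where(below, self._mu[0] + (hu - self._hu[0]) * self._first_slope, mu)
        return np.clip(mu, 0.0, None)

    def to_dict(self) -> dict:
        return {"breakpoints": [[h, m] for h, m in zip(self._hu, self._mu)]}

    @classmethod
    def from_dict(cls, d: dict) -> "HUToMuTable":
        return cls(tuple((h, m) for h, m in d["breakpoints"]))


@dataclass
class MuMapConfig:
    table: HUToMuTable = field(default_factory=HUToMuTable)
    psf_sigma_voxels: float = 2.0
    pet_grid: GridSpec | None = None  # None = keep the CT grid

    def __post_init__(self) -> None:
        if self.psf_sigma_voxels < 0:
            raise ValueError("psf_sigma_voxels must be nonnegative")


def hu_to_mu(ct: Volume, table: HUToMuTable | None = None) -> Volume:
    """Voxelwise piecewise-linear conversion of a CT to a 511 keV mu-map."""
    if ct.modality is not Modality.CT_HU:
        raise ValueError("hu_to_mu requires a CT_HU volume")
    table = table or HUToMuTable()
    return Volume(table(ct.values), ct.spacing, ct.origin, Modality.MU)


def make_mu_map(ct: Volume, cfg: MuMapConfig | None = None) -> Volume:
    """HU->mu conversion, PSF smoothing, and resampling to the PET grid.

    Smoothing is performed on the CT grid (sigma in CT voxel units) before
    resampling, matching the order convert -> smooth -> resample.
    """
    cfg = cfg or MuMapConfig()
    mu = hu_to_mu(ct, cfg.table)
    vals = mu.values
    if cfg.psf_sigma_voxels > 0:
        vals = ndimage.gaussian_filter(vals, cfg.psf_sigma_voxels, mode="nearest")
    mu = Volume(np.clip(vals, 0.0, None), ct.spacing, ct.origin, Modality.MU)
    if cfg.pet_grid is not None:
        mu, _ = resample(mu, cfg.pet_grid, interp="linear", fill_value=0.0)
        mu = Volume(np.clip(mu.values, 0.0, None), mu.spacing, mu.origin, Modality.MU)
    return mu
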