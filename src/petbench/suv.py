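"""SUV quantitation: decay correction, concentration-to-SUV conversion and
per-lesion SUV statistics (mean, max, peak) with lesion size.

The body-weight SUV used throughout is

    SUV = C [kBq/ml] * weight [g] / decayed dose [kBq]

with tissue density taken as 1 g/ml, so a voxel's SUV is its concentration
normalized by the average whole-body concentration had the decayed dose been
distributed uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import AcquisitionMeta, PETVolume

#: Sphere volume used for SUVpeak, mm^3 (1.0 cm^3).
PEAK_SPHERE_VOLUME_MM3 = 1000.0

#: Radius of the 1 cm^3 SUVpeak sphere, mm (diameter ~= 12.4 mm).
PEAK_SPHERE_RADIUS_MM = (3.0 * PEAK_SPHERE_VOLUME_MM3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def decayed_dose(meta: AcquisitionMeta) -> float:
    """Injected activity decay-corrected to scan start, in MBq.

    Returns ``total_dose * 2**(-delay / half_life)``.
    """
    if meta.delay < 0:
        raise ValueError("delay must be non-negative")
    return float(meta.total_dose * 2.0 ** (-meta.delay / meta.half_life))


@dataclass
class SUVVolume:
    """Dimensionless SUV volume on the source grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("SUVVolume requires a 3D array")


@dataclass(frozen=True)
class ROIStats:
    """Per-lesion SUV summary.

    ``max_length`` is the largest physical extent of the lesion in mm (see
    :func:`suv_stats` for the two supported definitions).
    """

    lesion_id: int
    n_voxels: int
    max_length: float
    suv_mean: float
    suv_max: float
    suv_peak: float

    def __post_init__(self) -> None:
        # suv_max >= suv_mean holds for any mask; suv_max >= suv_peak holds
        # whenever the lesion is a local maximum (the sphere may reach outside
        # the mask, so a hotter neighbor can formally break it — tolerated).
        if self.suv_max < self.suv_mean - 1e-9:
            raise ValueError("suv_max must dominate suv_mean")
        if not self.max_length > 0:
            raise ValueError("max_length must be strictly positive")


def to_suv(vol: PETVolume) -> SUVVolume:
    """Convert a concentration volume (kBq/ml) to SUV."""
    dose_kbq = decayed_dose(vol.meta) * 1000.0
    weight_g = vol.meta.weight * 1000.0
    if dose_kbq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be strictly positive")
    return SUVVolume(
        values=vol.values * (weight_g / dose_kbq),
        spacing=vol.spacing,
        meta=vol.meta,
    )


def sphere_offsets(spacing: tuple[float, float, float],
                   radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> np.ndarray:
    """Integer voxel offsets whose centers fall inside a sphere of
    ``radius_mm`` under anisotropic ``spacing``.  Shape (n, 3)."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    dist2 = ((offs * np.asarray(spacing)) ** 2).sum(axis=1)
    return offs[dist2 <= radius_mm**2]


def _sphere_footprint(spacing: tuple[float, float, float],
                      radius_mm: float) -> np.ndarray:
    offs = sphere_offsets(spacing, radius_mm)
    half = offs.max(axis=0)
    foot = np.zeros(2 * half + 1, dtype=bool)
    foot[tuple((offs + half).T)] = True
    return foot


def peak_map(suv: SUVVolume, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> np.ndarray:
    """Sphere-mean SUV at every voxel (fast path for SUVpeak).

    Sphere voxels beyond the grid boundary are excluded from the mean, so the
    map agrees with a brute-force enumeration that clips the sphere to the
    grid.
    """
    foot = _sphere_footprint(suv.spacing, radius_mm).astype(np.float64)
    sums = ndimage.correlate(suv.values, foot, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(suv.values), foot,
                               mode="constant", cval=0.0)
    return sums / counts


def mask_max_length(mask: np.ndarray, spacing: tuple[float, float, float],
                    exact: bool = False) -> float:
    """Largest physical extent of a binary mask in mm.

    Default: largest axis-aligned bounding-box extent, counting each voxel at
    its full spacing.  With ``exact=True``: maximum pairwise voxel-center
    distance plus one mean voxel diagonal contribution is *not* added — the
    raw center-to-center Feret-style distance is returned (suited to small
    lesions where the bounding box overestimates oblique extents).
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask has no length")
    sp = np.asarray(spacing)
    if not exact:
        extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * sp
        return float(extent.max())
    pts = idx * sp
    # pairwise distances; masks this is used for are small
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    d = float(np.sqrt(d2.max()))
    return d if d > 0 else float(sp.min())


def suv_stats(suv: SUVVolume, mask: np.ndarray, lesion_id: int = 1,
              exact_length: bool = False,
              _peak: np.ndarray | None = None) -> ROIStats:
    """SUVmean/max/peak and maximum length over one lesion mask.

    SUVpeak is the maximum, over candidate centers restricted to the mask, of
    the mean SUV inside a 1.0 cm^3 voxelized sphere centered at the candidate;
    sphere voxels are drawn from the whole volume and may extend beyond the
    mask.  ``_peak`` lets callers pass a precomputed :func:`peak_map`.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != suv.values.shape:
        raise ValueError("mask grid does not match the SUV volume")
    if not mask.any():
        raise ValueError("empty mask: no lesion voxels")
    vals = suv.values[mask]
    pk = peak_map(suv) if _peak is None else _peak
    return ROIStats(
        lesion_id=lesion_id,
        n_voxels=int(mask.sum()),
        max_length=mask_max_length(mask, suv.spacing, exact=exact_length),
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
        suv_peak=float(pk[mask].max()),
    )
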