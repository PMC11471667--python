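"""Core data containers for paired low-time / full-time PET studies.

Axis convention is (slice, row, col) with voxel centers at ``index * spacing``
(0-based).  Activity concentrations are stored in kBq/ml as float arrays of at
least 32-bit precision; label volumes are non-negative integers with 0 meaning
background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Acquisition times (seconds per bed position) used by the study protocol.
PROTOCOL_TIMES = (30, 60, 90)

#: Default geometry: 256 x 256 axial frames, 3.27 mm slices, 2.73 mm pixels.
DEFAULT_SPACING = (3.27, 2.73, 2.73)

#: Injected activity per unit body weight (MBq/kg).
DOSE_PER_KG = 7.0

#: 18F half-life in seconds.
F18_HALF_LIFE_S = 6586.2


@dataclass(frozen=True)
class AcquisitionMeta:
    """Scan metadata needed for SUV quantitation.

    Parameters
    ----------
    weight:
        Patient body weight in kg.
    total_dose:
        Total injected activity in MBq (at injection time).
    half_life:
        Tracer half-life in seconds.
    delay:
        Time from injection to scan start in seconds.
    time_per_bed:
        Acquisition duration per bed position in seconds.
    """

    weight: float
    total_dose: float
    half_life: float = F18_HALF_LIFE_S
    delay: float = 0.0
    time_per_bed: float = 90.0

    def __post_init__(self) -> None:
        for name in ("weight", "total_dose", "half_life", "time_per_bed"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    def with_time(self, time_per_bed: float) -> "AcquisitionMeta":
        return replace(self, time_per_bed=time_per_bed)

    def to_dict(self) -> dict:
        return {
            "weight_kg": self.weight,
            "total_dose_MBq": self.total_dose,
            "half_life_s": self.half_life,
            "delay_s": self.delay,
            "time_per_bed_s": self.time_per_bed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            weight=d["weight_kg"],
            total_dose=d["total_dose_MBq"],
            half_life=d["half_life_s"],
            delay=d["delay_s"],
            time_per_bed=d["time_per_bed_s"],
        )


@dataclass(frozen=True)
class Ellipsoid:
    """Organ-scale uptake region: axis-aligned ellipsoid in physical mm."""

    center: tuple[float, float, float]  # mm, (slice, row, col) axes
    semi_axes: tuple[float, float, float]  # mm
    suv: float

    def __post_init__(self) -> None:
        if not self.suv > 0:
            raise ValueError("target SUV must be strictly positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be strictly positive")


@dataclass(frozen=True)
class Sphere:
    """Lesion: sphere given by center (mm) and diameter (mm)."""

    center: tuple[float, float, float]
    diameter: float
    suv: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("lesion diameter must be strictly positive")
        if not self.suv > 0:
            raise ValueError("target SUV must be strictly positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and scene description for one synthetic patient."""

    shape: tuple[int, int, int] = (48, 256, 256)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    organs: tuple[Ellipsoid, ...] = ()
    lesions: tuple[Sphere, ...] = ()
    sensitivity: float = 0.01  # detector sensitivity eta, dimensionless
    psf_fwhm_mm: float = 5.0  # isotropic Gaussian PSF
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1):
            raise ValueError("sensitivity must lie in (0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("shape must be strictly positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class PETVolume:
    """3D activity-concentration volume (kBq/ml) with acquisition metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PETVolume requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")
        if np.any(self.values < 0):
            raise ValueError("concentration values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray) -> "PETVolume":
        """New volume with the same geometry/meta and different values."""
        return PETVolume(values=values, spacing=self.spacing, meta=self.meta)


@dataclass
class PairedStudy:
    """Co-registered acquisitions of one session at several bed times.

    All member volumes share grid, spacing and metadata except
    ``time_per_bed``; the lesion and organ label volumes live on the same
    grid (0 = background, lesions enumerated in scene order from 1).
    """

    volumes: dict[int, PETVolume]
    lesion_labels: np.ndarray
    organ_labels: np.ndarray
    meta: AcquisitionMeta
    spacing: tuple[float, float, float]
    patient_id: str = "phantom"

    def __post_init__(self) -> None:
        self.lesion_labels = np.asarray(self.lesion_labels)
        self.organ_labels = np.asarray(self.organ_labels)
        for lab in (self.lesion_labels, self.organ_labels):
            if not np.issubdtype(lab.dtype, np.integer):
                raise ValueError("label volumes must be integer typed")
            if lab.min() < 0:
                raise ValueError("label volumes must be non-negative")
        shapes = {v.shape for v in self.volumes.values()}
        shapes |= {self.lesion_labels.shape, self.organ_labels.shape}
        if len(shapes) != 1:
            raise ValueError("all volumes and labels must share one grid")

    def __getitem__(self, time_s: int) -> PETVolume:
        return self.volumes[time_s]

    @property
    def times(self) -> Sequence[int]:
        return sorted(self.volumes)
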