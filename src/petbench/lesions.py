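"""Lesion-level SUV agreement pipeline.

Masks are obtained from a pluggable provider (ground truth, SUV threshold,
or an external mask file), split into 3D connected components, filtered by
size and uptake, and summarized as paired FT/denoised ROI statistics.

Filtering rule: a component is *excluded* when its maximum length is less
than 7 mm or its mean SUV (on the full-time volume) is less than 0.5;
borderline equality retains the lesion.  The ROI is segmented once on the
full-time volume and the identical voxel set is reused on the denoised
volume, so paired statistics always compare the same region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import io as pio
from .metrics import AgreementReport, agreement_from_pairs
from .suv import ROIStats, SUVVolume, mask_max_length, peak_map, suv_stats, to_suv
from .types import PairedStudy, PETVolume

#: Exclusion thresholds: max length < 7 mm or mean SUV < 0.5 drops a lesion.
MIN_MAX_LENGTH_MM = 7.0
MIN_MEAN_SUV = 0.5

#: Default SUV threshold for the automatic (download-free) mask provider.
DEFAULT_SUV_THRESHOLD = 2.5


@dataclass(frozen=True)
class MaskProvider:
    """Source of the binary tumor mask on the study grid.

    strategy:
        ``ground_truth`` — phantom lesion labels > 0;
        ``suv_threshold`` — voxels of the FT SUV volume above ``threshold``;
        ``external_mask_file`` — integer-label NIfTI supplied by an outside
        segmenter, binarized as labels > 0.
    """

    strategy: str = "ground_truth"
    threshold: float = DEFAULT_SUV_THRESHOLD
    mask_path: str | None = None

    def __call__(self, study: PairedStudy, suv_ft: SUVVolume) -> np.ndarray:
        if self.strategy == "ground_truth":
            return study.lesion_labels > 0
        if self.strategy == "suv_threshold":
            return suv_ft.values > self.threshold
        if self.strategy == "external_mask_file":
            if self.mask_path is None:
                raise ValueError("external_mask_file requires mask_path")
            values, _ = pio.load_volume(self.mask_path)
            if values.shape != suv_ft.values.shape:
                raise ValueError("external mask does not match the study grid")
            return np.asarray(values) > 0
        raise ValueError(f"unknown mask strategy {self.strategy!r}")


@dataclass
class LesionTable:
    """Paired per-lesion statistics on identical voxel sets."""

    rows: list[tuple[int, ROIStats, ROIStats]] = field(default_factory=list)

    def pairs(self, statistic: str) -> list[tuple[float, float]]:
        return [(getattr(ft, statistic), getattr(den, statistic))
                for _, ft, den in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def connected_components(mask: np.ndarray,
                         connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label the 3D connected components of a binary mask.

    Components are labeled 1..K in deterministic first-voxel raster order.
    ``connectivity`` is 26 (default: corners touch) or 6 (faces only).
    """
    mask = np.asarray(mask)
    if not (np.issubdtype(mask.dtype, np.bool_)
            or set(np.unique(mask)) <= {0, 1}):
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels.astype(np.int32), 0
    # relabel by raster order of each component's first voxel
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    np.minimum.at(first, flat[idx], idx)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[labels], n


def filter_lesions(labels: np.ndarray, suv_ft: SUVVolume,
                   min_length_mm: float = MIN_MAX_LENGTH_MM,
                   min_mean_suv: float = MIN_MEAN_SUV,
                   exact_length: bool = False) -> list[int]:
    """Ids of components surviving the size/uptake exclusion filters.

    Retained iff ``max_length >= min_length_mm`` and
    ``mean SUV >= min_mean_suv`` on the full-time volume.
    """
    labels = np.asarray(labels)
    kept = []
    for lid in range(1, int(labels.max(initial=0)) + 1):
        mask = labels == lid
        if not mask.any():
            continue
        length = mask_max_length(mask, suv_ft.spacing, exact=exact_length)
        mean = float(suv_ft.values[mask].mean())
        if length >= min_length_mm and mean >= min_mean_suv:
            kept.append(lid)
    return kept


def paired_roi_stats(ft: PETVolume, den: PETVolume, labels: np.ndarray,
                     lesion_ids=None, exact_length: bool = False) -> LesionTable:
    """ROI statistics on ``to_suv(ft)`` and ``to_suv(den)`` over identical
    voxel sets for each retained lesion."""
    labels = np.asarray(labels)
    if not (ft.shape == den.shape == labels.shape):
        raise ValueError("volumes and labels are not on one grid")
    suv_ft = to_suv(ft)
    suv_den = to_suv(den)
    pk_ft = peak_map(suv_ft)
    pk_den = peak_map(suv_den)
    if lesion_ids is None:
        lesion_ids = [lid for lid in range(1, int(labels.max(initial=0)) + 1)
                      if (labels == lid).any()]
    table = LesionTable()
    for lid in lesion_ids:
        mask = labels == lid
        table.rows.append((
            int(lid),
            suv_stats(suv_ft, mask, lid, exact_length, _peak=pk_ft),
            suv_stats(suv_den, mask, lid, exact_length, _peak=pk_den),
        ))
    return table


def agreement(table: LesionTable, statistic: str = "suv_max") -> AgreementReport:
    """Bland-Altman and 1-R^2 summary for one SUV statistic."""
    if statistic not in ("suv_max", "suv_peak", "suv_mean"):
        raise ValueError(f"unsupported statistic {statistic!r}")
    if len(table) == 0:
        raise ValueError("no evaluable lesions in the table")
    return agreement_from_pairs(statistic, table.pairs(statistic))


def evaluate_lesions(study: PairedStudy, den: PETVolume, ft_time: int = 90,
                     provider: MaskProvider | None = None,
                     connectivity: int = 26) -> dict:
    """Full pipeline: mask, components, filters, paired stats, agreement.

    Returns a dict with the lesion table and one AgreementReport per SUV
    statistic (``suv_max`` and ``suv_peak``); empty-table studies yield
    ``None`` reports with a zero lesion count.
    """
    provider = provider or MaskProvider()
    ft = study[ft_time]
    suv_ft = to_suv(ft)
    mask = provider(study, suv_ft)
    labels, _ = connected_components(mask, connectivity=connectivity)
    kept = filter_lesions(labels, suv_ft)
    table = paired_roi_stats(ft, den, labels, lesion_ids=kept)
    out: dict = {"n_lesions": len(table), "table": table}
    for stat in ("suv_max", "suv_peak"):
        out[stat] = agreement(table, stat) if len(table) else None
    return out
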