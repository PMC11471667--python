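"""2D similarity metrics and agreement statistics for denoising evaluation.

Per-slice discrepancy is measured by RMSE and by ISSIM = 1 - SSIM (more
convenient than SSIM when all values crowd above 0.9).  Improvements are
summarized by the relative metric

    rel(m) = 100 * (1 - m(denoised, FT) / m(LT, FT))   [%]

which is 0% for an identity denoiser, 100% for perfect restoration and
negative when denoising hurts.  Lesion-level SUV agreement uses the
Bland-Altman median bias and interquartile range (robust to outliers) plus
1 - R^2 with R^2 the squared Pearson correlation of the paired values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .types import PETVolume


@dataclass(frozen=True)
class SliceMetrics:
    slice_index: int
    rmse: float
    issim: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("RMSE is non-negative")
        if not (0.0 <= self.issim <= 2.0):
            raise ValueError("ISSIM = 1 - SSIM lies in [0, 2]")


@dataclass(frozen=True)
class RelativeMetrics:
    """Relative improvement in percent; each <= 100, may be negative."""

    rel_rmse: float
    rel_issim: float

    def __post_init__(self) -> None:
        if self.rel_rmse > 100.0 + 1e-9 or self.rel_issim > 100.0 + 1e-9:
            raise ValueError("relative metrics cannot exceed 100%")


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of one SUV statistic between FT and denoised volumes."""

    statistic: str
    pairs: tuple[tuple[float, float], ...]  # (FT value, denoised value)
    median_bias: float
    iqr: float
    one_minus_r2: float

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("IQR is non-negative")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference over all pixels of two same-shape slices."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def issim(a: np.ndarray, b: np.ndarray, data_range: float,
          win_size: int = 7) -> float:
    """1 - SSIM with a uniform window (K1=0.01, K2=0.03, scikit-image
    parameterization)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range <= 0:
        raise ValueError("data_range must be strictly positive")
    if win_size > min(a.shape):
        raise ValueError("SSIM window larger than the slice")
    s = structural_similarity(a, b, data_range=data_range, win_size=win_size,
                              gaussian_weights=False, K1=0.01, K2=0.03)
    return float(1.0 - s)


def relative_improvement(metric_lt_vs_ft: float,
                         metric_den_vs_ft: float) -> float:
    """Percent reduction of a discrepancy metric attributable to denoising."""
    if metric_lt_vs_ft <= 0:
        raise ValueError(
            "reference discrepancy is zero: LT already identical to FT")
    return 100.0 * (1.0 - metric_den_vs_ft / metric_lt_vs_ft)


def slice_metrics(x: np.ndarray, ref: np.ndarray,
                  data_range: float) -> list[SliceMetrics]:
    if x.shape != ref.shape:
        raise ValueError("shape mismatch")
    return [
        SliceMetrics(i, rmse(x[i], ref[i]), issim(x[i], ref[i], data_range))
        for i in range(x.shape[0])
    ]


def volume_metrics(lt: PETVolume, den: PETVolume, ft: PETVolume,
                   data_range: float | None = None,
                   per_slice_relative: bool = False):
    """Slice-averaged absolute metrics and the derived relative metrics.

    RMSE and ISSIM are computed per axial slice against the full-time volume
    for both the raw low-time input and the denoised output, averaged over
    slices, and converted to relative improvements.  ``data_range`` defaults
    to the full-time volume maximum.  With ``per_slice_relative`` the relative
    metric is formed per slice and then averaged instead (non-default
    aggregation).

    Returns ``(absolute, relative)`` where ``absolute`` is a dict with keys
    ``rmse_lt, rmse_den, issim_lt, issim_den``.
    """
    if not (lt.shape == den.shape == ft.shape):
        raise ValueError("volumes are not co-registered")
    dr = float(ft.values.max()) if data_range is None else float(data_range)
    m_lt = slice_metrics(lt.values, ft.values, dr)
    m_den = slice_metrics(den.values, ft.values, dr)
    absolute = {
        "rmse_lt": float(np.mean([m.rmse for m in m_lt])),
        "rmse_den": float(np.mean([m.rmse for m in m_den])),
        "issim_lt": float(np.mean([m.issim for m in m_lt])),
        "issim_den": float(np.mean([m.issim for m in m_den])),
    }
    if per_slice_relative:
        rel = RelativeMetrics(
            rel_rmse=float(np.mean([
                relative_improvement(a.rmse, b.rmse)
                for a, b in zip(m_lt, m_den)])),
            rel_issim=float(np.mean([
                relative_improvement(a.issim, b.issim)
                for a, b in zip(m_lt, m_den)])),
        )
    else:
        rel = RelativeMetrics(
            rel_rmse=relative_improvement(absolute["rmse_lt"],
                                          absolute["rmse_den"]),
            rel_issim=relative_improvement(absolute["issim_lt"],
                                           absolute["issim_den"]),
        )
    return absolute, rel


def bland_altman(pairs) -> tuple[float, float]:
    """Median bias and IQR of the differences (denoised - FT).

    Quartiles use linear interpolation.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.size == 0:
        raise ValueError("no pairs")
    d = pairs[:, 1] - pairs[:, 0]
    q1, q3 = np.percentile(d, [25.0, 75.0], method="linear")
    return float(np.median(d)), float(q3 - q1)


def one_minus_r2(pairs) -> float:
    """1 minus the squared Pearson correlation of the paired values."""
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.shape[0] < 2:
        raise ValueError("need at least two pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r * r)


def agreement_from_pairs(statistic: str, pairs) -> AgreementReport:
    """Bundle Bland-Altman and correlation summaries for one statistic."""
    bias, iqr = bland_altman(pairs)
    try:
        omr2 = one_minus_r2(pairs)
    except ValueError:
        # identical/degenerate series: perfectly collinear pairs agree fully
        pairs_arr = np.asarray(pairs, dtype=np.float64)
        if np.allclose(pairs_arr[:, 0] - pairs_arr[:, 1],
                       pairs_arr[0, 0] - pairs_arr[0, 1]):
            omr2 = 0.0
        else:
            raise
    return AgreementReport(statistic=statistic,
                           pairs=tuple(map(tuple, np.asarray(pairs, float))),
                           median_bias=bias, iqr=iqr, one_minus_r2=omr2)
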