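"""M-mode echo analysis: dimensions, ejection fraction, remodeling rates.

``extract_dimensions`` reduces a multi-beat M-mode trace to mean diastolic and
systolic inner diameters and wall thicknesses.  ``ejection_fraction``
implements the cylindrical-slice EF estimator: the M-mode image is treated as
a cross-section through a cylindrical basal LV slice whose wall tissue is
incompressible, so the slice height extends as the wall cross-section thins,

    EF = 1 − (r_sys/r_dia)² · [(r_dia+LVWT_dia)² − r_dia²]
                              / [(r_sys+LVWT_sys)² − r_sys²].

The final denominator term is written here with r_sys², which is what the
tissue-volume-conservation argument requires; the variant with r_dia² that
sometimes appears in print is available via ``formula="printed"``.

``remodeling_rate`` is the normalized rate of change R[y] = ⟨dy/dt⟩ / y(t=0)
over the observation weeks, with ⟨dy/dt⟩ the ordinary least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .cohort import MModeTrace
from .errors import (
    ExtractionFailureError,
    InsufficientDataError,
    InvalidGeometryError,
    InvalidParameterError,
)

__all__ = [
    "EchoDimensions",
    "LongitudinalSeries",
    "ComparisonReport",
    "extract_dimensions",
    "ejection_fraction",
    "ejection_fraction_volume_oracle",
    "remodeling_rate",
    "cohort_compare",
]


@dataclass(frozen=True)
class EchoDimensions:
    """Per-recording averaged LV dimensions (mm)."""

    LVD_dia: float
    LVD_sys: float
    LVWT_dia: float
    LVWT_sys: float
    n_beats_averaged: int

    def __post_init__(self):
        vals = (self.LVD_dia, self.LVD_sys, self.LVWT_dia, self.LVWT_sys)
        if not all(np.isfinite(vals)):
            raise InvalidGeometryError("dimensions must be finite")
        if not (self.LVD_dia > self.LVD_sys > 0):
            raise InvalidGeometryError(
                f"need LVD_dia > LVD_sys > 0, got {self.LVD_dia}, {self.LVD_sys}")
        if not (self.LVWT_sys > self.LVWT_dia > 0):
            raise InvalidGeometryError(
                f"need LVWT_sys > LVWT_dia > 0 (systolic thickening), got "
                f"{self.LVWT_sys}, {self.LVWT_dia}")


@dataclass(frozen=True)
class LongitudinalSeries:
    """A quantity observed at increasing times (weeks)."""

    weeks: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weeks, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.shape != v.shape or w.ndim != 1:
            raise InvalidParameterError("weeks and values must match in shape")
        if w.size < 2:
            raise InsufficientDataError("need at least two observation points")
        if np.any(np.diff(w) <= 0):
            raise InvalidParameterError("weeks must be strictly increasing")
        object.__setattr__(self, "weeks", w)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ComparisonReport:
    """Two-group comparison (means, sds, Welch two-sided p)."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    # Savitzky-Golay with polyorder 2 is exact on locally quadratic extrema,
    # so smoothing does not bias the within-beat max/min of the waveforms.
    window = min(window, x.size if x.size % 2 == 1 else x.size - 1)
    if window < 5:
        return x
    return signal.savgol_filter(x, window_length=window, polyorder=2)


def extract_dimensions(
    trace: MModeTrace,
    expected_period_ms: float = 200.0,
    smooth_window_ms: float = 31.0,
) -> EchoDimensions:
    """Extract per-beat averaged LV dimensions from an M-mode trace.

    Beats are detected as peaks of the (smoothed) inner-diameter signal with a
    minimum separation of half the nominal period.  Within each beat the
    diastolic values are the maxima of the inner diameter (with the concurrent
    mean of the two wall thicknesses) and the systolic values the minima;
    results are averaged across all complete beats.
    """
    dt = float(trace.time[1] - trace.time[0])
    window = int(round(smooth_window_ms / dt))
    if window % 2 == 0:
        window += 1
    d = _smooth(trace.inner_diameter, window)
    w = _smooth(0.5 * (trace.near_wall_thickness + trace.far_wall_thickness),
                window)

    span = float(d.max() - d.min())
    if span < 1e-6:   # mm; flat to numerical precision
        raise InsufficientDataError("flat trace: no beats detectable")
    peaks, _ = signal.find_peaks(
        d,
        distance=max(1, int(round(0.5 * expected_period_ms / dt))),
        prominence=0.25 * span,
    )
    # Endpoint diastolic extremes are not detected by find_peaks; count them
    # in when the signal starts/ends near its maximum so no beat is lost.
    ends = []
    for idx in (0, d.size - 1):
        if d[idx] >= d.max() - 0.1 * span:
            ends.append(idx)
    peaks = np.unique(np.concatenate([peaks, np.array(ends, dtype=int)]))
    if peaks.size < 2:
        raise InsufficientDataError(
            f"only {peaks.size} diastolic peaks found; need >= 2 complete beats")

    dia_d, dia_w, sys_d, sys_w = [], [], [], []
    for i0, i1 in zip(peaks[:-1], peaks[1:]):
        seg_d = d[i0:i1 + 1]
        seg_w = w[i0:i1 + 1]
        j_max = int(np.argmax(seg_d))
        j_min = int(np.argmin(seg_d))
        dia_d.append(seg_d[j_max])
        dia_w.append(seg_w[j_max])
        sys_d.append(seg_d[j_min])
        sys_w.append(seg_w[j_min])

    dims = dict(
        LVD_dia=float(np.mean(dia_d)),
        LVD_sys=float(np.mean(sys_d)),
        LVWT_dia=float(np.mean(dia_w)),
        LVWT_sys=float(np.mean(sys_w)),
    )
    try:
        return EchoDimensions(n_beats_averaged=len(dia_d), **dims)
    except InvalidGeometryError as exc:
        raise ExtractionFailureError(
            f"non-physical averaged dimensions: {dims}") from exc


def ejection_fraction(dims: EchoDimensions, formula: str = "corrected") -> float:
    """Cylindrical-slice ejection fraction from averaged M-mode dimensions.

    ``formula='corrected'`` (default) uses the tissue-volume-conservation
    denominator (r_sys+LVWT_sys)² − r_sys²; ``'printed'`` retains the r_dia²
    variant for comparison.
    """
    r_d = dims.LVD_dia / 2.0
    r_s = dims.LVD_sys / 2.0
    num = (r_d + dims.LVWT_dia) ** 2 - r_d**2
    if formula == "corrected":
        den = (r_s + dims.LVWT_sys) ** 2 - r_s**2
    elif formula == "printed":
        den = (r_s + dims.LVWT_sys) ** 2 - r_d**2
    else:
        raise InvalidParameterError(f"unknown formula {formula!r}")
    if den <= 0:
        raise InvalidGeometryError("non-positive denominator in EF estimator")
    return 1.0 - (r_s / r_d) ** 2 * num / den


def ejection_fraction_volume_oracle(dims: EchoDimensions) -> float:
    """Direct cylinder-volume EF: build both cylinders explicitly.

    The annular wall cross-section fixes the height ratio through tissue
    incompressibility (h_sys/h_dia = A_dia/A_sys), then EF = 1 − V_sys/V_dia.
    Used as the independent cross-check of :func:`ejection_fraction`.
    """
    r_d = dims.LVD_dia / 2.0
    r_s = dims.LVD_sys / 2.0
    area_d = np.pi * ((r_d + dims.LVWT_dia) ** 2 - r_d**2)
    area_s = np.pi * ((r_s + dims.LVWT_sys) ** 2 - r_s**2)
    if area_s <= 0:
        raise InvalidGeometryError("non-positive systolic wall cross-section")
    h_d = 1.0
    h_s = h_d * area_d / area_s
    v_d = np.pi * r_d**2 * h_d
    v_s = np.pi * r_s**2 * h_s
    return 1.0 - v_s / v_d


def remodeling_rate(series: LongitudinalSeries) -> float:
    """Normalized remodeling rate R[y] = OLS-slope(y vs t) / y(t=0), per week."""
    y0 = series.values[0]
    if y0 == 0:
        raise ZeroDivisionError("y(t=0) = 0: normalized rate undefined")
    slope = np.polyfit(series.weeks, series.values, 1)[0]
    return float(slope / y0)


def cohort_compare(group_a, group_b) -> ComparisonReport:
    """Welch's two-sample two-sided t-test between two groups of rates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonReport(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
    )
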