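"""Intracellular calcium transients.

The contraction model is driven by a periodic free-calcium concentration
[Ca2+](t) characterized by its diastolic level DCa and peak level PCa.  The
measured transients behind the study are not public, so this module provides
an analytic two-phase waveform with exactly those extrema — a half-cosine rise
from DCa to PCa over ``time_to_peak`` followed by an exponential decay back
toward DCa — plus the "hybrid transient" construction used by the sensitivity
analysis: a convex combination of two affinely normalized traces rescaled to
convex-combined (DCa, PCa) levels.

Default peak levels are the measured cell values: 1.53 µM (SHAM) and 0.93 µM
(aortic-banded).  Diastolic levels are not reported; 0.10 / 0.12 µM are used
as typical resting myocyte values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ShapeMismatchError

__all__ = [
    "CalciumTransient",
    "generate_calcium_transient",
    "hybrid_transient",
    "sham_transient",
    "ab_transient",
    "SHAM_PCA_UM",
    "AB_PCA_UM",
    "SHAM_DCA_UM",
    "AB_DCA_UM",
]

#: Measured peak calcium of SHAM-heart cells (µM).
SHAM_PCA_UM = 1.53
#: Measured peak calcium of aortic-banded-heart cells (µM).
AB_PCA_UM = 0.93
#: Assumed diastolic calcium levels (µM); not reported for the measured cells.
SHAM_DCA_UM = 0.10
AB_DCA_UM = 0.12


@dataclass(frozen=True)
class CalciumTransient:
    """Periodic sampled free-calcium trace.

    Attributes
    ----------
    time : ndarray
        Sample instants in ms, uniform grid covering one period, endpoint
        included (``time[-1] == period``).
    conc : ndarray
        Free calcium concentration in µM at each instant.
    period : float
        Cycle length in ms.
    DCa, PCa : float
        Diastolic and peak levels in µM.  By construction ``min(conc) == DCa``
        and ``max(conc) == PCa``.
    """

    time: np.ndarray
    conc: np.ndarray
    period: float
    DCa: float
    PCa: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1 or t.size < 2:
            raise ShapeMismatchError("time and conc must be matching 1-D arrays")
        if np.any(c < 0):
            raise InvalidParameterError("calcium concentration must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "conc", c)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def value_at(self, t: float) -> float:
        """Concentration at arbitrary time (periodic linear interpolation)."""
        tau = float(np.mod(t, self.period))
        return float(np.interp(tau, self.time, self.conc))

    def values_at(self, t: np.ndarray) -> np.ndarray:
        tau = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(tau, self.time, self.conc)

    def normalized(self) -> np.ndarray:
        """Affine normalization n(t) = (Ca(t) − DCa)/(PCa − DCa); zeros if flat."""
        span = self.PCa - self.DCa
        if span == 0.0:
            return np.zeros_like(self.conc)
        return (self.conc - self.DCa) / span

    def with_levels(self, DCa: float, PCa: float) -> "CalciumTransient":
        """Same normalized waveform rescaled to new (DCa, PCa) levels.

        This is the single-trace specialization of the hybrid construction:
        the affinely normalized shape is preserved exactly.
        """
        if not (PCa >= DCa >= 0.0):
            raise InvalidParameterError(f"need PCa >= DCa >= 0, got {DCa}, {PCa}")
        conc = DCa + self.normalized() * (PCa - DCa)
        return CalciumTransient(time=self.time.copy(), conc=conc,
                                period=self.period, DCa=DCa, PCa=PCa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time, "ca_uM": self.conc})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "CalciumTransient":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(dtype=float)
        c = df["ca_uM"].to_numpy(dtype=float)
        return cls(time=t, conc=c, period=float(t[-1]),
                   DCa=float(c.min()), PCa=float(c.max()))


def generate_calcium_transient(
    DCa: float,
    PCa: float,
    time_to_peak: float = 20.0,
    decay_time_constant: float = 50.0,
    period: float = 200.0,
    dt: float = 0.5,
) -> CalciumTransient:
    """Analytic two-phase calcium transient.

    Half-cosine rise from DCa to PCa over ``time_to_peak`` ms, then exponential
    decay with time constant ``decay_time_constant`` ms back toward DCa.  The
    decay tail is affinely re-normalized so the trace closes the period exactly
    at DCa, making the waveform periodic and its extrema exactly (DCa, PCa).

    Parameters are in µM and ms.  ``dt`` must divide the period.
    """
    if not (PCa >= DCa >= 0.0):
        raise InvalidParameterError(f"need PCa >= DCa >= 0, got DCa={DCa}, PCa={PCa}")
    if period <= 0 or dt <= 0:
        raise InvalidParameterError("period and dt must be positive")
    if not (period > time_to_peak > 0):
        raise InvalidParameterError("need period > time_to_peak > 0")
    n = period / dt
    if abs(n - round(n)) > 1e-9:
        raise InvalidParameterError(f"dt={dt} does not divide period={period}")
    n = int(round(n))

    t = np.linspace(0.0, period, n + 1)
    amp = PCa - DCa
    conc = np.empty_like(t)
    rise = t <= time_to_peak
    conc[rise] = DCa + amp * 0.5 * (1.0 - np.cos(np.pi * t[rise] / time_to_peak))
    # Raw exponential decay does not reach DCa in finite time; rescale the
    # decaying excess so it vanishes exactly at t = period.
    td = t[~rise] - time_to_peak
    t_end = period - time_to_peak
    raw = np.exp(-td / decay_time_constant)
    raw_end = np.exp(-t_end / decay_time_constant)
    if amp > 0:
        conc[~rise] = DCa + amp * (raw - raw_end) / (1.0 - raw_end)
    else:
        conc[~rise] = DCa
    # Guard against floating-point undershoot/overshoot at the extrema.
    np.clip(conc, DCa, PCa if amp > 0 else None, out=conc)
    conc[0] = DCa
    conc[-1] = DCa
    return CalciumTransient(time=t, conc=conc, period=float(period),
                            DCa=float(DCa), PCa=float(PCa))


def _resample(trace: CalciumTransient, time: np.ndarray, period: float) -> np.ndarray:
    if trace.time.shape == time.shape and np.allclose(trace.time, time):
        return trace.conc
    if abs(trace.period - period) > 1e-9:
        raise ShapeMismatchError(
            f"transient periods differ: {trace.period} vs {period} ms")
    return np.interp(time, trace.time, trace.conc)


def hybrid_transient(
    sham: CalciumTransient,
    ab: CalciumTransient,
    w_DCa: float,
    w_PCa: float,
) -> CalciumTransient:
    """Hybrid calcium trace blending SHAM and AB transients.

    Levels interpolate exactly:  DCa' = (1−w_DCa)·DCa_sham + w_DCa·DCa_ab and
    likewise PCa'.  The waveform shape is the convex combination of the two
    affinely normalized traces with weight w̄ = (w_DCa + w_PCa)/2, mapped back
    to the (DCa', PCa') range.  w = 0 selects the pure SHAM value, w = 1 the
    pure AB value; the endpoints reproduce the inputs identically.
    """
    for name, w in (("w_DCa", w_DCa), ("w_PCa", w_PCa)):
        if not (0.0 <= w <= 1.0):
            raise InvalidParameterError(f"{name} must be in [0, 1], got {w}")
    time = sham.time
    period = sham.period
    ab_conc = _resample(ab, time, period)
    ab_resampled = CalciumTransient(time=time, conc=ab_conc, period=period,
                                    DCa=ab.DCa, PCa=ab.PCa)
    d = (1.0 - w_DCa) * sham.DCa + w_DCa * ab.DCa
    p = (1.0 - w_PCa) * sham.PCa + w_PCa * ab.PCa
    wbar = 0.5 * (w_DCa + w_PCa)
    n_hyb = (1.0 - wbar) * sham.normalized() + wbar * ab_resampled.normalized()
    # If the two peaks are not simultaneous the blended shape tops out below 1;
    # re-normalize to [0, 1] so the hybrid levels are attained exactly.
    lo, hi = float(n_hyb.min()), float(n_hyb.max())
    if hi > lo:
        n_hyb = (n_hyb - lo) / (hi - lo)
    conc = d + n_hyb * (p - d)
    return CalciumTransient(time=time.copy(), conc=conc, period=period,
                            DCa=float(d), PCa=float(p))


def sham_transient(period: float = 200.0, dt: float = 0.5) -> CalciumTransient:
    """Default SHAM transient (PCa 1.53 µM)."""
    return generate_calcium_transient(SHAM_DCA_UM, SHAM_PCA_UM,
                                      period=period, dt=dt)


def ab_transient(period: float = 200.0, dt: float = 0.5) -> CalciumTransient:
    """Default aortic-banded transient (PCa 0.93 µM)."""
    return generate_calcium_transient(AB_DCA_UM, AB_PCA_UM,
                                      period=period, dt=dt)
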