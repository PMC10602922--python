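"""Fluorescence calibration and inversion for trans-cleavage assays.

A fluorophore-quencher reporter is imperfectly quenched, so the observed
signal is a two-slope mixture of cleaved and uncleaved reporter pools:

    F(t) = m_cl * c_cl(t) + m_ucl * c_ucl(t)

with mass conservation c_cl + c_ucl = c_0.  Fitting the two slopes from
titrations of fully cleaved / uncleaved reporters lets observed fluorescence
be inverted into cleaved-reporter concentration,

    c_cl(t) = (F(t) - m_ucl * c_0) / (m_cl - m_ucl),

and differentiated into cleavage velocity in nM/s.  The reference instrument
slopes are m_cl = 0.14466 and m_ucl = 0.00007 AU/nM, so the inversion
denominator is 0.14459 AU/nM and the offset at c_0 = 125 nM is 0.00875 AU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceSeries",
    "CalibrationModel",
    "ConcentrationSeries",
    "PAPER_SLOPE_CLEAVED",
    "PAPER_SLOPE_UNCLEAVED",
    "reference_calibration",
    "fit_calibration",
    "invert_fluorescence",
    "cleavage_velocity",
]

# Reference AU/nM slopes of the plate-reader calibration this model family
# was characterized on; used as simulator defaults.
PAPER_SLOPE_CLEAVED = 0.14466
PAPER_SLOPE_UNCLEAVED = 0.00007


@dataclass
class FluorescenceSeries:
    """A background-referenced fluorescence time course (times in s, AU).

    ``background`` is either a scalar or a buffer-only control series on the
    same grid.
    """

    times: np.ndarray
    values: np.ndarray
    background: np.ndarray | float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if isinstance(self.background, np.ndarray):
            if self.background.shape != self.times.shape:
                raise ValueError("background series must match the time grid")

    def __len__(self) -> int:
        return self.times.size

    def background_subtracted(self) -> np.ndarray:
        return self.values - self.background

    def at(self, t: float) -> float:
        """Linear interpolation; errors outside the covered range."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"t={t} outside series range "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class CalibrationModel:
    """Fluorescence-per-concentration slopes (AU/nM) and instrument background."""

    m_cl: float
    m_ucl: float
    background: float = 0.0
    r_squared_cl: float = math.nan
    r_squared_ucl: float = math.nan

    def __post_init__(self) -> None:
        if not (self.m_cl > self.m_ucl >= 0):
            raise ValueError("require m_cl > m_ucl >= 0")

    @property
    def inversion_slope(self) -> float:
        """AU/nM denominator of the inversion, m_cl - m_ucl."""
        return self.m_cl - self.m_ucl


def reference_calibration(background: float = 0.0) -> CalibrationModel:
    """Calibration with the reference instrument slopes."""
    return CalibrationModel(PAPER_SLOPE_CLEAVED, PAPER_SLOPE_UNCLEAVED,
                            background=background,
                            r_squared_cl=1.0, r_squared_ucl=1.0)


@dataclass
class ConcentrationSeries:
    """Cleaved/uncleaved reporter concentrations over time (nM)."""

    times: np.ndarray
    c_cl: np.ndarray
    c_ucl: np.ndarray
    c_0: float
    clamped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_cl = np.asarray(self.c_cl, dtype=float)
        self.c_ucl = np.asarray(self.c_ucl, dtype=float)
        if self.clamped is None:
            self.clamped = np.zeros(self.times.shape, dtype=bool)


def _zero_intercept_fit(conc: np.ndarray, sig: np.ndarray) -> tuple[float, float]:
    slope = float(np.dot(conc, sig) / np.dot(conc, conc))
    resid = sig - slope * conc
    ss_tot = float(np.dot(sig, sig))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else math.nan
    return slope, r2


def fit_calibration(cleaved_titration, uncleaved_titration,
                    buffer_signal: float = 0.0,
                    zero_intercept: bool = True) -> CalibrationModel:
    """Fit the two calibration slopes from titration points.

    Each titration is a sequence of ``(concentration_nM, fluorescence_au)``
    pairs; ``buffer_signal`` (buffer-only well) is subtracted before the fit.
    By default the regression is forced through the origin, since the points
    are already background-subtracted; a free-intercept variant is available
    for diagnostics.
    """
    fitted = {}
    for label, pts in (("cl", cleaved_titration), ("ucl", uncleaved_titration)):
        pts = list(pts)
        if len(pts) < 3:
            raise ValueError(f"{label} titration needs at least 3 points")
        conc = np.array([p[0] for p in pts], dtype=float)
        if np.unique(conc).size != conc.size:
            raise ValueError(f"{label} titration concentrations must be distinct")
        sig = np.array([p[1] for p in pts], dtype=float) - buffer_signal
        if zero_intercept:
            slope, r2 = _zero_intercept_fit(conc, sig)
        else:
            coeffs = np.polyfit(conc, sig, 1)
            slope = float(coeffs[0])
            resid = sig - np.polyval(coeffs, conc)
            ss_tot = float(np.sum((sig - sig.mean()) ** 2))
            r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else math.nan
        if slope < 0:
            raise ValueError(f"titration inconsistent: negative {label} slope")
        fitted[label] = (slope, r2)
    (m_cl, r2_cl), (m_ucl, r2_ucl) = fitted["cl"], fitted["ucl"]
    return CalibrationModel(m_cl, m_ucl, background=buffer_signal,
                            r_squared_cl=r2_cl, r_squared_ucl=r2_ucl)


def invert_fluorescence(series: FluorescenceSeries, calib: CalibrationModel,
                        c_0: float) -> ConcentrationSeries:
    """Invert observed fluorescence into cleaved-reporter concentration.

    Uses the background-subtracted signal and the consistent denominator
    m_cl - m_ucl; values are clamped to [0, c_0] with a per-point flag.
    """
    if c_0 <= 0:
        raise ValueError("c_0 must be positive")
    denom = calib.inversion_slope
    if denom <= 0:
        raise ValueError("degenerate calibration: m_cl == m_ucl")
    f_bgsub = series.background_subtracted()
    c_cl = (f_bgsub - calib.m_ucl * c_0) / denom
    clamped = (c_cl < 0) | (c_cl > c_0)
    c_cl = np.clip(c_cl, 0.0, c_0)
    return ConcentrationSeries(series.times, c_cl, c_0 - c_cl, c_0, clamped)


def cleavage_velocity(series: FluorescenceSeries, calib: CalibrationModel) -> np.ndarray:
    """Cleavage velocity dc_cl/dt (nM/s) via finite differences of F(t).

    Central differences on interior points, one-sided at the ends, scaled by
    1/(m_cl - m_ucl).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 time points")
    denom = calib.inversion_slope
    if denom <= 0:
        raise ValueError("degenerate calibration: m_cl == m_ucl")
    dfdt = np.gradient(series.background_subtracted(), series.times)
    return dfdt / denom
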