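"""Michaelis-Menten parameter extraction from trans-cleavage time courses.

Initial velocities come from a linear regression of the first 600 s of each
fluorescence series (converted from AU/s to nM/s through the calibration
denominator m_cl - m_ucl); velocities versus substrate concentration are then
fitted to

    v = k_cat E0 [S] / (K_M + [S])

by nonlinear least squares.  In the low-substrate limit [S] << K_M the
progress curve is exponential, c_cl(t) = S0 (1 - exp(-r t)) with
r = k_cat E0 / K_M, which ``fit_first_order_limit`` estimates directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .calibration import CalibrationModel, ConcentrationSeries, FluorescenceSeries

__all__ = ["MMFit", "initial_velocity", "fit_michaelis_menten",
           "fit_first_order_limit", "activation_efficiency"]

logger = logging.getLogger(__name__)

DEFAULT_VELOCITY_WINDOW_S = 600.0


@dataclass
class MMFit:
    """Fitted Michaelis-Menten parameters and diagnostics."""

    k_cat: float                    # /s
    K_M: float                      # nM
    E0: float                       # nM enzyme used in the fit
    k_cat_se: float
    K_M_se: float
    velocities: list[tuple[float, float]] = field(default_factory=list)  # (S nM, v nM/s)
    flags: list[str] = field(default_factory=list)

    @property
    def kcat_over_KM(self) -> float:
        """Catalytic efficiency in /M/s."""
        return self.k_cat / self.K_M * 1e9


def initial_velocity(series: FluorescenceSeries, calib: CalibrationModel,
                     window_s: float = DEFAULT_VELOCITY_WINDOW_S) -> float:
    """Initial cleavage velocity (nM/s) from a linear fit over [0, window_s].

    The slope is fitted in AU/s on the background-subtracted signal and
    converted through 1/(m_cl - m_ucl).  Requires at least 5 points inside
    the window; a clearly negative slope is returned as-is with a warning.
    """
    mask = series.times <= window_s
    if int(mask.sum()) < 5:
        raise ValueError(f"need >= 5 points within {window_s} s, "
                         f"got {int(mask.sum())}")
    res = linregress(series.times[mask], series.background_subtracted()[mask])
    v = res.slope / calib.inversion_slope
    if v < 0 and res.stderr and abs(res.slope) > 3 * res.stderr:
        logger.warning("negative initial velocity %.3g nM/s beyond noise", v)
    return float(v)


def fit_michaelis_menten(points, E0: float) -> MMFit:
    """Fit (k_cat, K_M) to (S, v) points at known active-enzyme concentration.

    Requires >= 4 distinct substrate levels spanning at least a 4-fold range.
    Initial guesses: k_cat from the largest observed velocity, K_M from the
    median substrate level.  A fitted K_M far above the probed range, or a
    saturated (K_M -> 0) fit, is flagged rather than rejected.
    """
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    pts = sorted((float(s), float(v)) for s, v in points)
    S = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.unique(S).size < 4:
        raise ValueError("need at least 4 distinct substrate levels")
    if S.max() < 4 * S.min():
        raise ValueError("substrate levels must span at least a 4-fold range")

    def mm(s, k_cat, K_M):
        return k_cat * E0 * s / (K_M + s)

    p0 = (max(v.max(), 1e-12) / E0, float(np.median(S)))
    try:
        popt, pcov = curve_fit(mm, S, v, p0=p0, maxfev=20000,
                               bounds=([0.0, 0.0], [np.inf, np.inf]))
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}; "
                           f"p0={p0}, S range {S.min()}-{S.max()}") from exc
    k_cat, K_M = float(popt[0]), float(popt[1])
    ses = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    flags = []
    if K_M > 100 * S.max():
        flags.append("K_M poorly constrained (>100x max substrate)")
        logger.warning(flags[-1])
    if K_M < 1e-3 * S.min():
        flags.append("degenerate saturated fit (K_M -> 0)")
        logger.warning(flags[-1])
    return MMFit(k_cat=k_cat, K_M=K_M, E0=E0,
                 k_cat_se=float(ses[0]), K_M_se=float(ses[1]),
                 velocities=pts, flags=flags)


def fit_first_order_limit(series: ConcentrationSeries) -> dict:
    """Fit c_cl(t) = S0_hat (1 - exp(-r t)); r estimates k_cat E0 / K_M (/s)."""
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.c_cl, dtype=float)
    if t.size < 3:
        raise ValueError("series too short")
    s0_guess = max(series.c_0, float(c.max()), 1e-9)
    # crude rate guess from the earliest nonzero rise
    nz = np.nonzero(c > 0.05 * s0_guess)[0]
    r_guess = 1.0 / t[nz[0]] if nz.size and t[nz[0]] > 0 else 1.0 / max(t[-1], 1.0)

    def model(tt, s0, r):
        return s0 * (1.0 - np.exp(-r * tt))

    try:
        popt, _ = curve_fit(model, t, c, p0=(s0_guess, r_guess), maxfev=20000,
                            bounds=([0.0, 0.0], [np.inf, np.inf]))
    except RuntimeError as exc:
        raise RuntimeError(f"first-order fit did not converge: {exc}") from exc
    return {"rate": float(popt[1]), "S0_hat": float(popt[0])}


def activation_efficiency(v_controlled: float, v_uncontrolled: float) -> float:
    """Velocity of a gated configuration relative to the matched no-ERA control."""
    if v_uncontrolled <= 0:
        raise ValueError("uncontrolled reference velocity must be positive")
    return v_controlled / v_uncontrolled
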