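"""First-order contraction kinetics and Arrhenius analysis.

Heat-triggered sheath contraction monitored in bulk (e.g. by circular
dichroism at a fixed wavelength) behaves as a first-order reaction,
S(t) = S_inf + (S_0 - S_inf) exp(-k t).  With a temperature-independent
activation energy, ln k is linear in 1/T with slope -Ea/R (Arrhenius), so
an ordinary least-squares fit of ln k on 1/T yields Ea and its confidence
interval from the slope's standard error and the t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from dmad.errors import DomainError, FitError, InputError

__all__ = [
    "FirstOrderFit",
    "ArrheniusFit",
    "fit_first_order",
    "arrhenius",
    "subtract_control",
    "GAS_CONSTANT_KCAL",
]

#: gas constant, kcal/mol/K
GAS_CONSTANT_KCAL = 1.98720e-3


@dataclass
class FirstOrderFit:
    """Exponential decay fit S(t) = s_inf + (s0 - s_inf) exp(-k t)."""

    rate: float  # 1/time-unit of the input
    s0: float
    s_inf: float
    rate_stderr: float
    residuals: np.ndarray

    @property
    def amplitude(self) -> float:
        return self.s0 - self.s_inf


@dataclass
class ArrheniusFit:
    """Arrhenius regression of rates vs temperature.

    Ea = -slope * R with slope from ln(k) on 1/T ordinary least squares;
    ci95_Ea from the slope's standard error and the t distribution (NaN for
    a two-point fit, which is exact but has no error estimate).
    """

    Ea: float  # kcal/mol
    lnA: float
    ci95_Ea: float
    rates: np.ndarray
    temperatures: np.ndarray
    R: float = GAS_CONSTANT_KCAL


def fit_first_order(
    time: np.ndarray,
    signal: np.ndarray,
    trim_before: float = 0.0,
    amplitude_floor: float = 5.0,
) -> FirstOrderFit:
    """Nonlinear least-squares fit of a single-exponential time course.

    ``trim_before`` drops early points (sample heating/equilibration;
    bulk-contraction protocols typically trim the first 2 minutes).
    Initial guesses: endpoints for the plateaus and a half-life heuristic
    for the rate.  A fit whose amplitude is smaller than
    ``amplitude_floor`` times the residual noise is rejected as degenerate.
    """
    t = np.asarray(time, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise InputError("time and signal must be matching 1-D arrays")
    keep = t >= trim_before
    t, s = t[keep], s[keep]
    if len(t) < 5:
        raise InputError("need at least 5 points to fit a first-order decay")
    if np.any(t < 0.0):
        raise DomainError("times must be nonnegative")

    s0_g, sinf_g = s[0], s[-1]
    half = sinf_g + 0.5 * (s0_g - sinf_g)
    crossing = np.nonzero(np.sign(s - half) != np.sign(s[0] - half))[0]
    t_half = t[crossing[0]] - t[0] if crossing.size else (t[-1] - t[0]) / 2.0
    k_g = np.log(2.0) / max(t_half, (t[1] - t[0]))

    def model(tt, s_inf, amp, k):
        return s_inf + amp * np.exp(-k * (tt - t[0]))

    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            s,
            p0=[sinf_g, s0_g - sinf_g, k_g],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"first-order fit did not converge: {exc}") from exc
    s_inf, amp, k = popt
    resid = s - model(t, *popt)
    noise = float(np.sqrt(np.mean(resid**2)))
    if abs(amp) < amplitude_floor * max(noise, 1e-15):
        raise FitError(
            f"amplitude {amp:.3g} indistinguishable from zero "
            f"(noise {noise:.3g}); no decay to fit"
        )
    k_err = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
    # shift s0 back to t=0 of the trimmed series
    return FirstOrderFit(
        rate=float(k), s0=float(s_inf + amp), s_inf=float(s_inf),
        rate_stderr=k_err, residuals=resid,
    )


def arrhenius(rates: np.ndarray, temperatures: np.ndarray) -> ArrheniusFit:
    """Ea and lnA from ln(k) vs 1/T ordinary least squares.

    Exact for a noiseless two-point input; the 95% CI needs >= 3 points.
    """
    k = np.asarray(rates, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if k.shape != T.shape or k.ndim != 1 or len(k) < 2:
        raise InputError("need matching 1-D arrays of >= 2 rates and temperatures")
    if np.any(k <= 0.0) or np.any(T <= 0.0):
        raise DomainError("rates and temperatures must be positive")
    x = 1.0 / T
    y = np.log(k)
    if len(k) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return ArrheniusFit(
            Ea=float(-slope * GAS_CONSTANT_KCAL),
            lnA=float(intercept),
            ci95_Ea=float("nan"),
            rates=k,
            temperatures=T,
        )
    res = stats.linregress(x, y)
    tval = stats.t.ppf(0.975, len(k) - 2)
    return ArrheniusFit(
        Ea=float(-res.slope * GAS_CONSTANT_KCAL),
        lnA=float(res.intercept),
        ci95_Ea=float(tval * res.stderr * GAS_CONSTANT_KCAL),
        rates=k,
        temperatures=T,
    )


def subtract_control(
    sample: pd.DataFrame, control: pd.DataFrame, on: str = "time"
) -> pd.DataFrame:
    """Averaged-control subtraction of bulk time courses.

    Both frames need columns (time, signal); replicates (duplicate times)
    are averaged, the averaged control is interpolated onto the sample's
    time base and subtracted.
    """
    s = sample.groupby(on, as_index=False)["signal"].mean()
    c = control.groupby(on, as_index=False)["signal"].mean()
    interp = np.interp(s[on], c[on], c["signal"])
    out = s.copy()
    out["signal"] = s["signal"] - interp
    return out
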