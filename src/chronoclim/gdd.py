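"""Growing degree days from monthly means via a normal daily-temperature model.

GDD accumulates daily exceedance of mean temperature over a base T0 (0 or
5 degC).  With only monthly means available, applying the hinge max(T - T0, 0)
to the monthly mean underestimates GDD whenever the daily distribution
straddles the base (Jensen's inequality for a convex hinge).  Assuming daily
temperature is normal with mean Tbar and standard deviation sigma, the exact
expectation is

    E[max(T - T0, 0)] = sigma/sqrt(2 pi) exp(-z^2/2) + (Tbar - T0)/2 erfc(-z/sqrt(2))

with z = (Tbar - T0)/sigma.  The daily sigma is estimated from the monthly
sigma by splitting monthly variance into a white-noise-plus-memory part
(a n sigma_monthly^2, with the empirical memory constant a = 0.178) and an
annual-cycle part sigma_annual^2 computed from a piecewise-linear daily
annual cycle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc

from .grids import MONTH_DAYS

__all__ = [
    "MEMORY_CONSTANT",
    "gdd_day_expectation",
    "gdd_naive_day",
    "sigma_annual",
    "sigma_daily",
    "gdd_month",
    "gdd_monthly_cycle",
]

#: Empirical daily-memory constant in sigma_daily^2 = a n sigma_monthly^2 + sigma_annual^2.
MEMORY_CONSTANT = 0.178


def gdd_day_expectation(
    T_mean: np.ndarray, sigma: np.ndarray, T0: float
) -> np.ndarray:
    """Expected daily degree-day contribution under a normal daily PDF.

    Reduces to max(T_mean - T0, 0) as sigma -> 0 and always dominates it.
    """
    T_mean = np.asarray(T_mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    dT = T_mean - T0
    naive = np.maximum(dT, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dT / sigma
        val = sigma / np.sqrt(2.0 * np.pi) * np.exp(-0.5 * z**2) + 0.5 * dT * erfc(
            -z / np.sqrt(2.0)
        )
    return np.where(sigma == 0, naive, val)


def gdd_naive_day(T_mean: np.ndarray, T0: float) -> np.ndarray:
    """The usual monthly-mean hinge max(Tbar - T0, 0), for comparison."""
    return np.maximum(np.asarray(T_mean, dtype=float) - T0, 0.0)


def sigma_annual(
    T_prev: np.ndarray,
    T_cur: np.ndarray,
    T_next: np.ndarray,
    n_prev: float,
    n_cur: float,
    n_next: float,
) -> np.ndarray:
    """Within-month SD of the piecewise-linear daily annual cycle.

    The daily cycle is the piecewise-linear function equal to each monthly
    mean at the month's center; within the current month it ramps with slope
    a_minus before the center and a_plus after.  The standard deviation about
    the monthly mean is n * sqrt((5 a+^2 + 6 a+ a- + 5 a-^2) / 192).
    """
    T_prev, T_cur, T_next = (np.asarray(t, dtype=float) for t in (T_prev, T_cur, T_next))
    a_plus = 2.0 * (T_next - T_cur) / (n_next + n_cur)
    a_minus = 2.0 * (T_cur - T_prev) / (n_cur + n_prev)
    rad = (5.0 * a_plus**2 + 6.0 * a_plus * a_minus + 5.0 * a_minus**2) / 192.0
    return n_cur * np.sqrt(np.maximum(rad, 0.0))


def sigma_daily(
    sigma_monthly: np.ndarray,
    n: float,
    sig_annual: np.ndarray,
    a: float = MEMORY_CONSTANT,
) -> np.ndarray:
    """Daily SD from monthly SD: sqrt(a n sigma_monthly^2 + sigma_annual^2)."""
    sigma_monthly = np.asarray(sigma_monthly, dtype=float)
    sig_annual = np.asarray(sig_annual, dtype=float)
    if (sigma_monthly < 0).any() or (sig_annual < 0).any():
        raise ValueError("standard deviations must be non-negative")
    return np.sqrt(a * n * sigma_monthly**2 + sig_annual**2)


def gdd_month(
    T_monthly_mean: np.ndarray, sig_daily: np.ndarray, T0: float, n: float
) -> np.ndarray:
    """Monthly GDD (degC day): n times the expected daily contribution."""
    return n * gdd_day_expectation(T_monthly_mean, sig_daily, T0)


def gdd_monthly_cycle(
    T_monthly: np.ndarray,
    sigma_monthly: np.ndarray,
    T0: float,
    month_days: np.ndarray = MONTH_DAYS,
    a: float = MEMORY_CONSTANT,
) -> np.ndarray:
    """GDD for all 12 months of a climatological cycle.

    ``T_monthly`` and ``sigma_monthly`` have shape (12, ...); the annual-cycle
    variance term wraps cyclically.  The daily SD derived from modern data is
    held constant across time when applied to paleo temperatures.
    """
    T = np.asarray(T_monthly, dtype=float)
    sig_m = np.asarray(sigma_monthly, dtype=float)
    if T.shape[0] != 12:
        raise ValueError("first axis must be the 12 months")
    out = np.empty_like(T)
    for j in range(12):
        jp, jn = (j - 1) % 12, (j + 1) % 12
        s_ann = sigma_annual(
            T[jp], T[j], T[jn], month_days[jp], month_days[j], month_days[jn]
        )
        s_day = sigma_daily(sig_m[j], month_days[j], s_ann, a=a)
        out[j] = gdd_month(T[j], s_day, T0, month_days[j])
    return out
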