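"""Seasonal-to-monthly harmonization by constrained smoothness minimization.

Paleo archives often store only seasonal means.  Linear interpolation of
seasonal values to months damps the annual cycle and is *inconsistent*: the
resulting JJA monthly mean no longer equals the archived summer mean.  The
solvers here instead pick, among all 12-month vectors that reproduce the four
seasonal means exactly, the one with the smallest cyclic second-difference
energy (the "smoothest" annual cycle).

* additive variables: a 16x16 linear Lagrange (KKT) system -- 12 months plus
  4 multipliers.  Seasons are DJF, MAM, JJA, SON, with the cycle periodic
  (month 0 is December, month 13 is January).
* factor variables (precipitation fractions etc.): smoothness is measured on
  log(f) and the constraints are climatology-weighted, giving a 16-equation
  system, partly nonlinear, solved with a Powell-hybrid root finder.
* shortwave exponents: the additive solver applied to log(gamma), which keeps
  the power positive.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root

from .grids import SEASON_MONTHS

__all__ = ["s2m_additive", "s2m_factor", "s2m_gamma", "second_difference_matrix"]


def second_difference_matrix(n: int = 12) -> np.ndarray:
    """Cyclic second-difference operator D with rows T_{j-1} - 2 T_j + T_{j+1}."""
    D = np.zeros((n, n))
    for j in range(n):
        D[j, (j - 1) % n] = 1.0
        D[j, j] = -2.0
        D[j, (j + 1) % n] = 1.0
    return D


def _constraint_matrix() -> np.ndarray:
    """4x12 season-membership matrix A with A @ T = 3 S."""
    A = np.zeros((4, 12))
    for s, members in enumerate(SEASON_MONTHS):
        A[s, list(members)] = 1.0
    return A


_D = second_difference_matrix()
_Q = _D.T @ _D  # objective Hessian (x2), positive semi-definite
_A = _constraint_matrix()

# KKT matrix of the equality-constrained quadratic program:
#   minimize T' Q T  subject to  A T = 3 S
# The 16x16 system is [2Q A'; A 0] [T; lambda] = [0; 3S].  Q is singular
# (constants are in its null space) but A is not orthogonal to constants,
# so the KKT matrix is nonsingular and the solution unique.
_KKT = np.zeros((16, 16))
_KKT[:12, :12] = 2.0 * _Q
_KKT[:12, 12:] = _A.T
_KKT[12:, :12] = _A
_KKT_INV = np.linalg.inv(_KKT)


def s2m_additive(S: np.ndarray) -> np.ndarray:
    """Smoothest 12-month vector whose seasonal means equal S (4 values).

    Supports batches: S of shape (..., 4) returns (..., 12).  Constraints
    hold to machine precision; the solution is the unique stationary point
    of the 16-dimensional Lagrange system.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != 4:
        raise ValueError("expected 4 seasonal values on the last axis")
    if not np.isfinite(S).all():
        raise ValueError("seasonal means must be finite")
    rhs = np.zeros((*S.shape[:-1], 16))
    rhs[..., 12:] = 3.0 * S
    sol = rhs @ _KKT_INV.T
    return sol[..., :12]


def s2m_gamma(gamma_seasonal: np.ndarray) -> np.ndarray:
    """Monthly shortwave exponents from seasonal ones, via logs.

    gamma must stay positive, so the additive solver runs on log(gamma) and
    the result is exponentiated: the seasonal means of log(gamma_monthly)
    reproduce log(gamma_seasonal) exactly.
    """
    g = np.asarray(gamma_seasonal, dtype=float)
    if (g <= 0).any():
        raise ValueError("seasonal gamma must be positive")
    return np.exp(s2m_additive(np.log(g)))


def _factor_system(x: np.ndarray, P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Stationarity + constraint residuals for the log-factor problem.

    Unknowns x = (log f_1..log f_12, lambda_1..lambda_4).  Stationarity:
    2 (Q log f)_j + lambda_s P_j f_j = 0 for month j in season s; constraints:
    sum_{j in s} P_j f_j = F_s sum_{j in s} P_j.
    """
    logf = x[:12]
    lam = x[12:]
    f = np.exp(logf)
    res = np.empty(16)
    grad = 2.0 * (_Q @ logf)
    for s, members in enumerate(SEASON_MONTHS):
        for j in members:
            grad[j] += lam[s] * P[j] * f[j]
    res[:12] = grad
    for s, members in enumerate(SEASON_MONTHS):
        m = list(members)
        tot = P[m].sum()
        res[12 + s] = (P[m] * f[m]).sum() - F[s] * tot
    return res


def _factor_jacobian(x: np.ndarray, P: np.ndarray, F: np.ndarray) -> np.ndarray:
    logf = x[:12]
    lam = x[12:]
    f = np.exp(logf)
    J = np.zeros((16, 16))
    J[:12, :12] = 2.0 * _Q
    for s, members in enumerate(SEASON_MONTHS):
        for j in members:
            J[j, j] += lam[s] * P[j] * f[j]
            J[j, 12 + s] = P[j] * f[j]
            J[12 + s, j] = P[j] * f[j]
    return J


def s2m_factor(
    F: np.ndarray,
    P_clim: np.ndarray,
    tol: float = 1e-10,
    restarts: int = 3,
) -> np.ndarray:
    """Monthly factors f (12, positive) from seasonal factors F (4).

    The climatology weights P_clim (12, >= 0) enter the constraints: the
    seasonal *weighted* mean of f equals F for each season.  Months with zero
    climatology are unconstrained and take whatever value makes log(f)
    smoothest.  Each season must carry positive total weight.

    Solved with a Powell-hybrid root finder on the 16-equation stationarity
    system, initialized from the flat solution f_j = F_{season(j)}, with
    deterministic jittered restarts on non-convergence.
    """
    F = np.asarray(F, dtype=float)
    P = np.asarray(P_clim, dtype=float)
    if F.shape != (4,) or P.shape != (12,):
        raise ValueError("expected F of shape (4,) and P_clim of shape (12,)")
    if (F <= 0).any():
        raise ValueError("seasonal factors must be positive")
    if (P < 0).any():
        raise ValueError("climatology weights must be non-negative")
    for s, members in enumerate(SEASON_MONTHS):
        if P[list(members)].sum() <= 0:
            raise ValueError(f"season {s} has zero total climatology weight")

    # flat start: log f = log F of the owning season, multipliers 0
    x0 = np.zeros(16)
    for s, members in enumerate(SEASON_MONTHS):
        for j in members:
            x0[j] = np.log(F[s])

    rng = np.random.default_rng(0)  # deterministic jitter for restarts
    x_start = x0
    for attempt in range(restarts + 1):
        sol = root(
            _factor_system,
            x_start,
            args=(P, F),
            jac=_factor_jacobian,
            method="hybr",
            tol=tol,
        )
        # judge by residuals, not the status flag: hybr reports failure when
        # started at (or stepping onto) an exact root it cannot improve
        f = np.exp(sol.x[:12])
        stationarity = np.abs(_factor_system(sol.x, P, F)).max()
        if _constraint_residual(f, P, F) <= 1e-8 and stationarity <= 1e-6:
            return f
        x_start = x0 + rng.normal(scale=0.05 * (attempt + 1), size=16)
    raise RuntimeError(
        f"factor seasonal-to-monthly solver failed after {restarts} restarts "
        f"(F={F.tolist()}, P={P.tolist()})"
    )


def _constraint_residual(f: np.ndarray, P: np.ndarray, F: np.ndarray) -> float:
    """Max relative violation of the weighted seasonal constraints."""
    worst = 0.0
    for s, members in enumerate(SEASON_MONTHS):
        m = list(members)
        tot = P[m].sum()
        target = F[s] * tot
        if target == 0:
            continue
        worst = max(worst, abs((P[m] * f[m]).sum() - target) / abs(target))
    return worst
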