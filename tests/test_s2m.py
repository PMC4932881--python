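import numpy as np
import pytest
from scipy.optimize import minimize

from chronoclim.grids import SEASON_MONTHS, seasonal_from_monthly
from chronoclim.s2m import (
    _constraint_matrix,
    _KKT,
    s2m_additive,
    s2m_factor,
    s2m_gamma,
    second_difference_matrix,
)

D = second_difference_matrix()
A = _constraint_matrix()


def qp_oracle(S):
    """Independent equality-constrained QP solution via null-space lstsq.

    Minimize ||D T||^2 s.t. A T = 3 S: particular solution from the
    pseudo-inverse, then least squares over the null space of A.
    """
    T_p = np.linalg.pinv(A) @ (3.0 * S)
    _, _, Vt = np.linalg.svd(A)
    Z = Vt[4:].T  # null-space basis, shape (12, 8)
    y, *_ = np.linalg.lstsq(D @ Z, -D @ T_p, rcond=None)
    return T_p + Z @ y


def smoothness(T):
    return float(((D @ T) ** 2).sum())


def penalty_oracle(F, P, tol=1e-11):
    """Augmented-Lagrangian minimizer of the log-smoothness objective under
    the climatology-weighted seasonal constraints (independent of the
    root-finding path used by the implementation)."""
    Q = D.T @ D
    members = [np.array(m) for m in SEASON_MONTHS]
    season_of = np.empty(12, dtype=int)
    for s, m in enumerate(members):
        season_of[m] = s

    def cons(x):
        f = np.exp(x)
        return np.array(
            [(P[m] * f[m]).sum() - F[s] * P[m].sum() for s, m in enumerate(members)]
        )

    def al(x, lam, mu):
        c = cons(x)
        val = x @ Q @ x + lam @ c + 0.5 * mu * (c**2).sum()
        g = 2.0 * Q @ x + (lam + mu * c)[season_of] * P * np.exp(x)
        return val, g

    x = np.empty(12)
    for s, m in enumerate(members):
        x[m] = np.log(F[s])
    lam = np.zeros(4)
    mu = 100.0
    for _ in range(50):
        res = minimize(al, x, args=(lam, mu), jac=True, method="BFGS",
                       options={"gtol": 1e-13, "maxiter": 5000})
        x = res.x
        c = cons(x)
        if np.abs(c).max() < tol:
            break
        lam = lam + mu * c
        mu = min(mu * 5.0, 1e10)
    return np.exp(x)


class TestAdditive:
    def test_constant_seasons_give_constant_months(self):
        np.testing.assert_allclose(s2m_additive(np.full(4, 3.7)), 3.7)

    def test_lagrange_system_dimension_is_16(self):
        assert _KKT.shape == (16, 16)
        assert np.linalg.matrix_rank(_KKT) == 16

    def test_constraints_hold_to_machine_precision(self, rng):
        S = rng.normal(0, 15, size=(50, 4))
        T = s2m_additive(S)
        np.testing.assert_allclose(seasonal_from_monthly(T, axis=-1), S, atol=1e-10)

    def test_matches_qp_oracle_on_random_instances(self, rng):
        for _ in range(100):
            S = rng.normal(0, 15, size=4)
            np.testing.assert_allclose(s2m_additive(S), qp_oracle(S), atol=1e-8)

    def test_feasible_perturbations_increase_objective(self, rng):
        S = rng.normal(0, 10, size=4)
        T = s2m_additive(S)
        base = smoothness(T)
        _, _, Vt = np.linalg.svd(A)
        Z = Vt[4:].T
        for _ in range(20):
            d = Z @ rng.normal(size=8)
            assert smoothness(T + 1e-3 * d) >= base - 1e-12

    def test_kkt_residual_small(self, rng):
        S = rng.normal(0, 10, size=4)
        T = s2m_additive(S)
        # stationarity: 2 D'D T must lie in the row space of A
        g = 2 * D.T @ D @ T
        lam, *_ = np.linalg.lstsq(A.T, g, rcond=None)
        assert np.abs(A.T @ lam - g).max() < 1e-10

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            s2m_additive(np.array([1.0, np.nan, 2.0, 3.0]))


class TestFactor:
    def test_unit_factors_stay_unit(self, rng):
        P = rng.uniform(5, 100, size=12)
        np.testing.assert_allclose(s2m_factor(np.ones(4), P), 1.0, atol=1e-9)

    def test_constant_factor_uniform_weights(self):
        f = s2m_factor(np.full(4, 2.5), np.full(12, 40.0))
        np.testing.assert_allclose(f, 2.5, atol=1e-8)

    def test_constraints_and_positivity_on_random_instances(self, rng):
        for _ in range(100):
            F = np.exp(rng.normal(0, 0.5, size=4))
            P = rng.uniform(1, 120, size=12)
            f = s2m_factor(F, P)
            assert (f > 0).all()
            for s, m in enumerate(SEASON_MONTHS):
                got = (P[list(m)] * f[list(m)]).sum()
                want = F[s] * P[list(m)].sum()
                assert abs(got - want) <= 1e-8 * abs(want)

    def test_matches_penalty_oracle(self, rng):
        for _ in range(15):
            F = np.exp(rng.normal(0, 0.4, size=4))
            P = rng.uniform(5, 100, size=12)
            f = s2m_factor(F, P)
            f_oracle = penalty_oracle(F, P)
            np.testing.assert_allclose(f, f_oracle, atol=1e-6, rtol=1e-6)

    def test_reduces_to_additive_in_logs_for_uniform_weights(self, rng):
        F = np.exp(rng.normal(0, 0.5, size=4))
        f = s2m_factor(F, np.full(12, 50.0))
        # with uniform weights the weighted constraint is NOT the additive
        # constraint on log f, but the smoothest log-cycle through equal
        # seasonal levels must still be season-symmetric; compare against the
        # penalty oracle, which shares no code with the solver
        np.testing.assert_allclose(f, penalty_oracle(F, np.full(12, 50.0)), atol=1e-6)

    def test_zero_weight_months_are_smoothness_determined(self):
        P = np.array([30.0, 30, 30, 30, 30, 0.0, 30, 30, 30, 30, 30, 30])
        F = np.array([1.0, 1.0, 2.0, 1.0])
        f = s2m_factor(F, P)
        assert (f > 0).all()
        # constrained months still satisfy their season's weighted mean
        m = [5, 6, 7]
        got = (P[m] * f[m]).sum()
        assert got == pytest.approx(F[2] * P[m].sum(), rel=1e-8)

    def test_zero_total_season_weight_rejected(self):
        P = np.ones(12)
        P[[5, 6, 7]] = 0.0
        with pytest.raises(ValueError, match="season 2"):
            s2m_factor(np.ones(4), P)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            s2m_factor(np.array([1.0, -0.5, 1.0, 1.0]), np.ones(12))


class TestGamma:
    def test_unit_gamma(self):
        np.testing.assert_allclose(s2m_gamma(np.ones(4)), 1.0)

    def test_constant_e(self):
        np.testing.assert_allclose(s2m_gamma(np.full(4, np.e)), np.e)

    def test_log_seasonal_means_preserved(self, rng):
        g_seasonal = np.exp(rng.normal(0, 0.5, size=4))
        g = s2m_gamma(g_seasonal)
        assert (g > 0).all()
        np.testing.assert_allclose(
            seasonal_from_monthly(np.log(g)), np.log(g_seasonal), atol=1e-10
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            s2m_gamma(np.array([1.0, 0.0, 1.0, 1.0]))
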