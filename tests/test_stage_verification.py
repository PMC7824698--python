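import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dvmrank.stage_verification import (HCoefficients, StageParams, WeightMap,
                                        analytic_fitness, compare_coefficients,
                                        h_w_to_lambda, lambda_to_h,
                                        pqrs_from_M, stage_model_rhs, taylor_h)

TABLE_POINT = StageParams(p=0.1195, q=0.0075, r=0.2344, s=0.1086)


def unit_weights():
    return WeightMap(*([1.0] * 8))


def random_h_w(seed):
    rng = np.random.default_rng(seed)
    h = HCoefficients(rng.uniform(0.5, 2.0, size=4) * np.array([1, -1, 1, -1]),
                      np.triu(rng.uniform(-2.0, 2.0, size=(4, 4))))
    w = WeightMap(*rng.uniform(0.2, 3.0, size=8))
    return h, w


class TestStageModel:
    def test_extinction_is_an_equilibrium(self):
        assert stage_model_rhs(0.0, 0.0, TABLE_POINT, c=0.5) == (0.0, 0.0)

    def test_pure_reproduction(self):
        params = StageParams(p=0.0, q=0.0, r=1.0, s=0.0)
        assert stage_model_rhs(0.0, 1.0, params, c=0.0) == (1.0, 0.0)

    def test_total_density_bookkeeping(self):
        params = StageParams(p=0.3, q=0.1, r=0.8, s=0.2)
        nj, na, c = 1.3, 0.7, 0.05
        dj, da = stage_model_rhs(nj, na, params, c)
        expected = (params.r * na - params.q * nj - params.s * na
                    - c * (nj + na) ** 2)
        assert dj + da == pytest.approx(expected, rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            stage_model_rhs(-0.1, 0.5, TABLE_POINT)


class TestAnalyticFitness:
    def test_matches_eigenvalue_oracle_at_table_point(self):
        J = np.array([[-(TABLE_POINT.p + TABLE_POINT.q), TABLE_POINT.r],
                      [TABLE_POINT.p, -TABLE_POINT.s]])
        leading = np.max(np.linalg.eigvals(J).real)
        assert analytic_fitness(TABLE_POINT) == pytest.approx(leading, rel=1e-12)
        assert analytic_fitness(TABLE_POINT) == pytest.approx(0.049817, abs=1e-6)

    def test_pure_maturation_is_neutral(self):
        assert analytic_fitness(StageParams(p=1.0, q=0.0, r=0.0, s=0.0)) == 0.0

    def test_no_maturation_decouples_stages(self):
        params = StageParams(p=0.0, q=0.3, r=0.9, s=0.2)
        assert analytic_fitness(params) == pytest.approx(-0.2)

    def test_monotone_in_each_rate(self):
        rng = np.random.default_rng(3)
        eps = 1e-6
        for _ in range(10):
            p, q, r, s = rng.uniform(0.05, 0.5, size=4)
            base = analytic_fitness(StageParams(p, q, r, s))
            assert analytic_fitness(StageParams(p + eps, q, r, s)) > base
            assert analytic_fitness(StageParams(p, q + eps, r, s)) < base
            assert analytic_fitness(StageParams(p, q, r + eps, s)) > base
            assert analytic_fitness(StageParams(p, q, r, s + eps)) < base

    def test_shared_competition_cancels_from_ranking(self):
        """ODE oracle: with two strategies competing through a common
        density-dependent mortality, the tail slope of the log density
        ratio matches the analytic fitness difference."""
        good = StageParams(p=0.15, q=0.01, r=0.30, s=0.10)
        poor = StageParams(p=0.10, q=0.03, r=0.22, s=0.12)
        assert analytic_fitness(good) > analytic_fitness(poor)

        def rhs(_, y):
            n1j, n1a, n2j, n2a = np.maximum(y, 0.0)
            N = n1j + n1a + n2j + n2a
            d1j = good.r * n1a - (good.p + good.q) * n1j - 0.1 * n1j * N
            d1a = good.p * n1j - good.s * n1a - 0.1 * n1a * N
            d2j = poor.r * n2a - (poor.p + poor.q) * n2j - 0.1 * n2j * N
            d2a = poor.p * n2j - poor.s * n2a - 0.1 * n2a * N
            return [d1j, d1a, d2j, d2a]

        sol = solve_ivp(rhs, (0.0, 400.0), [0.1, 0.1, 0.1, 0.1],
                        t_eval=np.linspace(200.0, 400.0, 50), rtol=1e-8)
        ratio = ((sol.y[2] + sol.y[3]) / (sol.y[0] + sol.y[1]))
        slope = np.polyfit(sol.t, np.log(ratio), 1)[0]
        assert slope < 0  # the fitter strategy takes over


class TestChangeOfVariables:
    def test_unit_weights_identity(self):
        params = pqrs_from_M(np.array([1, 0, 0, 0, 2, 0, 0, 0.0]),
                             unit_weights())
        assert (params.p, params.q, params.r, params.s) == (1.0, 0.0, 2.0, 0.0)

    def test_negative_rate_clamped_with_warning(self):
        M = np.zeros(8)
        M[1] = -0.5  # M2 feeds q with positive weight zeta1
        w = WeightMap(1, 1, 1, 2, 1, 1, 1, 1)
        with pytest.warns(UserWarning, match="clamped"):
            params = pqrs_from_M(M, w)
        assert params.q == 0.0

    def test_linearity_before_clamping(self):
        rng = np.random.default_rng(0)
        w = unit_weights()
        G = w.group_vectors()
        M1, M2 = rng.normal(size=(2, 8))
        np.testing.assert_allclose(G @ (M1 + M2), G @ M1 + G @ M2, rtol=1e-12)


class TestTaylorH:
    def test_coordinate_function(self):
        h = taylor_h(lambda sp: sp.p, TABLE_POINT)
        np.testing.assert_allclose(h.linear, [1, 0, 0, 0], atol=1e-8)
        np.testing.assert_allclose(h.quadratic, np.zeros((4, 4)), atol=1e-4)

    def test_pure_cross_term(self):
        h = taylor_h(lambda sp: sp.p * sp.q, TABLE_POINT)
        assert h.quadratic[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.abs(np.diag(h.quadratic)) < 1e-4)

    def test_step_halving_converges(self):
        h1 = taylor_h(analytic_fitness, TABLE_POINT, step=1e-4)
        h2 = taylor_h(analytic_fitness, TABLE_POINT, step=5e-5)
        np.testing.assert_allclose(h1.linear, h2.linear, rtol=1e-6)
        np.testing.assert_allclose(h1.quadratic, h2.quadratic, rtol=1e-4,
                                   atol=1e-6)

    def test_adult_to_reproduction_tradeoff_at_table_point(self):
        """First-order ratio h4/h3 of the eigenvalue fitness at the
        reported demographic point, against an exact derivative oracle."""
        h = taylor_h(analytic_fitness, TABLE_POINT, convention="r=1")
        p, q, r, s = (TABLE_POINT.p, TABLE_POINT.q, TABLE_POINT.r,
                      TABLE_POINT.s)
        root = np.sqrt((p + q - s) ** 2 + 4 * p * r)
        dF_dr = p / root
        dF_ds = 0.5 * (-1.0 - (p + q - s) / root)
        assert h.linear[3] == pytest.approx(dF_ds / dF_dr, rel=1e-6)
        assert h.linear[3] == pytest.approx(-1.48, abs=0.01)

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            taylor_h(analytic_fitness, TABLE_POINT, step=0.0)


class TestLambdaHRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forward_backward_recovery(self, seed):
        h, w = random_h_w(seed)
        lam = h_w_to_lambda(h, w)
        h_rec, w_rec, residuals = lambda_to_h(lam, fixed_h=tuple(h.linear))
        assert residuals["consistent"]
        np.testing.assert_allclose(h_rec.linear, h.linear, rtol=1e-12)
        np.testing.assert_allclose(h_rec.quadratic, h.quadratic, atol=1e-10)
        for name in ("theta1", "phi1", "psi1", "zeta1",
                     "theta2", "phi2", "psi2", "zeta2"):
            assert getattr(w_rec, name) == pytest.approx(
                getattr(w, name), rel=1e-10)

    def test_zero_quadratic_lambda_gives_zero_h(self):
        h = HCoefficients(np.array([1.0, -1.0, 1.0, -1.0]), np.zeros((4, 4)))
        lam = h_w_to_lambda(h, unit_weights())
        h_rec, _, _ = lambda_to_h(lam, fixed_h=(1.0, -1.0, 1.0, -1.0))
        np.testing.assert_allclose(h_rec.quadratic, np.zeros((4, 4)),
                                   atol=1e-12)

    def test_fixed_h_must_be_nonzero(self):
        h, w = random_h_w(0)
        lam = h_w_to_lambda(h, w)
        with pytest.raises(ZeroDivisionError):
            lambda_to_h(lam, fixed_h=(1.0, 0.0, 1.0, 1.0))


class TestComparisonTable:
    def test_identical_inputs_give_zero_differences(self):
        h = taylor_h(analytic_fitness, TABLE_POINT, convention="r=1")
        table = compare_coefficients(h, h)
        assert np.all(table["abs_diff"] == 0.0)
        assert not table["sign_flip"].any()

    def test_reproduction_rows_normalize_to_one(self):
        h = taylor_h(analytic_fitness, TABLE_POINT, convention="r=1")
        table = compare_coefficients(h, h).set_index("coefficient")
        assert table.loc["h3", "analytic"] == pytest.approx(1.0)
        assert table.loc["h3", "reconstructed"] == pytest.approx(1.0)

    def test_sign_disagreement_flagged(self):
        h1 = HCoefficients(np.array([1.0, -1.0, 1.0, -1.0]),
                           np.zeros((4, 4)), "r=1")
        quad = np.zeros((4, 4))
        quad[0, 1] = -3.9
        h2 = HCoefficients(np.array([1.0, -1.0, 1.0, -1.0]), quad, "r=1")
        h1b = HCoefficients(h1.linear, _with(h1.quadratic, (0, 1), 3.9), "r=1")
        table = compare_coefficients(h1b, h2).set_index("coefficient")
        assert bool(table.loc["h12", "sign_flip"])

    def test_normalization_mismatch_rejected(self):
        h = taylor_h(analytic_fitness, TABLE_POINT)
        with pytest.raises(ValueError, match="normalization"):
            compare_coefficients(h, h.normalized_r1())


def _with(mat, idx, value):
    out = mat.copy()
    out[idx] = value
    return out
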