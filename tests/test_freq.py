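import numpy as np
import pandas as pd
import pytest

from carmap.freq import (
    dean_test,
    fit_negbin,
    fit_poisson,
    forward_select,
    moran_i,
)
from carmap.lattice import LatticeSpec, make_grid_adjacency


def brute_force_moran(z, W):
    """Literal double-loop evaluation of Moran's I."""
    z = np.asarray(z, dtype=float)
    z = z - z.mean()
    n = len(z)
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            S0 += W[i, j]
    return (n / S0) * num / np.sum(z**2)


class TestPoisson:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, size=30)
        off = rng.normal(0, 0.3, size=30)
        fit = fit_poisson(y, np.ones((30, 1)), off)
        assert fit.params.iloc[0] == pytest.approx(
            np.log(y.sum() / np.exp(off).sum()), abs=1e-8
        )
        # fitted shares proportional to offsets
        np.testing.assert_allclose(
            fit.mu / np.exp(off), fit.mu[0] / np.exp(off[0]), rtol=1e-8
        )
        assert fit.mu.sum() == pytest.approx(y.sum(), rel=1e-10)

    def test_saturated_two_area_fit(self):
        y = np.array([2.0, 4.0])
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = fit_poisson(y, X, np.zeros(2))
        np.testing.assert_allclose(fit.mu, y, rtol=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.standard_normal(n)
        off = np.log(rng.uniform(800, 3000, n))
        beta = np.array([-5.7, 0.12])
        y = rng.poisson(np.exp(off + beta[0] + beta[1] * x))
        fit = fit_poisson(y, np.column_stack([np.ones(n), x]), off)
        for j in range(2):
            assert abs(fit.params.iloc[j] - beta[j]) < 3 * fit.bse.iloc[j]

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_poisson(np.arange(10.0), X)


class TestNegbin:
    def test_poisson_limit(self):
        """Poisson data: NB collapses to Poisson (typical loglik gap < 0.5)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 500
            off = np.log(rng.uniform(500, 2000, n))
            y = rng.poisson(np.exp(off - 5.5))
            X = np.ones((n, 1))
            pois = fit_poisson(y, X, off)
            nb = fit_negbin(y, X, off)
            assert abs(nb.loglik - pois.loglik) < 0.5
            assert nb.theta > 100
            np.testing.assert_allclose(
                nb.params.to_numpy(), pois.params.to_numpy(), atol=1e-3
            )

    def test_dispersion_recovery(self):
        rng = np.random.default_rng(2)
        n = 500
        theta = 2.0
        off = np.log(rng.uniform(800, 3000, n))
        mu = np.exp(off - 5.0)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        nb = fit_negbin(y, np.ones((n, 1)), off)
        # generous recovery band: theta's sampling error at n=500 is sizeable
        assert 1.4 < nb.theta < 2.9

    def test_intercept_only_mean_identity(self):
        rng = np.random.default_rng(3)
        y = rng.negative_binomial(1.0, 0.2, size=100)
        nb = fit_negbin(y, np.ones((100, 1)))
        assert nb.mu.sum() == pytest.approx(y.sum(), rel=1e-4)


class TestDean:
    def test_exact_fit_gives_negative_statistic(self):
        y = np.full(12, 7.0)
        fit = fit_poisson(y, np.ones((12, 1)))
        res = dean_test(fit)
        np.testing.assert_allclose(fit.mu, y)
        assert res.statistic == pytest.approx(
            -y.sum() / np.sqrt(2 * np.sum(fit.mu**2))
        )
        assert not res.decision

    def test_overdispersed_data_detected(self):
        """NB2 with theta = 1: overdispersion flagged nearly always."""
        rng = np.random.default_rng(4)
        n = 56
        rej = 0
        R = 50
        for _ in range(R):
            mu = 7.0
            y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu), size=n)
            rej += dean_test(fit_poisson(y, np.ones((n, 1)))).decision
        assert rej / R > 0.9

    def test_small_sample_warns(self):
        y = np.array([1.0, 2.0, 3.0])
        fit = fit_poisson(y, np.ones((3, 1)))
        with pytest.warns(UserWarning, match="unreliable"):
            dean_test(fit)

    def test_requires_poisson_family(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(5, 50)
        nb = fit_negbin(y, np.ones((50, 1)))
        with pytest.raises(ValueError):
            dean_test(nb)


class TestMoran:
    def test_null_expectation_closed_form(self):
        lat = make_grid_adjacency(LatticeSpec(7, 8))
        rng = np.random.default_rng(0)
        res = moran_i(rng.standard_normal(56), lat.W)
        assert res.extra["expected"] == pytest.approx(-1 / 55)
        # for n = 53 areas the null expectation is -0.0192
        assert -1 / 52 == pytest.approx(-0.0192, abs=5e-4)

    def test_checkerboard_is_perfectly_negative(self):
        lat = make_grid_adjacency(LatticeSpec(4, 4, "rook"))
        z = np.array([(-1.0) ** (i // 4 + i % 4) for i in range(16)])
        res = moran_i(z, lat.W)
        assert res.statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        A = (rng.random((n, n)) < 0.4).astype(float)
        W = np.triu(A, 1)
        W = W + W.T
        if W.sum() == 0:
            W[0, 1] = W[1, 0] = 1.0
        z = rng.standard_normal(n)
        assert moran_i(z, W).statistic == pytest.approx(
            brute_force_moran(z, W), abs=1e-12
        )

    def test_permutation_p_close_to_analytic(self):
        lat = make_grid_adjacency(LatticeSpec(6, 6))
        rng = np.random.default_rng(8)
        z = rng.standard_normal(36)
        res = moran_i(z, lat.W, permutations=999, seed=1)
        assert abs(res.extra["p_permutation"] - res.extra["p_normal"]) < 0.1

    def test_constant_residuals_rejected(self, grid12):
        with pytest.raises(ValueError, match="constant"):
            moran_i(np.ones(12), grid12.W)


class TestForwardSelect:
    @staticmethod
    def _sim(seed, beta_econ=0.0, n=56):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "ECON": rng.standard_normal(n),
                "MIG": rng.standard_normal(n),
                "FRAG": rng.standard_normal(n),
            }
        )
        off = np.log(rng.uniform(1000, 3000, n))
        y = rng.poisson(np.exp(off - 5.7 + beta_econ * X["ECON"].to_numpy()))
        return y, X, off

    def test_no_improvement_stops_immediately(self):
        # seed chosen s.t. no noise candidate happens to lower AIC
        for seed in range(20):
            y, X, off = self._sim(seed)
            tr = forward_select(
                y, np.ones((56, 1)), {c: X[c] for c in X}, fit_poisson, off
            )
            if tr.best_variables == ():
                assert len(tr.rounds) == 2  # base record + one candidate round
                return
        pytest.fail("expected at least one all-null selection in 20 seeds")

    def test_active_covariate_selected_first(self):
        hits = 0
        R = 200
        for seed in range(R):
            y, X, off = self._sim(seed, beta_econ=0.2)
            tr = forward_select(
                y, np.ones((56, 1)), {c: X[c] for c in X}, fit_poisson, off
            )
            hits += bool(tr.best_variables) and tr.best_variables[0] == "ECON"
        assert hits / R >= 0.9

    def test_trace_round_shapes(self):
        y, X, off = self._sim(0, beta_econ=0.2)
        tr = forward_select(
            y, np.ones((56, 1)), {c: X[c] for c in X}, fit_poisson, off
        )
        sizes = [len(r) for r in tr.rounds[1:]]
        assert sizes == [3, 2, 1][: len(sizes)]

    def test_candidates_overlapping_base_rejected(self):
        y, X, off = self._sim(1)
        base = pd.DataFrame({"intercept": np.ones(56), "ECON": X["ECON"]})
        with pytest.raises(ValueError, match="overlap"):
            forward_select(y, base, {"ECON": X["ECON"]}, fit_poisson, off)

    def test_loglik_monotone_in_nested_models(self):
        y, X, off = self._sim(2, beta_econ=0.15)
        Xd = pd.DataFrame({"intercept": np.ones(56)})
        last = -np.inf
        for c in ["ECON", "MIG", "FRAG"]:
            Xd[c] = X[c]
            fit = fit_poisson(y, Xd, off)
            assert fit.loglik >= last - 1e-8
            last = fit.loglik
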