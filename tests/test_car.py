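import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from carmap.car import (
    CARFit,
    CARModelSpec,
    MCMCConfig,
    car_precision,
    dic,
    fit_car,
    geweke_z,
    smoothed_rr,
)
from carmap.freq import fit_poisson
from carmap.lattice import AreaLattice


def path_graph(n):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


class TestPrecision:
    def test_leroux_limits(self, grid12):
        np.testing.assert_allclose(
            car_precision("LER", grid12.W, 0.0), np.eye(12)
        )
        D = np.diag(grid12.degrees)
        np.testing.assert_allclose(
            car_precision("LER", grid12.W, 1.0), D - grid12.W
        )
        np.testing.assert_allclose(car_precision("IAR", grid12.W), D - grid12.W)

    def test_three_area_path_hand_value(self):
        Q = car_precision("LER", path_graph(3), 0.5)
        np.testing.assert_allclose(
            Q, [[1.0, -0.5, 0.0], [-0.5, 1.5, -0.5], [0.0, -0.5, 1.0]]
        )

    def test_bym_returns_both_parts(self, grid12):
        Qs, Qu = car_precision("BYM", grid12.W)
        np.testing.assert_allclose(Qu, np.eye(12))
        np.testing.assert_allclose(Qs, np.diag(grid12.degrees) - grid12.W)

    def test_disconnected_iar_warns(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        with pytest.warns(UserWarning, match="disconnected"):
            car_precision("IAR", W)

    def test_invalid_rho(self, grid12):
        with pytest.raises(ValueError):
            car_precision("LER", grid12.W, 1.5)


def _toy():
    """3-area toy: counts, offsets and a path adjacency, frozen for oracles."""
    y = np.array([2.0, 5.0, 1.0])
    n = np.array([120.0, 150.0, 90.0])
    return y, np.log(n), path_graph(3)


def grid_integration_posterior_mean(y, offset, sigma2, beta_var=1e5):
    """Exact posterior mean of the intercept under the IND model.

    Brute-force oracle: the exchangeable random effects integrate out
    area-by-area with Gauss-Hermite quadrature, leaving a one-dimensional
    integral over the intercept evaluated on a dense grid.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    t = np.sqrt(2 * sigma2) * nodes  # theta values; weights /= sqrt(pi)
    b = np.linspace(-8.0, 0.0, 4001)
    log_post = -0.5 * b**2 / beta_var
    for yk, ok in zip(y, offset):
        lam = np.exp(ok + b[:, None] + t[None, :])
        like = np.exp(yk * np.log(lam) - lam - gammaln(yk + 1))
        log_post += np.log((like * weights).sum(axis=1) / np.sqrt(np.pi))
    post = np.exp(log_post - log_post.max())
    post /= np.trapezoid(post, b)
    return np.trapezoid(b * post, b)


class TestFitCar:
    def test_posterior_concentrates_on_ml_when_effects_off(self, dataset56, design56):
        """Degenerate random-effect prior: posterior mean ~ Poisson ML."""
        X, off = design56
        ml = fit_poisson(dataset56.y, X, off)
        fit = fit_car(
            CARModelSpec("IND", sigma2_fixed=0.0),
            dataset56.y, X, off, dataset56.lattice.W,
            MCMCConfig(n_burnin=2000, n_keep=4000, thin=2, seed=0),
        )
        post_mean = fit.chains["beta"].mean(axis=0)
        np.testing.assert_allclose(post_mean, ml.params.to_numpy(), atol=0.02)

    def test_matches_grid_integration_oracle(self):
        """3-area toy: MCMC intercept mean vs dense numerical integration."""
        import arviz

        y, off, W = _toy()
        oracle = grid_integration_posterior_mean(y, off, sigma2=0.25)
        fit = fit_car(
            CARModelSpec("IND", sigma2_fixed=0.25),
            y, pd.DataFrame({"intercept": np.ones(3)}), off, W,
            MCMCConfig(n_burnin=3000, n_keep=6000, thin=5, seed=1),
        )
        chain = fit.chains["beta"][:, 0]
        mcse = chain.std() / np.sqrt(arviz.ess(chain))
        assert abs(chain.mean() - oracle) < 3 * mcse

    def test_fixed_seed_reproduces_chains(self, dataset56, design56):
        X, off = design56
        kw = dict(n_burnin=200, n_keep=300, thin=1, seed=7)
        a = fit_car(CARModelSpec("LER"), dataset56.y, X, off,
                    dataset56.lattice.W, MCMCConfig(**kw))
        b = fit_car(CARModelSpec("LER"), dataset56.y, X, off,
                    dataset56.lattice.W, MCMCConfig(**kw))
        for key in a.chains:
            np.testing.assert_array_equal(a.chains[key], b.chains[key])

    def test_fitted_totals_track_observed(self, dataset56, design56):
        X, off = design56
        fit = fit_car(
            CARModelSpec("LER"), dataset56.y, X, off, dataset56.lattice.W,
            MCMCConfig(n_burnin=1000, n_keep=2000, thin=1, seed=2),
        )
        assert abs(fit.fitted.sum() - dataset56.y.sum()) / dataset56.y.sum() < 0.05

    def test_missing_intercept_rejected(self, dataset56):
        X = pd.DataFrame({"ECON": dataset56.covariates["ECON"]})
        with pytest.raises(ValueError, match="intercept"):
            fit_car(CARModelSpec("IAR"), dataset56.y, X, dataset56.offset,
                    dataset56.lattice.W, MCMCConfig(n_burnin=10, n_keep=10, thin=1))

    def test_credible_interval_contains_median(self, dataset56, design56):
        X, off = design56
        fit = fit_car(
            CARModelSpec("LER"), dataset56.y, X, off, dataset56.lattice.W,
            MCMCConfig(n_burnin=500, n_keep=1000, thin=1, seed=3),
        )
        lo, hi = np.percentile(fit.chains["rho"], [2.5, 97.5])
        assert lo <= np.median(fit.chains["rho"]) <= hi
        assert fit.chains["rho"].shape == (1000,)


def _degenerate_fit(mu_row, y):
    """CARFit whose chains repeat a single posterior draw."""
    S = 50
    n = len(y)
    mu = np.tile(mu_row, (S, 1))
    dev = np.full(
        S, float(-2 * np.sum(y * np.log(mu_row) - mu_row - gammaln(y + 1)))
    )
    X = pd.DataFrame({"intercept": np.ones(n)})
    beta = np.tile(np.log(mu_row.mean()), (S, 1))
    # chains constructed so the plug-in deviance equals the sampled one
    return CARFit(
        structure="IND",
        chains={"beta": beta, "theta": np.tile(np.log(mu_row) - beta[0, 0], (S, 1))},
        mu=mu,
        deviance=dev,
        dic=np.nan,
        p_d=np.nan,
        geweke=pd.Series(dtype=float),
        acceptance={},
        variables=("intercept",),
        y=np.asarray(y, dtype=float),
        X=X,
        offset=np.zeros(n),
    )


class TestDic:
    def test_degenerate_chain_has_zero_pd(self):
        y = np.array([3.0, 6.0, 2.0])
        fit = _degenerate_fit(np.array([3.5, 5.5, 2.5]), y)
        d, p_d = dic(fit)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert d == pytest.approx(fit.deviance[0], abs=1e-9)

    def test_true_covariate_lowers_dic(self, grid56):
        """Adding a real effect (0.2/SD) lowers DIC in most replicates."""
        from carmap.synthetic import (
            GenerativeTruth, simulate_counts, simulate_covariates,
            simulate_population,
        )

        wins = 0
        R = 25
        for s in range(R):
            pop = simulate_population(grid56, seed=s)
            X = simulate_covariates(grid56, 0.0, seed=s)
            truth = GenerativeTruth(
                beta=np.array([np.log(358 / 109397), 0.2, 0.0, 0.0]),
                rho=0.0, tau2=0.0, sigma2_unstructured=0.05,
            )
            y, _ = simulate_counts(truth, pop, X, grid56, seed=s)
            off = np.log(pop.totals.astype(float))
            base = pd.DataFrame({"intercept": np.ones(56)})
            with_cov = base.copy()
            with_cov["ECON"] = X["ECON"].to_numpy()
            cfg = dict(n_burnin=500, n_keep=800, thin=1)
            f0 = fit_car(CARModelSpec("IND"), y, base, off, grid56.W,
                         MCMCConfig(seed=2 * s, **cfg))
            f1 = fit_car(CARModelSpec("IND"), y, with_cov, off, grid56.W,
                         MCMCConfig(seed=2 * s + 1, **cfg))
            wins += f1.dic < f0.dic
        assert wins / R >= 0.8


class TestGeweke:
    def test_identical_segments_give_zero(self):
        seg = np.sin(np.arange(500)) + np.linspace(0, 1, 500)
        chain = np.concatenate([seg, seg])
        assert geweke_z(chain, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_null_calibration(self):
        """iid chains: |Z| < 1.96 about 95% of the time."""
        rng = np.random.default_rng(0)
        inside = sum(
            abs(geweke_z(rng.standard_normal(10000))) < 1.96 for _ in range(300)
        )
        assert 0.91 <= inside / 300 <= 0.99

    def test_trend_detected(self):
        chain = np.linspace(0.0, 1.0, 5000) + np.random.default_rng(1).normal(
            0, 0.05, 5000
        )
        assert abs(geweke_z(chain)) > 1.96

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            geweke_z(np.arange(50.0))
        with pytest.raises(ValueError, match="zero-variance"):
            geweke_z(np.ones(500))


class TestSmoothedRR:
    def test_all_samples_above_expected(self):
        y = np.array([5.0, 5.0])
        fit = _degenerate_fit(np.array([8.0, 9.0]), y)
        hs = smoothed_rr(fit, np.array([5.0, 5.0]))
        assert np.all(hs.table["exceedance"] == 1.0)
        assert np.all(hs.table["hotspot"])

    def test_symmetric_posterior_is_not_flagged(self):
        y = np.array([5.0])
        fit = _degenerate_fit(np.array([5.0]), y)
        # symmetric log-RR: half the samples above E, half below
        fit.mu = np.concatenate(
            [np.full((25, 1), 5.0 * 1.3), np.full((25, 1), 5.0 / 1.3)]
        )
        hs = smoothed_rr(fit, np.array([5.0]))
        assert hs.table["exceedance"].iloc[0] == pytest.approx(0.5)
        assert not hs.table["hotspot"].iloc[0]

    def test_hotspot_set_deterministic_given_chains(self, dataset56, design56):
        X, off = design56
        fit = fit_car(
            CARModelSpec("LER"), dataset56.y, X, off, dataset56.lattice.W,
            MCMCConfig(n_burnin=300, n_keep=500, thin=1, seed=4),
        )
        a = smoothed_rr(fit, dataset56.expected)
        b = smoothed_rr(fit, dataset56.expected)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_nonpositive_expected_rejected(self):
        fit = _degenerate_fit(np.array([2.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            smoothed_rr(fit, np.array([0.0]))


def test_invalid_specs_and_configs():
    with pytest.raises(ValueError):
        CARModelSpec("CARROT")
    with pytest.raises(ValueError):
        CARModelSpec("LER", rho_fixed=2.0)
    with pytest.raises(ValueError):
        MCMCConfig(n_burnin=0)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)
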