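"""Bayesian disease mapping with conditional autoregressive (CAR) priors.

Four random-effect structures for a Poisson log-linear model
``y_k ~ Poisson(exp(o_k + x_k' beta + effects_k))`` are provided:

IND
    exchangeable effects ``theta_k ~ N(0, sigma2)`` — no spatial structure;
    area risks shrink toward the overall mean.
IAR
    intrinsic autoregressive effects, precision ``tau2^-1 (D - W)`` — each
    area's conditional prior mean is the average of its neighbours.
BYM
    convolution of the IAR field and an exchangeable field.
LER
    the Leroux structure, precision ``tau2^-1 [rho (D - W) + (1 - rho) I]``
    with ``rho ~ U(0, 1)`` — a single mixing parameter interpolating between
    independence (rho = 0) and the intrinsic field (rho = 1), so the model
    carries separate parameters for overdispersion and for the strength of
    spatial dependence.

Inference is Metropolis-within-Gibbs: random-walk Metropolis for the
regression block and for each random-effect site (the Poisson likelihood is
non-conjugate), conjugate inverse-gamma draws for the variances, and a
logit-random-walk Metropolis step for ``rho`` using the exact
log-determinant of the Leroux precision via pre-computed eigenvalues of
``D - W``.  Random-effect sites are updated in vectorised blocks over a
proper graph colouring (sites of one colour are conditionally independent).
The structured field is constrained to sum to zero — recentred each sweep
with the mean transferred into the intercept so the likelihood is untouched
— which identifies the level for the improper IAR prior and keeps the
proper Leroux prior aligned with the same convention (its variance update
and mixing-parameter determinant therefore live on the sum-to-zero
subspace, rank ``n - 1``).  A joint amplitude move rescales the field and
its variance together to traverse the funnel-shaped (field, variance)
posterior efficiently at low counts.

Model comparison uses the deviance information criterion
``DIC = Dbar + p_D`` with ``p_D = Dbar - D(posterior mean)``, convergence is
assessed by Geweke's spectral Z diagnostic, and hotspots are areas whose
smoothed relative risk ``mu_k / E_k`` exceeds 1 with posterior probability
above 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .lattice import AreaLattice

__all__ = [
    "CARModelSpec",
    "MCMCConfig",
    "CARFit",
    "HotspotReport",
    "car_precision",
    "fit_car",
    "dic",
    "geweke_z",
    "smoothed_rr",
]

STRUCTURES = ("IND", "IAR", "BYM", "LER")


@dataclass(frozen=True)
class CARModelSpec:
    """Model structure and priors.

    Priors default to the weakly-informative ecosystem conventions:
    ``beta ~ N(0, 1e5)``, variances ``~ InverseGamma(1, 0.01)``,
    ``rho ~ Uniform(0, 1)``.  A variance or rho may be pinned (``*_fixed``)
    for limit checks and degenerate-prior experiments.
    """

    structure: str
    beta_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_rate: float = 0.01
    sigma2_shape: float = 1.0
    sigma2_rate: float = 0.01
    rho_fixed: float | None = None
    tau2_fixed: float | None = None
    sigma2_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.beta_var <= 0 or min(
            self.tau2_shape, self.tau2_rate, self.sigma2_shape, self.sigma2_rate
        ) <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.rho_fixed is not None and not 0.0 <= self.rho_fixed <= 1.0:
            raise ValueError("rho_fixed must lie in [0, 1]")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths, thinning and proposal tuning.

    ``n_keep`` counts retained samples; the sampler runs
    ``n_burnin + n_keep * thin`` sweeps.  Proposal scales adapt toward the
    target acceptance rates during burn-in only and are frozen afterwards to
    preserve detailed balance.
    """

    n_burnin: int = 20000
    n_keep: int = 10000
    thin: int = 10
    seed: int = 0
    beta_scale: float = 1.0
    phi_scale: float = 0.5
    rho_scale: float = 0.7
    rescale_scale: float = 0.3
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if min(self.n_burnin, self.n_keep) <= 0 or self.thin < 1:
            raise ValueError("chain lengths must be positive, thin >= 1")


def car_precision(structure: str, W: np.ndarray, rho: float | None = None):
    """Precision matrix (up to the variance factor) of a CAR structure.

    Returns ``Q`` for IND/IAR/LER and the pair ``(Q_spatial, Q_unstructured)``
    for BYM.  The IAR precision is singular (rank ``n - 1`` on a connected
    graph) and is used with a sum-to-zero constraint.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    D = np.diag(W.sum(axis=1))
    if structure == "IND":
        return np.eye(n)
    if structure == "IAR":
        lat = AreaLattice(W=W)
        if not lat.is_connected():
            warnings.warn("disconnected graph: IAR needs one constraint per component")
        return D - W
    if structure == "LER":
        if rho is None or not 0.0 <= rho <= 1.0:
            raise ValueError("LER precision needs rho in [0, 1]")
        return rho * (D - W) + (1.0 - rho) * np.eye(n)
    if structure == "BYM":
        return D - W, np.eye(n)
    raise ValueError(f"unknown structure {structure!r}")


def _poisson_deviance(y: np.ndarray, mu: np.ndarray, lgy1: np.ndarray) -> float:
    return float(-2.0 * np.sum(y * np.log(mu) - mu - lgy1))


@dataclass
class CARFit:
    """Posterior sample record of one CAR model fit."""

    structure: str
    chains: dict[str, np.ndarray]
    mu: np.ndarray  # (n_keep, n_areas) posterior fitted means
    deviance: np.ndarray
    dic: float
    p_d: float
    geweke: pd.Series
    acceptance: dict[str, float]
    variables: tuple[str, ...]
    y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    X: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    offset: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    spec: CARModelSpec | None = field(repr=False, default=None)
    config: MCMCConfig | None = field(repr=False, default=None)

    @property
    def criterion(self) -> float:
        return self.dic

    @property
    def fitted(self) -> np.ndarray:
        """Posterior mean fitted count per area."""
        return self.mu.mean(axis=0)

    def effect_table(self, conf_level: float = 0.95) -> pd.DataFrame:
        """Posterior summaries of ``exp(beta)`` (rate-ratio scale)."""
        lo = 100 * (0.5 - conf_level / 2)
        B = self.chains["beta"]
        return pd.DataFrame(
            {
                "estimate": B.mean(axis=0),
                "exp_estimate": np.exp(B).mean(axis=0),
                "ci_low": np.exp(np.percentile(B, lo, axis=0)),
                "ci_high": np.exp(np.percentile(B, 100 - lo, axis=0)),
            },
            index=list(self.X.columns),
        )

    def credible_interval(self, param: str, level: float = 0.95) -> tuple:
        lo = 100 * (0.5 - level / 2)
        c = self.chains[param]
        return tuple(np.percentile(c, [lo, 100 - lo], axis=0).T.tolist())

    def chains_frame(self) -> pd.DataFrame:
        """Retained scalar chains, one column per parameter."""
        cols = {}
        for j, name in enumerate(self.X.columns):
            cols[f"beta_{name}"] = self.chains["beta"][:, j]
        for key in ("tau2", "sigma2", "rho"):
            if key in self.chains:
                cols[key] = self.chains[key]
        cols["deviance"] = self.deviance
        return pd.DataFrame(cols)


def _find_intercept(X: pd.DataFrame) -> int:
    for j, c in enumerate(X.columns):
        col = X.iloc[:, j].to_numpy(dtype=float)
        if np.all(col == col[0]) and col[0] != 0:
            return j
    return -1


def fit_car(
    spec: CARModelSpec,
    y,
    X,
    offset,
    W,
    config: MCMCConfig | None = None,
) -> CARFit:
    """Fit one CAR disease-mapping model by Metropolis-within-Gibbs MCMC.

    ``X`` must contain an explicit intercept column (needed to identify the
    level of improper random-effect fields).  Reproducible under a fixed
    ``config.seed``.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).copy()
    Xm = X.to_numpy(dtype=float)
    offset = np.asarray(offset, dtype=float)
    W = np.asarray(W, dtype=float)
    lattice = AreaLattice(W=W)
    n, p = Xm.shape
    d = lattice.degrees
    DW = np.diag(d) - W
    colors = lattice.coloring()
    lgy1 = gammaln(y + 1.0)

    has_phi = spec.structure in ("IAR", "BYM", "LER")
    has_theta = spec.structure in ("IND", "BYM")
    is_ler = spec.structure == "LER"
    rho = (
        (spec.rho_fixed if spec.rho_fixed is not None else 0.5) if is_ler
        else (1.0 if spec.structure in ("IAR", "BYM") else 0.0)
    )
    sample_rho = is_ler and spec.rho_fixed is None
    # The structured field lives in the sum-to-zero subspace (recentred each
    # sweep, mean absorbed by the intercept), so its prior has rank n - 1.
    i0 = _find_intercept(X)
    if has_phi and i0 < 0:
        raise ValueError("CAR structures need an intercept column in X")
    if sample_rho:
        # Nonzero spectrum of D - W: on the sum-to-zero subspace
        # log det Q(rho) = sum_i log(rho*lam_i + 1 - rho) over lam_i > 0.
        lam = np.linalg.eigvalsh(DW)
        lam = lam[lam > 1e-10]

    # Initial state from the Poisson ML fit; its covariance shapes the beta proposal.
    from .freq import fit_poisson

    glm = fit_poisson(y, X, offset)
    beta = glm.params.to_numpy().copy()
    import statsmodels.api as sm

    cov = (
        sm.GLM(y, Xm, family=sm.families.Poisson(), offset=offset)
        .fit()
        .cov_params()
    )
    Lb = np.linalg.cholesky(np.asarray(cov) + 1e-12 * np.eye(p))
    phi = np.zeros(n)
    theta = np.zeros(n)
    tau2 = spec.tau2_fixed if spec.tau2_fixed is not None else 0.1
    sigma2 = spec.sigma2_fixed if spec.sigma2_fixed is not None else 0.1

    Xb = Xm @ beta
    eta = offset + Xb + phi + theta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite posterior density at initialization")

    s_beta, s_phi, s_rho = config.beta_scale, config.phi_scale, config.rho_scale
    s_scale = config.rescale_scale
    acc = {"beta": 0, "phi": 0, "rho": 0, "scale": 0}
    tries = {"beta": 0, "phi": 0, "rho": 0, "scale": 0}
    acc_win = dict.fromkeys(acc, 0)
    tries_win = dict.fromkeys(acc, 0)

    n_keep, thin = config.n_keep, config.thin
    n_iter = config.n_burnin + n_keep * thin
    keep_beta = np.empty((n_keep, p))
    keep_phi = np.empty((n_keep, n)) if has_phi else None
    keep_theta = np.empty((n_keep, n)) if has_theta else None
    keep_tau2 = np.empty(n_keep) if has_phi else None
    keep_sigma2 = np.empty(n_keep) if has_theta else None
    keep_rho = np.empty(n_keep) if is_ler else None
    keep_mu = np.empty((n_keep, n))
    keep_dev = np.empty(n_keep)

    def loglik(eta_):
        return np.sum(y * eta_ - np.exp(eta_))

    kept = 0
    for it in range(n_iter):
        # --- beta block (random-walk Metropolis on the ML covariance shape)
        prop = beta + s_beta * (Lb @ rng.standard_normal(p))
        Xb_prop = Xm @ prop
        eta_prop = offset + Xb_prop + phi + theta
        delta = (
            loglik(eta_prop)
            - loglik(eta)
            - 0.5 * (prop @ prop - beta @ beta) / spec.beta_var
        )
        tries["beta"] += 1
        tries_win["beta"] += 1
        if np.log(rng.random()) < delta:
            beta, Xb, eta = prop, Xb_prop, eta_prop
            acc["beta"] += 1
            acc_win["beta"] += 1

        # --- structured field phi, colour-blocked single-site Metropolis
        if has_phi and tau2 > 0:
            for S in colors:
                Wphi = W @ phi
                if is_ler:
                    prec = (rho * d[S] + (1.0 - rho)) / tau2
                    m = rho * Wphi[S] / (rho * d[S] + (1.0 - rho))
                else:
                    prec = d[S] / tau2
                    m = Wphi[S] / d[S]
                cur = phi[S]
                prop_s = cur + s_phi * rng.standard_normal(S.size)
                eta_S = eta[S]
                dlog = (
                    y[S] * (prop_s - cur)
                    - (np.exp(eta_S + prop_s - cur) - np.exp(eta_S))
                    - 0.5 * prec * ((prop_s - m) ** 2 - (cur - m) ** 2)
                )
                accept = np.log(rng.random(S.size)) < dlog
                phi[S] = np.where(accept, prop_s, cur)
                eta[S] = np.where(accept, eta_S + prop_s - cur, eta_S)
                acc["phi"] += int(accept.sum())
                acc_win["phi"] = acc_win.get("phi", 0) + int(accept.sum())
                tries["phi"] += S.size
                tries_win["phi"] = tries_win.get("phi", 0) + S.size
            # sum-to-zero constraint: recenter phi, absorb the mean in the
            # intercept (likelihood-invariant)
            shift = phi.mean()
            phi -= shift
            beta[i0] += shift / Xm[0, i0]
            Xb = Xm @ beta

        # --- unstructured field theta (independent prior: fully vectorised)
        if has_theta and sigma2 > 0:
            cur = theta
            prop_t = cur + s_phi * rng.standard_normal(n)
            dlog = (
                y * (prop_t - cur)
                - (np.exp(eta + prop_t - cur) - np.exp(eta))
                - 0.5 * ((prop_t**2) - (cur**2)) / sigma2
            )
            accept = np.log(rng.random(n)) < dlog
            eta = np.where(accept, eta + prop_t - cur, eta)
            theta = np.where(accept, prop_t, cur)

        # --- joint field-rescaling moves (phi* = c phi, tau2* = c^2 tau2).
        # The (field, variance) posterior is funnel-shaped at low counts;
        # single-site updates then traverse field amplitude very slowly.
        # This group move jumps amplitude directly.  The CAR prior exponent
        # is invariant under the map and the rank terms cancel, leaving
        #   log alpha = dloglik + (2 - 2(a+1)) log c - (b/tau2)(c^-2 - 1).
        if has_phi and spec.tau2_fixed is None:
            c = np.exp(s_scale * rng.standard_normal())
            eta_prop = eta + (c - 1.0) * phi
            dlog = (
                loglik(eta_prop) - loglik(eta)
                + (2.0 - 2.0 * (spec.tau2_shape + 1.0)) * np.log(c)
                - (spec.tau2_rate / tau2) * (c**-2 - 1.0)
            )
            tries["scale"] += 1
            tries_win["scale"] += 1
            if np.log(rng.random()) < dlog:
                phi = c * phi
                tau2 = c**2 * tau2
                eta = eta_prop
                acc["scale"] += 1
                acc_win["scale"] += 1
        if has_theta and spec.sigma2_fixed is None:
            c = np.exp(s_scale * rng.standard_normal())
            eta_prop = eta + (c - 1.0) * theta
            dlog = (
                loglik(eta_prop) - loglik(eta)
                + (2.0 - 2.0 * (spec.sigma2_shape + 1.0)) * np.log(c)
                - (spec.sigma2_rate / sigma2) * (c**-2 - 1.0)
            )
            if np.log(rng.random()) < dlog:
                theta = c * theta
                sigma2 = c**2 * sigma2
                eta = eta_prop

        # --- conjugate variance draws
        if has_phi and spec.tau2_fixed is None:
            if is_ler:
                quad = rho * (phi @ DW @ phi) + (1.0 - rho) * (phi @ phi)
            else:
                quad = phi @ DW @ phi
            # rank n - 1: the field is constrained to the sum-to-zero subspace
            tau2 = 1.0 / rng.gamma(spec.tau2_shape + (n - 1) / 2.0,
                                   1.0 / (spec.tau2_rate + quad / 2.0))
        if has_theta and spec.sigma2_fixed is None:
            sigma2 = 1.0 / rng.gamma(spec.sigma2_shape + n / 2.0,
                                     1.0 / (spec.sigma2_rate + theta @ theta / 2.0))

        # --- rho (Leroux mixing), logit random walk with exact log-determinant
        if sample_rho:
            qDW = phi @ DW @ phi
            qI = phi @ phi
            logit = np.log(rho / (1.0 - rho))
            logit_prop = logit + s_rho * rng.standard_normal()
            rho_prop = 1.0 / (1.0 + np.exp(-logit_prop))

            def rho_target(r):
                return (
                    0.5 * np.sum(np.log(r * lam + (1.0 - r)))
                    - (r * qDW + (1.0 - r) * qI) / (2.0 * tau2)
                    + np.log(r) + np.log(1.0 - r)  # Jacobian of the logit map
                )

            tries["rho"] += 1
            tries_win["rho"] += 1
            if np.log(rng.random()) < rho_target(rho_prop) - rho_target(rho):
                rho = rho_prop
                acc["rho"] += 1
                acc_win["rho"] += 1

        # --- adaptive scaling (burn-in only)
        if it < config.n_burnin and (it + 1) % config.adapt_interval == 0:
            if tries_win["beta"]:
                r = acc_win["beta"] / tries_win["beta"]
                s_beta *= np.exp(0.5 * (r - 0.35))
            if tries_win.get("phi"):
                r = acc_win["phi"] / tries_win["phi"]
                s_phi *= np.exp(0.5 * (r - 0.45))
            if tries_win["rho"]:
                r = acc_win["rho"] / tries_win["rho"]
                s_rho *= np.exp(0.5 * (r - 0.35))
            if tries_win["scale"]:
                r = acc_win["scale"] / tries_win["scale"]
                s_scale *= np.exp(0.5 * (r - 0.35))
            acc_win = dict.fromkeys(acc_win, 0)
            tries_win = dict.fromkeys(tries_win, 0)

        # --- record
        if it >= config.n_burnin and (it - config.n_burnin) % thin == thin - 1:
            mu = np.exp(eta)
            keep_beta[kept] = beta
            if has_phi:
                keep_phi[kept] = phi
                keep_tau2[kept] = tau2
            if has_theta:
                keep_theta[kept] = theta
                keep_sigma2[kept] = sigma2
            if is_ler:
                keep_rho[kept] = rho
            keep_mu[kept] = mu
            keep_dev[kept] = _poisson_deviance(y, mu, lgy1)
            kept += 1

    rates = {k: (acc[k] / tries[k] if tries[k] else np.nan) for k in acc}
    for k, r in rates.items():
        if np.isfinite(r) and not 0.05 < r < 0.95:
            warnings.warn(f"{k} acceptance rate {r:.2f} outside (0.05, 0.95)")

    chains: dict[str, np.ndarray] = {"beta": keep_beta}
    if has_phi:
        chains["phi"] = keep_phi
        chains["tau2"] = keep_tau2
    if has_theta:
        chains["theta"] = keep_theta
        chains["sigma2"] = keep_sigma2
    if is_ler:
        chains["rho"] = keep_rho

    fit = CARFit(
        structure=spec.structure,
        chains=chains,
        mu=keep_mu,
        deviance=keep_dev,
        dic=np.nan,
        p_d=np.nan,
        geweke=pd.Series(dtype=float),
        acceptance=rates,
        variables=tuple(X.columns),
        y=y,
        X=X,
        offset=offset,
        spec=spec,
        config=config,
    )
    fit.dic, fit.p_d = dic(fit)
    gz = {}
    for j, name in enumerate(X.columns):
        gz[f"beta_{name}"] = geweke_z(keep_beta[:, j])
    for key in ("tau2", "sigma2", "rho"):
        if key in chains and np.std(chains[key]) > 0:
            gz[key] = geweke_z(chains[key])
    fit.geweke = pd.Series(gz, dtype=float)
    return fit


def dic(fit: CARFit) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    ``DIC = Dbar + p_D`` with ``p_D = Dbar - D(thetabar)``; the plug-in
    deviance is evaluated at the posterior means of the regression and
    random-effect components.
    """
    if fit.deviance.size == 0:
        raise ValueError("empty chains")
    lgy1 = gammaln(fit.y + 1.0)
    d_bar = float(fit.deviance.mean())
    eta_bar = fit.offset + fit.X.to_numpy(dtype=float) @ fit.chains["beta"].mean(axis=0)
    if "phi" in fit.chains:
        eta_bar = eta_bar + fit.chains["phi"].mean(axis=0)
    if "theta" in fit.chains:
        eta_bar = eta_bar + fit.chains["theta"].mean(axis=0)
    d_hat = _poisson_deviance(fit.y, np.exp(eta_bar), lgy1)
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariances."""
    m = x.size
    xc = x - x.mean()
    L = max(1, int(np.sqrt(m)))
    g0 = float(xc @ xc) / m
    s = g0
    for lag in range(1, L + 1):
        g = float(xc[:-lag] @ xc[lag:]) / m
        s += 2.0 * (1.0 - lag / (L + 1.0)) * g
    return max(s, 1e-300)


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence Z: early-vs-late segment means over spectral SEs.

    ``Z = (mean_A - mean_B) / sqrt(S_A(0)/n_A + S_B(0)/n_B)`` with the
    first 10% and last 50% of the chain as segments; |Z| < 1.96 is the
    conventional no-evidence-against-convergence band.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("Geweke diagnostic needs a chain of length >= 100")
    if np.std(x) == 0:
        raise ValueError("zero-variance chain")
    a = x[: max(2, int(x.size * first_frac))]
    b = x[-max(2, int(x.size * last_frac)):]
    num = a.mean() - b.mean()
    den = np.sqrt(_spectral_var0(a) / a.size + _spectral_var0(b) / b.size)
    return float(num / den)


@dataclass
class HotspotReport:
    """Per-area smoothed relative risks and exceedance flags."""

    table: pd.DataFrame  # columns: rr_mean, exceedance, hotspot
    cutoff: float = 0.75

    @property
    def hotspots(self) -> np.ndarray:
        return np.nonzero(self.table["hotspot"].to_numpy())[0]

    def to_geojson(self, lattice: AreaLattice) -> dict:
        gj = lattice.to_geojson()
        for feat in gj["features"]:
            k = feat["id"]
            feat["properties"].update(
                rr_mean=float(self.table.loc[k, "rr_mean"]),
                exceedance=float(self.table.loc[k, "exceedance"]),
                hotspot=bool(self.table.loc[k, "hotspot"]),
            )
        return gj


def smoothed_rr(fit: CARFit, E, cutoff: float = 0.75) -> HotspotReport:
    """Smoothed relative risks, exceedance probabilities and hotspot flags.

    Per retained sample the relative risk is the fitted count over the
    expected count, ``RR_k = mu_k / E_k``; the exceedance probability is the
    posterior fraction of samples with ``RR_k > 1`` and an area is flagged a
    hotspot when that probability exceeds the cutoff (0.75 by convention).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    rr = fit.mu / E
    exceed = (rr > 1.0).mean(axis=0)
    table = pd.DataFrame(
        {"rr_mean": rr.mean(axis=0), "exceedance": exceed, "hotspot": exceed > cutoff}
    )
    return HotspotReport(table=table, cutoff=cutoff)
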