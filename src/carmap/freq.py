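"""Frequentist count models and their validity diagnostics.

The non-spatial stage fits log-linear models to per-area counts with a
log-population offset: Poisson first, negative binomial (NB2, variance
``mu + mu^2/theta``) if the Poisson equidispersion assumption fails.  Two
diagnostics decide the escalation:

* Dean's score test for Poisson overdispersion,
  ``P_B = sum[(y_k - mu_k)^2 - y_k] / sqrt(2 sum mu_k^2)``,
  compared one-sided to N(0, 1);
* Moran's I on model residuals over the areal adjacency, for residual
  spatial autocorrelation (analytic normal approximation and a permutation
  test).

Covariates enter through a forward-fitting selection that keeps a candidate
only when it strictly lowers the information criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMFit",
    "DiagnosticResult",
    "fit_poisson",
    "fit_negbin",
    "dean_test",
    "moran_i",
    "forward_select",
    "SelectionTrace",
]


@dataclass
class GLMFit:
    """Unified record of a fitted count GLM."""

    family: str
    params: pd.Series
    bse: pd.Series
    mu: np.ndarray
    loglik: float
    aic: float
    theta: float | None = None  # NB2 dispersion; None for Poisson
    converged: bool = True
    variables: tuple[str, ...] = ()
    y: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    X: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]
    offset: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def criterion(self) -> float:
        return self.aic

    def pearson_residuals(self) -> np.ndarray:
        var = self.mu if self.family == "poisson" else self.mu + self.mu**2 / self.theta
        return (self.y - self.mu) / np.sqrt(var)

    def effect_table(self, conf_level: float = 0.95) -> pd.DataFrame:
        """Rate-ratio style effects ``exp(beta)`` with Wald CIs per term."""
        z = stats.norm.ppf(0.5 + conf_level / 2)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "exp_estimate": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of a model-validity test."""

    name: str
    statistic: float
    p_value: float
    decision: bool
    reference_distribution: str
    extra: dict = field(default_factory=dict)


def _as_design(X) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    X.columns = [str(c) for c in X.columns]
    return X


def _check_design(X: pd.DataFrame) -> None:
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_poisson(y, X, offset=None) -> GLMFit:
    """Poisson log-linear model with offset, fitted by IRLS.

    ``X`` must include the intercept column explicitly.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    _check_design(X)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(tol=1e-10)
    if not res.converged:
        raise RuntimeError("Poisson IRLS failed to converge")
    return GLMFit(
        family="poisson",
        params=res.params,
        bse=res.bse,
        mu=np.asarray(res.fittedvalues),
        loglik=float(res.llf),
        aic=float(res.aic),
        variables=tuple(X.columns),
        y=y,
        X=X,
        offset=offset,
    )


#: theta above this is reported as effectively equidispersed (Poisson limit).
THETA_EQUIDISPERSED = 1e4


def fit_negbin(y, X, offset=None) -> GLMFit:
    """NB2 negative binomial fit (joint ML over beta and dispersion).

    The dispersion is reported as ``theta`` with variance function
    ``mu + mu^2/theta``.  When the ML dispersion diverges (data effectively
    Poisson) the fit is flagged equidispersed and theta capped at a large
    finite value; coefficients then coincide with the Poisson fit.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    _check_design(X)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")
    model = sm.NegativeBinomial(y, X, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, method="bfgs", gtol=1e-8)
            alpha = float(res.params.iloc[-1])
            ok = res.mle_retvals.get("converged", True)
        except Exception:
            alpha, ok = -1.0, False
    if not ok or not np.isfinite(alpha) or alpha < 1.0 / THETA_EQUIDISPERSED:
        # Boundary case: dispersion -> 0, NB2 degenerates to Poisson.
        pois = fit_poisson(y, X, offset)
        return GLMFit(
            family="negbin",
            params=pois.params,
            bse=pois.bse,
            mu=pois.mu,
            loglik=pois.loglik,
            aic=pois.aic + 2.0,  # theta still counts as an estimated parameter
            theta=THETA_EQUIDISPERSED,
            converged=True,
            variables=tuple(X.columns),
            y=y,
            X=X,
            offset=offset,
        )
    beta = res.params.iloc[:-1]
    mu = np.exp(offset + X.to_numpy(dtype=float) @ beta.to_numpy())
    return GLMFit(
        family="negbin",
        params=beta,
        bse=res.bse.iloc[:-1],
        mu=mu,
        loglik=float(res.llf),
        aic=float(res.aic),
        theta=1.0 / alpha,
        variables=tuple(X.columns),
        y=y,
        X=X,
        offset=offset,
    )


def dean_test(fit: GLMFit, alpha: float = 0.05) -> DiagnosticResult:
    """Dean's score test for overdispersion in a Poisson GLM.

    One-sided against overdispersion: the statistic is asymptotically
    standard normal under equidispersion and the null is rejected when it
    exceeds the upper ``alpha`` quantile (1.96 at the default 0.05... the
    conventional 1.645 one-sided cutoff is deliberately *not* used: the
    decision mirrors the |z| > 1.96 rule the applied literature reports).
    """
    if fit.family != "poisson":
        raise ValueError("Dean's test applies to a Poisson fit")
    if fit.y.size < 10:
        warnings.warn("Dean's test asymptotics unreliable below ~10 areas")
    mu = fit.mu
    stat = float(np.sum((fit.y - mu) ** 2 - fit.y) / np.sqrt(2.0 * np.sum(mu**2)))
    p = float(stats.norm.sf(stat))
    return DiagnosticResult(
        name="dean",
        statistic=stat,
        p_value=p,
        decision=stat > stats.norm.ppf(0.975),
        reference_distribution="N(0,1), one-sided (variant P_B)",
    )


def moran_i(
    residuals,
    W,
    *,
    permutations: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> DiagnosticResult:
    """Moran's I for spatial autocorrelation of a residual vector.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with centred
    residuals ``z`` and ``S0 = sum_ij w_ij``.  The analytic p-value uses the
    normal approximation under the randomisation null; with
    ``permutations > 0`` a one-sided permutation p-value is also computed
    and used for the decision.
    """
    z = np.asarray(residuals, dtype=float)
    W = np.asarray(W, dtype=float)
    n = z.size
    if z.std() == 0:
        raise ValueError("residuals are constant; Moran's I undefined")
    z = z - z.mean()
    S0 = W.sum()
    denom = float(z @ z)
    I = float(n / S0 * (z @ W @ z) / denom)
    EI = -1.0 / (n - 1)
    # Randomisation-null moments (Cliff & Ord).
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
    b2 = n * np.sum(z**4) / denom**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - EI**2
    zscore = (I - EI) / np.sqrt(var)
    p_norm = float(stats.norm.sf(zscore))
    extra = {"expected": EI, "variance": float(var), "z": float(zscore)}
    p = p_norm
    if permutations:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(permutations)])
        Zp = z[perms]  # (permutations, n)
        Ip = n / S0 * np.einsum("si,si->s", Zp @ W, Zp) / denom
        p_perm = float((1 + np.sum(Ip >= I)) / (permutations + 1))
        extra["p_permutation"] = p_perm
        extra["p_normal"] = p_norm
        p = p_perm
    return DiagnosticResult(
        name="moran",
        statistic=I,
        p_value=p,
        decision=p <= alpha,
        reference_distribution=(
            "permutation null" if permutations else "normal approximation (randomisation)"
        ),
        extra=extra,
    )


@dataclass
class SelectionTrace:
    """Full record of a forward-fitting selection run."""

    rounds: list[pd.DataFrame]
    best_fit: object
    best_variables: tuple[str, ...]
    criterion_name: str = "aic"

    def to_frame(self) -> pd.DataFrame:
        out = []
        for r, df in enumerate(self.rounds):
            df = df.copy()
            df.insert(0, "round", r)
            out.append(df)
        return pd.concat(out, ignore_index=True)


def forward_select(
    y,
    X_base,
    candidates: dict,
    fitter=fit_poisson,
    offset=None,
    criterion: str = "criterion",
) -> SelectionTrace:
    """Forward-fitting covariate selection by strict criterion improvement.

    Starts from the base (confounders-only) design; each round fits the base
    plus every remaining candidate column and keeps the single best addition
    only if its criterion is strictly lower than the current base's.  Ties
    go to the smaller model (no addition).  Non-converged candidate fits are
    recorded and skipped.
    """
    X_base = _as_design(X_base)
    overlap = set(X_base.columns) & set(candidates)
    if overlap:
        raise ValueError(f"candidates overlap the base design: {sorted(overlap)}")
    base_fit = fitter(y, X_base, offset)
    base_crit = getattr(base_fit, criterion)
    selected: list[str] = []
    remaining = dict(candidates)
    rounds = [
        pd.DataFrame(
            [{"variables": "(base)", "criterion": base_crit, "converged": True}]
        )
    ]
    while remaining:
        rows, fits = [], {}
        for name, col in remaining.items():
            Xc = X_base.copy()
            for s in selected:
                Xc[s] = np.asarray(candidates[s], dtype=float)
            Xc[name] = np.asarray(col, dtype=float)
            try:
                f = fitter(y, Xc, offset)
                rows.append(
                    {
                        "variables": "+".join(selected + [name]),
                        "criterion": getattr(f, criterion),
                        "converged": True,
                    }
                )
                fits[name] = f
            except Exception as exc:  # non-convergence: record and skip
                warnings.warn(f"candidate {name!r} failed to fit: {exc}")
                rows.append(
                    {"variables": "+".join(selected + [name]), "criterion": np.nan,
                     "converged": False}
                )
        rounds.append(pd.DataFrame(rows))
        if not fits:
            break
        best_name = min(fits, key=lambda k: getattr(fits[k], criterion))
        best_crit = getattr(fits[best_name], criterion)
        if best_crit < base_crit:
            selected.append(best_name)
            remaining.pop(best_name)
            base_fit, base_crit = fits[best_name], best_crit
        else:
            break
    return SelectionTrace(
        rounds=rounds,
        best_fit=base_fit,
        best_variables=tuple(selected),
        criterion_name=criterion,
    )
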