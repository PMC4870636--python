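"""Synthetic small-area datasets with known generative parameters.

The generator mirrors the data-generating process the analysis assumes: a
lattice of ~2000-resident areas, counts drawn as

    y_k ~ Poisson( exp( log n_k + x_k' beta + phi_k [+ theta_k] ) ),

with ``phi`` a Leroux conditional-autoregressive Gaussian field (spatial
dependence ``rho``, variance ``tau2``) under a sum-to-zero constraint, and
``theta`` optional exchangeable noise (variance ``sigma2``).  Because the
true ``beta``, ``rho``, ``tau2`` are known, every downstream stage —
standardization, GLM diagnostics, MCMC smoothing, model selection — can be
tested for recovery and calibration without any external data.

Default parameter values reproduce the catchment conditions of the packaged
fixture: 53-ish areas (7x8 grid), populations ~2064 +/- 705, crude treated
prevalence 358/109397, a deprivation log-rate-ratio of 0.12 per SD, and a
strongly spatial residual field (rho 0.8, tau2 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import STRATA, AreaDataset, StratifiedPopulation, table1_strata
from .lattice import AreaLattice, LatticeSpec, make_grid_adjacency
from .standardize import catchment_stratum_prevalence, expected_counts

__all__ = [
    "GenerativeTruth",
    "simulate_population",
    "simulate_covariates",
    "sample_car_field",
    "simulate_counts",
    "simulate_dataset",
]

#: Crude treated prevalence of the packaged catchment fixture (358 / 109397).
DEFAULT_PREVALENCE = 358.0 / 109397.0

COVARIATE_NAMES = ("ECON", "MIG", "FRAG")


@dataclass(frozen=True)
class GenerativeTruth:
    """True parameters of the synthetic data-generating process.

    ``beta`` holds the intercept followed by one log-rate-ratio per SD for
    each covariate column (ECON, MIG, FRAG).
    """

    beta: np.ndarray = None  # type: ignore[assignment]
    rho: float = 0.8
    tau2: float = 0.3
    sigma2_unstructured: float = 0.0
    baseline_prevalence: float = DEFAULT_PREVALENCE

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.tau2 < 0 or self.sigma2_unstructured < 0:
            raise ValueError("variances must be nonnegative")
        beta = self.beta
        if beta is None:
            beta = np.array([np.log(self.baseline_prevalence), 0.12, 0.0, 0.0])
        beta = np.asarray(beta, dtype=float)
        if beta.ndim != 1 or not np.all(np.isfinite(beta)):
            raise ValueError("beta must be a finite vector")
        object.__setattr__(self, "beta", beta)


def _default_strata_dirichlet() -> np.ndarray:
    # Concentration proportional to the catchment stratum shares; total
    # concentration 200 gives mild area-to-area variation in age structure.
    shares = table1_strata()["population"].to_numpy(dtype=float)
    return 200.0 * shares / shares.sum()


def simulate_population(
    lattice: AreaLattice,
    mean_pop: float = 2064.0,
    sd_pop: float = 705.0,
    strata_dirichlet=None,
    seed: int = 0,
) -> StratifiedPopulation:
    """Draw per-area populations and allocate them to adjustment strata.

    Totals are lognormal with moments matched to ``(mean_pop, sd_pop)``
    (positive and right-skewed, as census area populations are), rounded to
    integers >= 1.  Strata are allocated Dirichlet-multinomially around the
    catchment age/gender composition.
    """
    if mean_pop <= 0:
        raise ValueError("mean_pop must be positive")
    if sd_pop < 0:
        raise ValueError("sd_pop must be nonnegative")
    rng = np.random.default_rng(seed)
    n = lattice.n_areas
    if sd_pop == 0:
        totals = np.full(n, max(1, round(mean_pop)), dtype=int)
    else:
        s2 = np.log1p((sd_pop / mean_pop) ** 2)
        mu = np.log(mean_pop) - s2 / 2.0
        totals = np.maximum(1, np.rint(rng.lognormal(mu, np.sqrt(s2), size=n))).astype(int)
    alpha = (
        np.asarray(strata_dirichlet, dtype=float)
        if strata_dirichlet is not None
        else _default_strata_dirichlet()
    )
    if alpha.shape != (len(STRATA),) or np.any(alpha <= 0):
        raise ValueError("strata_dirichlet must be a positive vector over the 5 strata")
    shares = rng.dirichlet(alpha, size=n)
    counts = np.empty((n, len(STRATA)), dtype=int)
    for k in range(n):
        counts[k] = rng.multinomial(totals[k], shares[k])
        if counts[k].sum() == 0:  # pragma: no cover - totals >= 1
            counts[k, -1] = 1
    return StratifiedPopulation(counts=counts)


def sample_car_field(
    lattice: AreaLattice, rho: float, tau2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one Leroux CAR field phi ~ N(0, tau2 * Q(rho)^-1), sum-to-zero.

    ``Q(rho) = rho (D - W) + (1 - rho) I``.  At ``rho = 1`` the precision is
    the (singular) intrinsic autoregressive one; the draw is then taken in
    the subspace orthogonal to the null vector.
    """
    if tau2 == 0:
        return np.zeros(lattice.n_areas)
    W = lattice.W
    n = lattice.n_areas
    Q = rho * (np.diag(lattice.degrees) - W) + (1.0 - rho) * np.eye(n)
    z = rng.standard_normal(n)
    if rho >= 1.0:
        lam, U = np.linalg.eigh(Q)
        keep = lam > 1e-10
        phi = U[:, keep] @ (z[keep] / np.sqrt(lam[keep]))
    else:
        L = np.linalg.cholesky(Q)
        phi = np.linalg.solve(L.T, z)
    phi = np.sqrt(tau2) * phi
    return phi - phi.mean()


def simulate_covariates(
    lattice: AreaLattice, spatial_corr: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """Spatially smooth covariate columns, each Z-scored across areas.

    Columns are drawn independently from a proper CAR Gaussian field with
    dependence ``spatial_corr`` and then standardized to mean 0, SD 1
    (population SD), matching the Z-score convention of the ecological
    indices.
    """
    if not 0.0 <= spatial_corr < 1.0:
        raise ValueError("spatial_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in COVARIATE_NAMES:
        x = (
            sample_car_field(lattice, spatial_corr, 1.0, rng)
            if spatial_corr > 0
            else rng.standard_normal(lattice.n_areas)
        )
        cols[name] = (x - x.mean()) / x.std()
    return pd.DataFrame(cols)


def simulate_counts(
    truth: GenerativeTruth,
    population: StratifiedPopulation,
    X: pd.DataFrame,
    lattice: AreaLattice,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-area case counts from the generative model.

    Returns ``(y, stratum_cases)`` where ``stratum_cases`` are catchment
    stratum case totals obtained by splitting each area's cases across its
    strata proportionally to the stratum populations (the generator has no
    age/gender effect, so within-area rates are uniform); these totals feed
    internal indirect standardization exactly as stratum-tagged cases would.
    """
    rng = np.random.default_rng(seed)
    n = lattice.n_areas
    Xm = np.asarray(X, dtype=float)
    if Xm.shape != (n, truth.beta.size - 1):
        raise ValueError("covariate matrix misaligned with beta/lattice")
    eta = (
        np.log(population.totals.astype(float))
        + truth.beta[0]
        + Xm @ truth.beta[1:]
        + sample_car_field(lattice, truth.rho, truth.tau2, rng)
    )
    if truth.sigma2_unstructured > 0:
        eta = eta + rng.normal(0.0, np.sqrt(truth.sigma2_unstructured), size=n)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor in simulation")
    y = rng.poisson(np.exp(eta))
    shares = population.counts / population.totals[:, None]
    stratum_cases = np.zeros(len(population.strata), dtype=int)
    for k in range(n):
        if y[k] > 0:
            stratum_cases += rng.multinomial(y[k], shares[k])
    return y, stratum_cases


def simulate_dataset(
    spec: LatticeSpec | None = None,
    truth: GenerativeTruth | None = None,
    mean_pop: float = 2064.0,
    sd_pop: float = 705.0,
    spatial_corr: float = 0.5,
    seed: int = 0,
) -> AreaDataset:
    """End-to-end synthetic dataset: lattice, population, covariates, counts, E_k.

    The default 7x8 rook grid (56 areas) is the nearest rectangular stand-in
    for the 53-area catchment.  Expected counts are computed by internal
    indirect standardization so the dataset arrives analysis-ready.
    """
    spec = spec if spec is not None else LatticeSpec(7, 8, "rook", seed)
    truth = truth if truth is not None else GenerativeTruth()
    lattice = make_grid_adjacency(spec)
    ss = np.random.SeedSequence(seed)
    s_pop, s_cov, s_y = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    population = simulate_population(lattice, mean_pop, sd_pop, seed=s_pop)
    X = simulate_covariates(lattice, spatial_corr, seed=s_cov)
    y, stratum_cases = simulate_counts(truth, population, X, lattice, seed=s_y)
    prev = catchment_stratum_prevalence(population, stratum_cases)
    E = expected_counts(population, prev)
    return AreaDataset(
        y=y,
        population=population,
        covariates=X,
        lattice=lattice,
        expected=E,
        stratum_cases=stratum_cases,
        truth={
            "beta": truth.beta.tolist(),
            "rho": truth.rho,
            "tau2": truth.tau2,
            "sigma2_unstructured": truth.sigma2_unstructured,
            "baseline_prevalence": truth.baseline_prevalence,
            "seed": seed,
        },
    )
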