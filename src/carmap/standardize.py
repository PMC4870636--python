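"""Indirect standardization and ecological index construction.

Expected counts are obtained by *internal* indirect standardization: the
catchment-wide prevalence in each adjustment stratum (age-band x gender
group) is applied to each area's stratum denominators,

    E_k = sum_g n_kg * p_g,      p_g = (catchment cases in g) / (catchment pop in g).

Because the stratum rates come from the same data, the identity
``sum_k E_k == sum_k y_k`` holds exactly; the ratio ``y_k / E_k`` is the
prevalence rate ratio (the SMR analogue for prevalence data).

Ecological deprivation/migration/fragmentation indices are composites of two
per-area proportions, each standardized to a Z-score across areas and summed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import STRATA, StratifiedPopulation

__all__ = [
    "stratum_prevalence",
    "expected_counts",
    "prevalence_rate_ratio",
    "zscore",
    "composite_index",
    "adjustment_design",
]


def stratum_prevalence(
    cases, pop, *, strata=None, ci: bool = False, conf_level: float = 0.95
) -> pd.DataFrame:
    """Prevalence (%) per stratum, optionally with a Wilson score interval.

    Parameters
    ----------
    cases, pop
        Stratum case counts and populations at risk, aligned.
    strata
        Optional stratum labels for the index and for error messages.

    Returns
    -------
    DataFrame with columns ``cases, population, prevalence_pct`` and, when
    ``ci`` is set, ``ci_low_pct, ci_high_pct``.
    """
    cases = np.asarray(cases, dtype=float)
    pop = np.asarray(pop, dtype=float)
    labels = list(strata) if strata is not None else list(range(len(cases)))
    bad = np.nonzero(pop <= 0)[0]
    if bad.size:
        raise ValueError(f"zero population at risk in stratum {labels[bad[0]]!r}")
    prev = 100.0 * cases / pop
    out = pd.DataFrame(
        {"cases": cases.astype(int), "population": pop.astype(int), "prevalence_pct": prev},
        index=labels,
    )
    if ci:
        z = stats.norm.ppf(0.5 + conf_level / 2)
        p = cases / pop
        denom = 1 + z**2 / pop
        centre = (p + z**2 / (2 * pop)) / denom
        half = z * np.sqrt(p * (1 - p) / pop + z**2 / (4 * pop**2)) / denom
        out["ci_low_pct"] = 100 * np.clip(centre - half, 0, 1)
        out["ci_high_pct"] = 100 * np.clip(centre + half, 0, 1)
    return out


def expected_counts(population: StratifiedPopulation, stratum_prev) -> np.ndarray:
    """Indirectly standardized expected count ``E_k`` per area.

    ``stratum_prev`` gives the catchment-wide prevalence per stratum as a
    *fraction* (not percent), aligned with ``population.strata``; a mapping
    keyed by stratum name is also accepted.
    """
    if isinstance(stratum_prev, dict):
        missing = [s for s in population.strata if s not in stratum_prev]
        if missing:
            raise ValueError(f"missing stratum prevalence for {missing}")
        p = np.array([stratum_prev[s] for s in population.strata], dtype=float)
    else:
        p = np.asarray(stratum_prev, dtype=float)
        if p.shape != (len(population.strata),):
            raise ValueError("stratum prevalence vector misaligned with strata")
    return population.counts @ p


def catchment_stratum_prevalence(
    population: StratifiedPopulation, stratum_cases
) -> np.ndarray:
    """Catchment stratum prevalences (fractions) from stratum case totals."""
    cases = np.asarray(stratum_cases, dtype=float)
    pop_tot = population.counts.sum(axis=0).astype(float)
    if cases.shape != pop_tot.shape:
        raise ValueError("stratum case totals misaligned with strata")
    if np.any(pop_tot <= 0):
        empty = [s for s, n in zip(population.strata, pop_tot) if n <= 0]
        raise ValueError(f"zero population at risk in stratum {empty[0]!r}")
    return cases / pop_tot


def prevalence_rate_ratio(y, E) -> np.ndarray:
    """Per-area prevalence rate ratio ``PRR_k = y_k / E_k``.

    Areas with ``E_k = 0`` and cases observed get ``inf`` (flagged ratio);
    ``E_k = 0`` with no cases yields ``nan`` (undefined).
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = np.where(E > 0, y / np.where(E > 0, E, 1.0), np.where(y > 0, np.inf, np.nan))
    return prr


def zscore(x, *, ddof: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1 across areas (population SD by default)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot Z-score a constant component")
    return (x - x.mean()) / sd


def composite_index(prop_a, prop_b, name: str = "index") -> pd.Series:
    """Two-component ecological index: ``z(prop_a) + z(prop_b)`` per area.

    The components are per-area proportions (e.g. unemployment rate and
    carless-household share for economic deprivation).  The result has mean
    0 by construction and SD in (0, 2], reaching 2 only for perfectly
    correlated components.
    """
    a = np.asarray(prop_a, dtype=float)
    if a.size < 2:
        raise ValueError("composite index needs at least 2 areas")
    value = zscore(prop_a) + zscore(prop_b)
    return pd.Series(value, name=name)


def adjustment_design(population: StratifiedPopulation) -> pd.DataFrame:
    """Confounder design: non-reference stratum proportions plus offset.

    Returns one column of resident proportions for each of the four
    non-reference strata (18-24, F 25-39, M 25-39, 40-54; the 55+ band is
    the reference and omitted) and the ``offset`` column ``log n_k``.
    """
    n_k = population.totals.astype(float)
    props = population.counts / n_k[:, None]
    cols = {f"prop_{s}": props[:, i] for i, s in enumerate(STRATA) if s != "55+"}
    cols["offset"] = np.log(n_k)
    return pd.DataFrame(cols)
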