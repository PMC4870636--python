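"""Data containers and the packaged catchment fixture.

The analysis operates on area-level data: an observed case count per area, a
population at risk stratified into five age/gender adjustment groups, the
ecological covariates, and an indirectly standardized expected count.  The
raw per-area data of the motivating study are not public; what is packaged
here are the catchment-wide aggregates (cases and populations at risk per
gender and age-band) plus the study's bookkeeping constants, which anchor
the standardization machinery.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import AreaLattice

__all__ = [
    "STRATA",
    "StratifiedPopulation",
    "AreaDataset",
    "table1_fixture",
    "table1_strata",
    "catchment_summary",
]

#: The five adjustment strata: one age-band below 25, gender-split 25-39
#: (the only band with a gender difference in prevalence), and two pooled
#: older bands.  "55+" is the reference category in regression designs.
STRATA = ("18-24", "F25-39", "M25-39", "40-54", "55+")

#: Case-ascertainment bookkeeping of the catchment study.
CATCHMENT = {
    "cases_identified": 462,
    "cases_excluded": 104,  # outside catchment or long-term care
    "n_areas": 53,
    "population_by_city": {"Creteil": 66681, "Maisons-Alfort": 42716},
}


def table1_fixture() -> pd.DataFrame:
    """Catchment aggregates: cases and population at risk per gender x age-band.

    Returns an 8-row frame (4 age-bands x 2 genders) with columns
    ``age_band, gender, cases, population``.
    """
    ref = importlib.resources.files("carmap") / "data" / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table1_strata() -> pd.DataFrame:
    """Fixture collapsed to the five adjustment strata.

    Frame indexed by :data:`STRATA` with columns ``cases`` and ``population``.
    """
    t = table1_fixture()
    rows = {}
    sel = t.set_index(["age_band", "gender"])
    rows["18-24"] = sel.loc["18-24"].sum()
    rows["F25-39"] = sel.loc[("25-39", "F")]
    rows["M25-39"] = sel.loc[("25-39", "M")]
    rows["40-54"] = sel.loc["40-54"].sum()
    rows["55+"] = sel.loc["55+"].sum()
    out = pd.DataFrame(rows).T.loc[list(STRATA)]
    return out.astype(int)


def catchment_summary() -> dict:
    """Derived bookkeeping of the catchment study (computed, not stored)."""
    t = table1_fixture()
    included = CATCHMENT["cases_identified"] - CATCHMENT["cases_excluded"]
    total_pop = int(sum(CATCHMENT["population_by_city"].values()))
    return {
        "cases_included": included,
        "mean_cases_per_area": included / CATCHMENT["n_areas"],
        "population_at_risk": total_pop,
        "fixture_total_cases": int(t["cases"].sum()),
        "fixture_total_population": int(t["population"].sum()),
        "crude_prevalence": included / total_pop,
    }


@dataclass(frozen=True)
class StratifiedPopulation:
    """Per-area persons at risk in the five adjustment strata.

    ``counts`` is an ``(n_areas, 5)`` integer array in :data:`STRATA` order.
    Every retained area must have a positive total.
    """

    counts: np.ndarray
    strata: tuple[str, ...] = STRATA

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != len(self.strata):
            raise ValueError(f"counts must be (n_areas, {len(self.strata)})")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("stratum counts must be nonnegative integers")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError("every area must have a positive population at risk")
        object.__setattr__(self, "counts", counts)

    @property
    def n_areas(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> np.ndarray:
        """Persons at risk ``n_k`` per area (sum over strata)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=list(self.strata))


@dataclass
class AreaDataset:
    """Per-area analysis table plus the adjacency structure.

    Fields
    ------
    y : case count per area
    population : :class:`StratifiedPopulation`
    covariates : frame of ecological indices (ECON, MIG, FRAG)
    expected : indirectly standardized expected count ``E_k`` (may be None
        until :func:`carmap.standardize.expected_counts` has been applied)
    lattice : the adjacency skeleton
    stratum_cases : catchment-wide case totals per stratum, needed for
        internal indirect standardization
    """

    y: np.ndarray
    population: StratifiedPopulation
    covariates: pd.DataFrame
    lattice: AreaLattice
    expected: np.ndarray | None = None
    stratum_cases: np.ndarray | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        n = self.population.n_areas
        if self.y.shape != (n,):
            raise ValueError("y must have one entry per area")
        if np.any(self.y < 0):
            raise ValueError("case counts must be nonnegative")
        if len(self.covariates) != n or self.lattice.n_areas != n:
            raise ValueError("covariates/lattice misaligned with population")

    @property
    def n_areas(self) -> int:
        return self.population.n_areas

    @property
    def offset(self) -> np.ndarray:
        """Log persons at risk, the rate-model offset."""
        return np.log(self.population.totals.astype(float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": np.arange(self.n_areas), "y": self.y})
        df["n"] = self.population.totals
        df = pd.concat([df, self.population.to_frame()], axis=1)
        df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        if self.expected is not None:
            df["E"] = self.expected
        return df

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write areas table, adjacency edge list and truth sidecar to a directory."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"areas": out / "areas.csv", "adjacency": out / "adjacency.csv"}
        self.to_frame().to_csv(paths["areas"], index=False)
        self.lattice.edge_list().to_csv(paths["adjacency"], index=False)
        if self.truth is not None:
            paths["truth"] = out / "truth.json"
            paths["truth"].write_text(json.dumps(self.truth, indent=2))
        if self.lattice.coords is not None:
            paths["geojson"] = out / "areas.geojson"
            paths["geojson"].write_text(json.dumps(self.lattice.to_geojson()))
        return paths

    @classmethod
    def read(cls, areas_csv: str | Path, adjacency_csv: str | Path) -> "AreaDataset":
        """Load an areas table and edge-list adjacency written by :meth:`write`."""
        df = pd.read_csv(areas_csv)
        edges = pd.read_csv(adjacency_csv)
        n = len(df)
        strata_cols = [s for s in STRATA if s in df.columns]
        if len(strata_cols) != len(STRATA):
            raise ValueError("areas table is missing stratum columns")
        pop = StratifiedPopulation(df[list(STRATA)].to_numpy(dtype=int))
        cov_cols = [c for c in df.columns if c in ("ECON", "MIG", "FRAG")]
        lattice = AreaLattice.from_edge_list(n, edges)
        return cls(
            y=df["y"].to_numpy(dtype=int),
            population=pop,
            covariates=df[cov_cols].copy(),
            lattice=lattice,
            expected=df["E"].to_numpy() if "E" in df.columns else None,
        )
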