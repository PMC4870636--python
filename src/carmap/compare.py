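"""Cross-paradigm model comparison and the end-to-end pipeline.

The frequentist and Bayesian stages are compared on the observed scale with
two criteria: the coefficient of determination between observed and fitted
per-area values (squared Pearson correlation, which is guaranteed to lie in
[0, 1] for non-least-squares fits) and the root mean squared deviation.

:func:`run_pipeline` strings the stages together the way a small-area
prevalence analysis proceeds: standardize, fit the simplest count model,
escalate only when a validity test fails — Poisson, then negative binomial
on overdispersion (Dean's test), then the CAR sweep on residual spatial
autocorrelation (Moran's I) — and finish with model comparison and the
hotspot report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .car import CARFit, CARModelSpec, MCMCConfig, fit_car, smoothed_rr
from .datasets import AreaDataset
from .freq import GLMFit, SelectionTrace, dean_test, fit_negbin, fit_poisson, forward_select, moran_i
from .standardize import adjustment_design
from .synthetic import GenerativeTruth, simulate_dataset
from .lattice import LatticeSpec

__all__ = ["r_squared", "rmsd", "fitted_observed_ratio", "model_table",
           "ComparisonResult", "PipelineResult", "run_pipeline"]


def r_squared(observed, fitted) -> float:
    """Squared Pearson correlation between observed and fitted values."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.size < 3:
        raise ValueError("r_squared needs at least 3 areas")
    if obs.std() == 0 or fit.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(obs, fit)[0, 1] ** 2)


def r_squared_sse(observed, fitted) -> float:
    """The 1 - SSE/SST variant (can be negative for badly fitting models)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant")
    return float(1.0 - np.sum((obs - fit) ** 2) / sst)


def rmsd(observed, fitted) -> float:
    """Root mean squared deviation between fitted and observed values."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    return float(np.sqrt(np.mean((fit - obs) ** 2)))


def fitted_observed_ratio(observed, fitted) -> np.ndarray:
    """Per-area fitted/observed ratio; observed zeros are reported missing."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    return np.where(obs > 0, fit / np.where(obs > 0, obs, 1.0), np.nan)


@dataclass(frozen=True)
class ComparisonResult:
    """Fit-quality comparison of one model against the observed counts."""

    label: str
    r2: float
    r2_sse: float
    rmsd: float
    ratio: np.ndarray = field(repr=False)


def compare_fit(label: str, observed, fitted) -> ComparisonResult:
    return ComparisonResult(
        label=label,
        r2=r_squared(observed, fitted),
        r2_sse=r_squared_sse(observed, fitted),
        rmsd=rmsd(observed, fitted),
        ratio=fitted_observed_ratio(observed, fitted),
    )


def _fit_kind(fit) -> str:
    if isinstance(fit, CARFit):
        return "dic"
    if isinstance(fit, GLMFit):
        return "aic"
    raise TypeError(f"unrecognised fit object {type(fit)!r}")


def model_table(fits: dict) -> pd.DataFrame:
    """Ranked model-comparison table from ``{label: fit}``.

    All fits must carry the same criterion kind (AIC or DIC; the two are not
    comparable and mixing them raises).  Rows are sorted ascending by
    criterion, ties broken toward the model with fewer terms; the best row
    is flagged.
    """
    kinds = {_fit_kind(f) for f in fits.values()}
    if len(kinds) > 1:
        raise ValueError("cannot rank AIC and DIC fits in one table")
    kind = kinds.pop()
    rows = []
    for label, f in fits.items():
        rows.append(
            {
                "model": label,
                "family": f.structure if isinstance(f, CARFit) else f.family,
                "variables": "+".join(f.variables),
                "n_terms": len(f.variables),
                "criterion": f.criterion,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["criterion", "n_terms"], kind="stable", ignore_index=True
    )
    df["criterion_name"] = kind
    df["best"] = False
    df.loc[0, "best"] = True
    return df


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus a machine-readable summary."""

    dataset: AreaDataset
    poisson_trace: SelectionTrace
    dean: object
    negbin_trace: SelectionTrace | None
    moran: object
    car_traces: dict[str, SelectionTrace]
    best_freq: GLMFit
    best_car: CARFit | None
    comparison: list[ComparisonResult]
    hotspots: object | None
    summary: dict
    log: list[str]

    def write(self, out_dir: str | Path) -> None:
        """Emit tables, run log, summary JSON and the hotspot layers."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.write(out / "data")
        self.poisson_trace.to_frame().to_csv(out / "poisson_selection.csv", index=False)
        if self.negbin_trace is not None:
            self.negbin_trace.to_frame().to_csv(out / "negbin_selection.csv", index=False)
        self.best_freq.effect_table().to_csv(out / "best_freq_effects.csv")
        if self.car_traces:
            rows = []
            for structure, trace in self.car_traces.items():
                df = trace.to_frame()
                df.insert(0, "structure", structure)
                rows.append(df)
            pd.concat(rows, ignore_index=True).to_csv(out / "car_selection.csv", index=False)
        if self.best_car is not None:
            self.best_car.effect_table().to_csv(out / "best_car_effects.csv")
            self.best_car.chains_frame().to_csv(out / "chains.csv", index=False)
            meta = {
                "structure": self.best_car.structure,
                "acceptance": self.best_car.acceptance,
                "geweke_z": self.best_car.geweke.to_dict(),
                "dic": self.best_car.dic,
                "p_d": self.best_car.p_d,
            }
            (out / "best_car_meta.json").write_text(json.dumps(meta, indent=2))
        if self.hotspots is not None:
            self.hotspots.table.to_csv(out / "hotspots.csv", index_label="area_id")
            if self.dataset.lattice.coords is not None:
                (out / "hotspots.geojson").write_text(
                    json.dumps(self.hotspots.to_geojson(self.dataset.lattice))
                )
        if self.comparison:
            pd.DataFrame(
                [
                    {"model": c.label, "r2": c.r2, "r2_sse": c.r2_sse, "rmsd": c.rmsd}
                    for c in self.comparison
                ]
            ).to_csv(out / "comparison.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def _dataset_from_config(config: dict, seed: int | None) -> AreaDataset:
    if "inputs" in config:
        inp = config["inputs"]
        ds = AreaDataset.read(inp["areas"], inp["adjacency"])
        if ds.expected is None:
            raise ValueError("input areas table must carry expected counts E")
        return ds
    sim = dict(config.get("simulate", {}))
    sim_seed = seed if seed is not None else sim.get("seed", 0)
    truth = GenerativeTruth(
        beta=np.asarray(sim["beta"], dtype=float) if "beta" in sim else None,
        rho=sim.get("rho", 0.8),
        tau2=sim.get("tau2", 0.3),
        sigma2_unstructured=sim.get("sigma2", 0.0),
        baseline_prevalence=sim.get("baseline_prevalence", 358.0 / 109397.0),
    )
    spec = LatticeSpec(
        sim.get("n_rows", 7), sim.get("n_cols", 8), sim.get("adjacency_rule", "rook"),
        sim_seed,
    )
    return simulate_dataset(
        spec=spec,
        truth=truth,
        mean_pop=sim.get("mean_pop", 2064.0),
        sd_pop=sim.get("sd_pop", 705.0),
        spatial_corr=sim.get("spatial_corr", 0.5),
        seed=sim_seed,
    )


def run_pipeline(config: dict, seed: int | None = None, out_dir=None) -> PipelineResult:
    """Run the full escalation pipeline on simulated or loaded data.

    Stages: standardize -> Poisson forward selection (AIC) -> Dean's test ->
    (if overdispersed) negative binomial forward selection -> Moran's I on
    the best frequentist fit's Pearson residuals -> (if autocorrelated, or
    ``force_bayesian``) CAR sweep of the four structures, each forward
    selected by DIC -> observed/fitted comparison -> hotspot report from the
    best Bayesian model.

    The stage gating is purely a function of the diagnostic decisions, so a
    fixed seed and config reproduce the identical summary.
    """
    log: list[str] = []
    t0 = time.time()

    def note(msg: str) -> None:
        log.append(f"[{time.time() - t0:7.2f}s] {msg}")

    alpha = config.get("alpha", 0.05)
    stage = "data"
    try:
        ds = _dataset_from_config(config, seed)
        note(f"dataset ready: {ds.n_areas} areas, {int(ds.y.sum())} cases")

        stage = "design"
        design = adjustment_design(ds.population)
        offset = design.pop("offset").to_numpy()
        X_base = design
        X_base.insert(0, "intercept", 1.0)
        if not config.get("include_confounders", True):
            X_base = X_base[["intercept"]]
        candidates = {c: ds.covariates[c].to_numpy() for c in ds.covariates.columns}

        stage = "poisson"
        pois_trace = forward_select(ds.y, X_base, candidates, fit_poisson, offset)
        best_freq: GLMFit = pois_trace.best_fit
        note(f"Poisson selection kept {pois_trace.best_variables or ('nothing',)} "
             f"(AIC {best_freq.aic:.2f})")

        stage = "dean"
        dean = dean_test(best_freq, alpha=alpha)
        note(f"Dean's test: statistic {dean.statistic:.2f}, "
             f"{'overdispersed' if dean.decision else 'equidispersed'}")

        negbin_trace = None
        if dean.decision:
            stage = "negbin"
            negbin_trace = forward_select(ds.y, X_base, candidates, fit_negbin, offset)
            best_freq = negbin_trace.best_fit
            note(f"negative binomial selection kept "
                 f"{negbin_trace.best_variables or ('nothing',)} (AIC {best_freq.aic:.2f})")

        stage = "moran"
        moran = moran_i(
            best_freq.pearson_residuals(),
            ds.lattice.W,
            permutations=config.get("moran_permutations", 999),
            alpha=alpha,
            seed=seed,
        )
        note(f"Moran's I on residuals: {moran.statistic:.3f} (p = {moran.p_value:.3f})")

        car_traces: dict[str, SelectionTrace] = {}
        best_car: CARFit | None = None
        hotspots = None
        comparison: list[ComparisonResult] = []
        go_bayes = moran.decision or config.get("force_bayesian", False)
        if go_bayes:
            stage = "car"
            mcmc_cfg = dict(config.get("mcmc", {}))
            base_seed = seed if seed is not None else mcmc_cfg.pop("seed", 0)
            mcmc_cfg.pop("seed", None)
            structures = config.get("structures", ("IND", "IAR", "BYM", "LER"))
            ss = np.random.SeedSequence(base_seed)
            children = iter(ss.spawn(4 * (len(candidates) ** 2 + len(candidates) + 2)))

            for structure in structures:
                def car_fitter(y, X, off, _structure=structure):
                    child = next(children)
                    cfg = MCMCConfig(
                        seed=int(child.generate_state(1)[0] % (2**31)), **mcmc_cfg
                    )
                    return fit_car(CARModelSpec(_structure), y, X, off, ds.lattice.W, cfg)

                trace = forward_select(ds.y, X_base, dict(candidates), car_fitter, offset)
                car_traces[structure] = trace
                fit: CARFit = trace.best_fit
                note(f"CAR {structure}: kept {trace.best_variables or ('nothing',)} "
                     f"(DIC {fit.dic:.2f})")
                if best_car is None or fit.dic < best_car.dic:
                    best_car = fit

            stage = "comparison"
            comparison.append(compare_fit("best_frequentist", ds.y, best_freq.mu))
            comparison.append(compare_fit("best_bayesian", ds.y, best_car.fitted))
            note(f"comparison: r2 {comparison[1].r2:.2f} (Bayes) vs "
                 f"{comparison[0].r2:.2f} (freq)")

            stage = "hotspots"
            hotspots = smoothed_rr(best_car, ds.expected,
                                   cutoff=config.get("exceedance_cutoff", 0.75))
            note(f"hotspots: {len(hotspots.hotspots)} area(s) above "
                 f"{hotspots.cutoff:.2f} exceedance")
        else:
            note("no residual autocorrelation detected: stopping at the "
                 "frequentist stage")
    except Exception as exc:
        note(f"stage {stage!r} failed: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    chosen = (
        {"paradigm": "bayesian", "structure": best_car.structure,
         "variables": list(best_car.variables), "dic": best_car.dic}
        if best_car is not None
        else {"paradigm": "frequentist", "family": best_freq.family,
              "variables": list(best_freq.variables), "aic": best_freq.aic}
    )
    summary = {
        "n_areas": int(ds.n_areas),
        "total_cases": int(ds.y.sum()),
        "dean_statistic": dean.statistic,
        "overdispersed": bool(dean.decision),
        "moran_i": moran.statistic,
        "moran_p": moran.p_value,
        "autocorrelated": bool(moran.decision),
        "ran_bayesian": bool(best_car is not None),
        "chosen_model": chosen,
        "n_hotspots": int(len(hotspots.hotspots)) if hotspots is not None else None,
    }
    result = PipelineResult(
        dataset=ds,
        poisson_trace=pois_trace,
        dean=dean,
        negbin_trace=negbin_trace,
        moran=moran,
        car_traces=car_traces,
        best_freq=best_freq,
        best_car=best_car,
        comparison=comparison,
        hotspots=hotspots,
        summary=summary,
        log=log,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
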