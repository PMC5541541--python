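"""End-to-end orchestration: data -> synchrony -> climate models -> SEMs.

The pipeline sequences the full analysis: compute FDP and synchrony
indices from incidence records, prepare seasonal climate predictors, fit
the hierarchical Bayesian climate-sensitivity model per species, reduce
traits and climate responses to factors, assemble the species table, and
fit and compare the dispersal / climate / combined structural equation
models, including the migrant-exclusion and random-removal experiments.
Every stochastic stage derives its seed deterministically from the master
seed, so a config and seed reproduce the report bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, factors, hier_bayes, sem, synchrony
from .data_io import write_table
from .synthetic import MODEL_TERMS, SimulationConfig, StudyBundle, generate_study

logger = logging.getLogger("lepisync")

REPORT_SCHEMA_VERSION = 1

#: species-table column for each model term's posterior-mean response
RESPONSE_COLUMNS = {term: f"r_{term}" for term in MODEL_TERMS}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulation`` is set (synthetic study) or the four input paths
    are.  MCMC defaults are the desk-scale protocol (2 chains x 5000
    iterations after 1000 burn-in); the full-length protocol is a matter
    of raising ``mcmc_iterations``.
    """

    simulation: SimulationConfig | None = None
    observations_path: str | None = None
    weather_path: str | None = None
    ssta_path: str | None = None
    traits_path: str | None = None

    min_sites: int = 3
    absence_years: int = 8
    min_overlap_years: int = 24

    mcmc_iterations: int = 5000
    mcmc_burn_in: int = 1000
    mcmc_chains: int = 2

    rotation: str = "oblimin"
    sem_models: tuple = ("dispersal", "climate", "combined")
    sem_variant: str = "latent"
    removal_reps: int = 1000
    n_remove: int = 9

    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"


def _load_study(config: PipelineConfig) -> StudyBundle | tuple:
    from . import data_io

    if config.simulation is not None:
        return generate_study(config.simulation.with_(seed=config.seed))
    paths = (config.observations_path, config.weather_path,
             config.ssta_path, config.traits_path)
    if any(p is None for p in paths):
        raise PipelineError("load", "either simulation or all four input "
                                    "paths must be configured")
    return (data_io.read_observations(paths[0]), data_io.read_weather(paths[1]),
            data_io.read_ssta(paths[2]), data_io.read_traits(paths[3]))


def species_seed(master_seed: int, species_index: int) -> np.random.SeedSequence:
    """Deterministic per-species seed; independent of execution order."""
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(species_index,))


def fit_all_species(fdp: pd.DataFrame, seasonal: pd.DataFrame,
                    enso: pd.DataFrame, species_ids: list,
                    n_iter: int, burn_in: int, chains: int,
                    master_seed: int) -> pd.DataFrame:
    """Hierarchical-model responses for every species (posterior means).

    Returns one row per species with the seven transect-wide slope
    posterior means plus worst-case convergence diagnostics.  Per-species
    runs use seeds derived from the master seed and are independent, so
    results do not depend on execution order.
    """
    records = []
    for i, sp in enumerate(species_ids):
        t0 = time.time()
        design = hier_bayes.build_design(sp, fdp, seasonal, enso)
        draws = hier_bayes.run_mcmc(design, n_iter=n_iter, burn_in=burn_in,
                                    chains=chains,
                                    seed=species_seed(master_seed, i))
        summ = hier_bayes.summarize(draws)
        hyper = summ.table[summ.table["parameter"].str.startswith(
            ("mu_", "tau_"))]
        rec = {"species_id": sp,
               **{RESPONSE_COLUMNS[t]: summ.response[t] for t in MODEL_TERMS},
               "max_rhat": float(hyper["rhat"].max()),
               "min_ess": float(hyper["ess"].min())}
        records.append(rec)
        logger.info("fitted %s (%d/%d) in %.1fs", sp, i + 1, len(species_ids),
                    time.time() - t0)
    return pd.DataFrame(records)


def assemble_species_table(synchrony_table: pd.DataFrame,
                           covariates: pd.DataFrame,
                           responses: pd.DataFrame,
                           traits: pd.DataFrame) -> pd.DataFrame:
    """Inner-join all species-level components into the SEM input table.

    Traits are log-transformed (they live on skewed positive scales) and
    every analysis column is z-scored across the included species.
    Species missing any component are logged and excluded.
    """
    parts = {
        "synchrony": synchrony_table[["species_id", "index"]].rename(
            columns={"index": "synchrony"}),
        "covariates": covariates[["species_id", "abundance_z",
                                  "avg_sites_occupied_z", "trend_z"]].rename(
            columns={"abundance_z": "abundance",
                     "avg_sites_occupied_z": "avg_sites_occupied",
                     "trend_z": "trend"}),
        "responses": responses[["species_id"] + list(RESPONSE_COLUMNS.values())],
        "traits": traits.assign(**{
            t: np.log(traits[t])
            for t in ("wingspan", "geographic_range", "diet_breadth",
                      "elevational_range")
        })[["species_id", "wingspan", "geographic_range", "diet_breadth",
            "elevational_range", "migratory"]],
    }
    table: pd.DataFrame | None = None
    ids = None
    for name, part in parts.items():
        ids = set(part["species_id"]) if ids is None else ids & set(part["species_id"])
        table = part if table is None else table.merge(part, on="species_id",
                                                       how="inner")
    all_ids = set().union(*(set(p["species_id"]) for p in parts.values()))
    for sp in sorted(all_ids - set(table["species_id"])):
        logger.warning("species %s missing a component; excluded from SEM", sp)
    if len(table) == 0:
        raise PipelineError("assemble", "no species with complete components")
    for col in table.columns:
        if col in ("species_id", "migratory"):
            continue
        v = table[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd > 0:
            table[col] = (v - v.mean()) / sd
    return table.reset_index(drop=True)


def _sem_report(fit_obj: sem.SemFit) -> dict:
    out = {
        "chi2": fit_obj.chi2, "df": fit_obj.df, "p_value": fit_obj.p_value,
        "aic": fit_obj.aic, "n": fit_obj.n, "fml": fit_obj.fml,
        "proper": fit_obj.proper,
        "r2": {v: sem.r_squared(fit_obj, v)
               for v in ("synchrony", "avg_sites_occupied", "trend")},
    }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    from .data_io import setup_logging

    setup_logging(config.log_level)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- load / simulate -------------------------------------------------
    study = _load_study(config)
    if isinstance(study, StudyBundle):
        observations, weather, ssta, traits = (study.observations, study.weather,
                                               study.ssta, study.traits)
    else:
        observations, weather, ssta, traits = study

    # ---- synchrony -------------------------------------------------------
    try:
        fdp = synchrony.compute_fdp(observations)
        fdp_kept, exclusions = synchrony.apply_inclusion_rules(
            fdp, min_sites=config.min_sites, absence_years=config.absence_years)
        if len(fdp_kept) == 0:
            raise ValueError(
                f"no species survive the inclusion rules "
                f"(min_sites={config.min_sites}, "
                f"absence_years={config.absence_years})")
        delta = synchrony.compute_delta(fdp_kept)
        sync = synchrony.synchrony_index(
            delta, min_overlap_years=config.min_overlap_years)
        covs = synchrony.species_covariates(
            fdp_kept[fdp_kept["species_id"].isin(sync.table["species_id"])],
            delta[delta["species_id"].isin(sync.table["species_id"])])
    except (ValueError, KeyError) as exc:
        raise PipelineError("synchrony", str(exc)) from exc

    # ---- climate preparation --------------------------------------------
    try:
        seasonal = climate.aggregate_seasonal(weather)
        enso = climate.enso_winter_mean(ssta)
        redundancy = climate.weather_redundancy_diagnostic(seasonal)
    except (ValueError, KeyError) as exc:
        raise PipelineError("climate_prep", str(exc)) from exc

    # ---- hierarchical Bayesian responses ---------------------------------
    try:
        responses = fit_all_species(
            fdp_kept, seasonal, enso, list(sync.table["species_id"]),
            n_iter=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
            chains=config.mcmc_chains, master_seed=config.seed)
    except (ValueError, KeyError) as exc:
        raise PipelineError("hier_bayes", str(exc)) from exc

    # ---- species table and factor analyses -------------------------------
    try:
        table = assemble_species_table(sync.table, covs, responses, traits)
        disp_fa = factors.fit_ml_factors(
            table[["wingspan", "geographic_range", "diet_breadth",
                   "elevational_range"]], k=2, rotation=config.rotation)
        clim_fa = factors.fit_ml_factors(
            table[[RESPONSE_COLUMNS[t] for t in MODEL_TERMS[:5]]], k=2,
            rotation=config.rotation)
    except (ValueError, RuntimeError) as exc:
        raise PipelineError("factors", str(exc)) from exc

    if config.sem_variant == "scores":
        d_scores = factors.factor_scores(
            disp_fa, table[["wingspan", "geographic_range", "diet_breadth",
                            "elevational_range"]])
        c_scores = factors.factor_scores(
            clim_fa, table[[RESPONSE_COLUMNS[t] for t in MODEL_TERMS[:5]]])
        table["dispersal1"], table["dispersal2"] = (d_scores["factor1"],
                                                    d_scores["factor2"])
        table["climate1"], table["climate2"] = (c_scores["factor1"],
                                                c_scores["factor2"])

    # ---- structural equation models & experiments ------------------------
    sem_fits: dict[str, dict] = {}
    experiments: dict[str, dict] = {}
    migratory = table["migratory"].astype(bool)
    for which in config.sem_models:
        try:
            spec = sem.canned_models(which, variant=config.sem_variant)
            fit_obj = sem.fit(spec, table)
            sem_fits[which] = _sem_report(fit_obj)
            excl = sem.exclusion_experiment(spec, table, mode="migrants",
                                            migratory=migratory)
            rand = sem.exclusion_experiment(
                spec, table, mode="random", n_remove=config.n_remove,
                reps=config.removal_reps, seed=config.seed)
            experiments[which] = {
                "without_migrants": {
                    "n": int((~migratory).sum()),
                    "r2_synchrony": float(excl.r2_values[0]),
                },
                "random_removal": {
                    "reps": rand.n_replicates, "n_remove": config.n_remove,
                    "mean_r2": rand.mean, "interval": list(rand.interval),
                    "n_failed": rand.n_failed,
                },
            }
        except (RuntimeError, ValueError) as exc:
            raise PipelineError(f"sem:{which}", str(exc)) from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_species": int(len(table)),
        "synchrony": {
            "mean_index": float(sync.table["index"].mean()),
            "n_above_0.1": int((sync.table["index"] > 0.1).sum()),
            "n_above_0.2": int((sync.table["index"] > 0.2).sum()),
            "n_above_0.4": int((sync.table["index"] > 0.4).sum()),
            "n_negative": int((sync.table["index"] < 0).sum()),
            "n_excluded": len(exclusions),
        },
        "weather_redundancy": {
            "mean_abs_cross_site_correlation":
                redundancy["mean_abs_cross_site_correlation"],
        },
        "mcmc": {
            "iterations": config.mcmc_iterations,
            "burn_in": config.mcmc_burn_in,
            "chains": config.mcmc_chains,
            "max_rhat": float(responses["max_rhat"].max()),
            "min_ess": float(responses["min_ess"].min()),
        },
        "factor_analysis": {
            "dispersal_variance_explained":
                disp_fa.proportion_variance.tolist(),
            "climate_variance_explained": clim_fa.proportion_variance.tolist(),
        },
        "sem": sem_fits,
        "experiments": experiments,
    }

    if out_dir:
        write_table(sync.table, out_dir / "synchrony.csv")
        write_table(responses, out_dir / "responses.csv")
        write_table(table, out_dir / "species_table.csv")
        (out_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                        sort_keys=True))
        manifest = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": config.seed,
            "simulated": config.simulation is not None,
            "exclusions": exclusions,
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
    return report
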