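import numpy as np
import pandas as pd
import pytest

from lepisync.pipeline import PipelineConfig, run_pipeline
from lepisync.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def study_small():
    """A small but complete synthetic study shared across test modules."""
    cfg = SimulationConfig(n_sites=6, n_species=25, n_years=18,
                           visits_per_year=12, seed=11)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at reduced scale (shared; takes a few minutes)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        simulation=SimulationConfig(n_sites=8, n_species=65, n_years=22,
                                    visits_per_year=15),
        min_overlap_years=10,
        mcmc_iterations=400, mcmc_burn_in=200,
        removal_reps=20,
        seed=3, log_level="WARNING", out_dir=str(out),
    )
    report = run_pipeline(cfg)
    table = pd.read_csv(out / "species_table.csv")
    return {"report": report, "table": table}


@pytest.fixture(scope="session")
def pipeline_report(pipeline_run):
    return pipeline_run["report"]


def toy_observations() -> pd.DataFrame:
    """Two sites, two species, two years, hand-countable detections."""
    rows = []
    detections = {
        # (site, year, species) -> visits on which it was seen (of 4)
        ("A", 2000, "s1"): [1, 2], ("A", 2001, "s1"): [1],
        ("B", 2000, "s1"): [1, 2, 3], ("B", 2001, "s1"): [],
        ("A", 2000, "s2"): [4], ("A", 2001, "s2"): [1, 2, 3, 4],
        ("B", 2000, "s2"): [], ("B", 2001, "s2"): [2],
    }
    for (site, year, sp), seen in detections.items():
        for visit in range(1, 5):
            rows.append({"site_id": site, "year": year, "visit_index": visit,
                         "species_id": sp, "detected": int(visit in seen)})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_obs():
    return toy_observations()
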