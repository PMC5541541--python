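"""Species-level spatial synchrony from incidence records.

The abundance proxy is the fraction of days positive (FDP): for each
site x species x year, the number of visits on which the species was seen
divided by the number of visits that year.  Year-over-year first
differences (dFDP) are correlated across sites in a pairwise fashion
(Pearson's r) on the years both sites share, and the unweighted mean of
the pairwise correlations is the species' synchrony index.

Inclusion rules mirror long-term monitoring practice: a site is dropped
for a species that was absent there for eight or more years, and a species
must remain at three or more sites to receive an index.  Both thresholds
are parameters; every exclusion is logged with the rule that fired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataError


def compute_fdp(observations: pd.DataFrame,
                species: list | None = None) -> pd.DataFrame:
    """Per site x species x year fraction of visits with a detection.

    Visits are counted per site-year from the distinct visit indices, so a
    species never recorded at a site still gets records (with zero
    positives) for every visited year, provided it appears in ``species``
    (default: every species in the table).  Years with no visits yield no
    record at all.

    Returns a table ``site_id, species_id, year, visits, positives, fdp``.
    """
    if species is None:
        species = sorted(observations["species_id"].unique())
    visits = (
        observations.groupby(["site_id", "year"])["visit_index"]
        .nunique()
        .rename("visits")
        .reset_index()
    )
    positives = (
        observations.groupby(["site_id", "year", "species_id"])["detected"]
        .sum()
        .rename("positives")
        .reset_index()
    )
    # cross join site-years with the configured species list
    grid = visits.merge(pd.DataFrame({"species_id": species}), how="cross")
    out = grid.merge(positives, on=["site_id", "year", "species_id"], how="left")
    out["positives"] = out["positives"].fillna(0).astype(int)
    out["fdp"] = out["positives"] / out["visits"]
    return out[["site_id", "species_id", "year", "visits", "positives", "fdp"]].sort_values(
        ["species_id", "site_id", "year"]
    ).reset_index(drop=True)


def compute_delta(fdp: pd.DataFrame) -> pd.DataFrame:
    """Year-over-year change in FDP, defined only for consecutive years.

    For each site x species, dFDP in year t is FDP_t - FDP_{t-1} and exists
    only when both years have visit records; gaps produce no value.  Series
    with fewer than two years simply contribute nothing.
    """
    df = fdp.sort_values(["site_id", "species_id", "year"]).copy()
    g = df.groupby(["site_id", "species_id"])
    prev_year = g["year"].shift(1)
    prev_fdp = g["fdp"].shift(1)
    consecutive = df["year"] - prev_year == 1
    out = df.loc[consecutive, ["site_id", "species_id", "year"]].copy()
    out["delta_fdp"] = (df["fdp"] - prev_fdp)[consecutive]
    return out.reset_index(drop=True)


def apply_inclusion_rules(fdp: pd.DataFrame, min_sites: int = 3,
                          absence_years: int = 8,
                          consecutive: bool = False) -> tuple[pd.DataFrame, list[dict]]:
    """Filter FDP series by the absence and minimum-site rules.

    A site x species series with ``absence_years`` or more zero-positive
    years is removed (total count by default; ``consecutive=True`` switches
    to the longest run of zero years).  A species left with fewer than
    ``min_sites`` sites is removed entirely.  Returns the filtered table
    and an exclusion log (one dict per exclusion, naming the rule).
    """
    log: list[dict] = []

    def zero_years(s: pd.Series) -> int:
        zeros = (s == 0).to_numpy()
        if not consecutive:
            return int(zeros.sum())
        best = run = 0
        for z in zeros:
            run = run + 1 if z else 0
            best = max(best, run)
        return best

    absent = (
        fdp.sort_values("year")
        .groupby(["site_id", "species_id"])["positives"]
        .apply(zero_years)
    )
    drop_pairs = absent[absent >= absence_years]
    for (site, sp), n in drop_pairs.items():
        log.append({"rule": "absence_years", "species_id": sp, "site_id": site,
                    "zero_years": int(n)})
    keep = ~fdp.set_index(["site_id", "species_id"]).index.isin(drop_pairs.index)
    filtered = fdp[keep]

    n_sites = filtered.groupby("species_id")["site_id"].nunique()
    drop_species = n_sites[n_sites < min_sites]
    for sp, n in drop_species.items():
        log.append({"rule": "min_sites", "species_id": sp, "n_sites": int(n)})
    filtered = filtered[~filtered["species_id"].isin(drop_species.index)]
    return filtered.reset_index(drop=True), log


@dataclass
class SynchronyResult:
    """Per-species synchrony indices plus drop provenance."""

    table: pd.DataFrame
    dropped_pairs: list[dict] = field(default_factory=list)
    flagged_species: list = field(default_factory=list)


def synchrony_index(delta: pd.DataFrame, min_overlap_years: int = 24) -> SynchronyResult:
    """Mean pairwise Pearson correlation of dFDP series across sites.

    For every pair of sites at which a species occurs, the two dFDP series
    are aligned on their shared years (the longer record truncated to the
    shorter one's coverage), Pearson's r is computed, and the species index
    is the unweighted mean over pairs.  Pairs with fewer than
    ``min_overlap_years`` shared years, or with a zero-variance series
    (r undefined), are dropped and logged; a species with no valid pair is
    flagged instead of indexed.
    """
    records = []
    dropped: list[dict] = []
    flagged: list = []
    for sp, sub in delta.groupby("species_id"):
        series = {
            site: s.set_index("year")["delta_fdp"]
            for site, s in sub.groupby("site_id")
        }
        sites = sorted(series)
        rs = []
        overlaps = []
        for a, b in itertools.combinations(sites, 2):
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < max(min_overlap_years, 2):
                dropped.append({"species_id": sp, "pair": (a, b),
                                "reason": "overlap", "n_years": int(len(shared))})
                continue
            x = series[a].loc[shared].to_numpy()
            y = series[b].loc[shared].to_numpy()
            if x.std() == 0 or y.std() == 0:
                dropped.append({"species_id": sp, "pair": (a, b),
                                "reason": "zero_variance", "n_years": int(len(shared))})
                continue
            rs.append(float(np.corrcoef(x, y)[0, 1]))
            overlaps.append(len(shared))
        if not rs:
            flagged.append(sp)
            continue
        records.append({
            "species_id": sp,
            "index": float(np.mean(rs)),
            "n_sites": len(sites),
            "n_pairs": len(rs),
            "mean_overlap_years": float(np.mean(overlaps)),
        })
    table = pd.DataFrame(records, columns=["species_id", "index", "n_sites",
                                           "n_pairs", "mean_overlap_years"])
    return SynchronyResult(table=table, dropped_pairs=dropped, flagged_species=flagged)


def species_covariates(fdp: pd.DataFrame, delta: pd.DataFrame) -> pd.DataFrame:
    """Per-species abundance, occupancy and trend covariates, z-scored.

    * abundance — mean FDP across all site-years;
    * avg_sites_occupied — mean over years of the number of sites with at
      least one positive visit;
    * trend — mean dFDP across site-years (negative under decline).

    Each covariate is z-standardised across the included species
    (``*_z`` columns); requires at least two species.
    """
    if fdp["species_id"].nunique() < 2:
        raise DataError("z-scoring species covariates needs >= 2 species")
    abundance = fdp.groupby("species_id")["fdp"].mean().rename("abundance")
    occupied = (
        fdp.assign(occ=fdp["positives"] > 0)
        .groupby(["species_id", "year"])["occ"].sum()
        .groupby("species_id").mean()
        .rename("avg_sites_occupied")
    )
    trend = delta.groupby("species_id")["delta_fdp"].mean().rename("trend")
    out = pd.concat([abundance, occupied, trend], axis=1).reset_index()
    for col in ("abundance", "avg_sites_occupied", "trend"):
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise DataError(f"covariate {col!r} is constant across species")
        out[f"{col}_z"] = (v - v.mean()) / sd
    return out
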