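"""Seasonal climate predictors on a water-year calendar.

Monthly weather is aggregated into seasonal values following a "water year"
that starts in the autumn of the previous calendar year, matching the
Mediterranean precipitation cycle of Northern California: autumn is
Sep-Nov of the previous calendar year, winter is Dec of the previous year
plus Jan-Feb of the current year, spring is Mar-May and summer Jun-Aug.
Seasonal temperature is the mean of the three monthly means; seasonal
precipitation is the sum of the three monthly totals.  Each site x variable
series is then z-scored across water-years so that regression coefficients
are comparable across sites.

The ENSO index is the mean sea-surface-temperature anomaly of December,
January and February of each water year (the seasonal peak of ENSO),
optionally z-scored across water-years like the weather predictors.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .data_io import DataError

SEASONS = ("autumn", "winter", "spring", "summer")

#: seasonal variables produced by :func:`aggregate_seasonal`
SEASONAL_VARIABLES = tuple(
    f"{season}_{kind}" for season in SEASONS for kind in ("temp", "precip")
)

#: the subset that enters the hierarchical model as local-weather predictors
MODEL_WEATHER_VARIABLES = (
    "winter_temp",
    "spring_temp",
    "winter_precip",
    "spring_precip",
    "summer_precip",
)


def water_year_season(year: int, month: int) -> tuple[int, str]:
    """Map a calendar (year, month) to (water_year, season).

    Sep-Nov of calendar year Y belong to water year Y+1 (autumn); so does
    December (winter).  Jan-Feb of Y are winter of water year Y; Mar-May
    spring and Jun-Aug summer of water year Y.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1-12, got {month}")
    if month >= 12:
        return year + 1, "winter"
    if month >= 9:
        return year + 1, "autumn"
    if month >= 6:
        return year, "summer"
    if month >= 3:
        return year, "spring"
    return year, "winter"


def zscore(values: np.ndarray | pd.Series, ddof: int = 0) -> np.ndarray:
    """Plain z-score; raises on zero spread."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("cannot z-score a constant (or empty) series")
    return (v - v.mean()) / sd


def aggregate_seasonal(weather: pd.DataFrame, zscored: bool = True) -> pd.DataFrame:
    """Aggregate monthly weather to z-scored water-year seasonal values.

    Parameters
    ----------
    weather
        Validated monthly table (``site_id, year, month, tmean, precip``).
    zscored
        If True (default), add a ``z`` column with the value standardised
        within each site x variable across water-years.

    Returns
    -------
    Long table ``site_id, water_year, variable, value[, z]`` with one row
    per complete season.  Seasons observed with fewer than three months
    (typically the boundary water-years) are dropped and reported in the
    ``attrs['incomplete']`` list of the result.
    """
    wy = [water_year_season(y, m) for y, m in zip(weather["year"], weather["month"])]
    df = weather.assign(water_year=[t[0] for t in wy], season=[t[1] for t in wy])
    grouped = df.groupby(["site_id", "water_year", "season"]).agg(
        tmean=("tmean", "mean"),
        precip=("precip", "sum"),
        n_months=("month", "size"),
    ).reset_index()

    incomplete = grouped[grouped["n_months"] != 3]
    complete = grouped[grouped["n_months"] == 3]

    long = pd.concat(
        [
            complete.assign(variable=complete["season"] + "_temp", value=complete["tmean"]),
            complete.assign(variable=complete["season"] + "_precip", value=complete["precip"]),
        ],
        ignore_index=True,
    )[["site_id", "water_year", "variable", "value"]].sort_values(
        ["site_id", "variable", "water_year"]
    ).reset_index(drop=True)

    if zscored:
        long["z"] = long.groupby(["site_id", "variable"])["value"].transform(
            lambda s: (s - s.mean()) / s.std(ddof=0)
        )
    long.attrs["incomplete"] = incomplete[["site_id", "water_year", "season", "n_months"]].to_dict(
        "records"
    )
    return long


def enso_winter_mean(ssta: pd.DataFrame, zscored: bool = True) -> pd.DataFrame:
    """Winter (Dec-Jan-Feb) mean SSTA per water year.

    A water year's value is the mean of exactly December of the previous
    calendar year and January and February of the current one; water-years
    missing any of the three months get no row.
    """
    wy = [water_year_season(y, m) for y, m in zip(ssta["year"], ssta["month"])]
    df = ssta.assign(water_year=[t[0] for t in wy], season=[t[1] for t in wy])
    winter = df[df["season"] == "winter"]
    agg = winter.groupby("water_year").agg(
        ssta_winter_mean=("ssta", "mean"), n_months=("month", "size")
    ).reset_index()
    out = agg[agg["n_months"] == 3].drop(columns="n_months").reset_index(drop=True)
    if zscored and len(out) > 1:
        out["ssta_z"] = zscore(out["ssta_winter_mean"])
    return out


def weather_redundancy_diagnostic(seasonal: pd.DataFrame) -> dict:
    """Summarise how strongly weather is shared across sites.

    Two readings are reported as a labelled diagnostic (neither feeds the
    downstream models): the mean pairwise cross-site Pearson correlation of
    each seasonal variable's yearly values, and the variance-explained
    spectrum of a principal-component decomposition of the
    year x (site, variable) matrix.
    """
    sites = sorted(seasonal["site_id"].unique())
    if len(sites) < 2:
        raise DataError("diagnostic needs at least two sites")
    wide = seasonal.pivot_table(
        index="water_year", columns=["site_id", "variable"], values="value"
    ).dropna()
    if len(wide) < 2:
        raise DataError("diagnostic needs at least two complete water-years")

    per_variable: dict[str, float] = {}
    for var in seasonal["variable"].unique():
        cols = [c for c in wide.columns if c[1] == var]
        rs = [
            wide[a].corr(wide[b])
            for a, b in itertools.combinations(cols, 2)
            if wide[a].std() > 0 and wide[b].std() > 0
        ]
        if rs:
            per_variable[var] = float(np.mean(np.abs(rs)))
    mean_abs = float(np.mean(list(per_variable.values())))

    X = wide.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    sv = np.linalg.svd(X, compute_uv=False)
    var_explained = sv**2 / np.sum(sv**2)

    return {
        "mean_abs_cross_site_correlation": mean_abs,
        "cross_site_correlation_by_variable": per_variable,
        "pc_variance_explained": var_explained.tolist(),
        "n_sites": len(sites),
        "n_years": int(len(wide)),
    }
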