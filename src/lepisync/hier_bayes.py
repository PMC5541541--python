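"""Hierarchical Bayesian binomial logit model of climate sensitivity.

For one species, day positives out of visits in water-year *i* at site *j*
are Binomial(v_ij, p_ij) with

    logit(p_ij) = mu_j + b1j winter_temp + b2j spring_temp
                + b3j winter_precip + b4j spring_precip + b5j summer_precip
                + b6j SSTA + b7j year,

all predictors z-scored.  Site-level intercepts and slopes are drawn from
transect-wide normals, mu_j ~ N(mu_mu, tau_mu) and b_kj ~ N(mu_bk, tau_bk)
with precisions tau, under vague hyperpriors mu ~ N(0, precision 1e-5)
(variance 1e5) and tau ~ Gamma(shape 0.1, rate 1e-3).  The normal/gamma
parameterisation follows the Gibbs-sampler convention (mean-precision,
shape-rate), the only reading under which these hyperpriors are vague.

Sampling is Gibbs for the conjugate transect-wide means and precisions and
adaptive random-walk Metropolis for each site-level coefficient, with
proposal adaptation frozen after burn-in to preserve detailed balance.
The posterior mean of each transect-wide slope mu_bk is the species'
climate response used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MODEL_TERMS
from . import climate

# hyperprior constants (mean-precision / shape-rate convention)
HYPER_MEAN_PRECISION = 1.0e-5
TAU_SHAPE = 0.1
TAU_RATE = 1.0e-3

N_TERMS = len(MODEL_TERMS)


@dataclass
class DesignMatrix:
    """Aligned response and predictors for one species.

    Rows are (site, water_year) pairs that passed the inclusion rules and
    have complete climate predictors; ``site_index`` maps each row to
    ``site_ids``.  ``X`` columns follow :data:`lepisync.synthetic.MODEL_TERMS`.
    """

    species_id: object
    site_ids: list
    site_index: np.ndarray      # (n,) int
    water_year: np.ndarray      # (n,) int
    y: np.ndarray               # positives, (n,)
    v: np.ndarray               # visits, (n,)
    X: np.ndarray               # (n, 7) z-scored predictors
    dropped: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def __len__(self) -> int:
        return len(self.y)


def build_design(species_id, fdp: pd.DataFrame, seasonal: pd.DataFrame,
                 enso: pd.DataFrame) -> DesignMatrix:
    """Join FDP records with climate predictors into a model design.

    The year covariate is centered on the midpoint of the observed window
    and scaled to unit standard deviation, mirroring the z-scoring of the
    weather predictors.  Site-years with FDP but incomplete climate are
    dropped and recorded in ``dropped``.
    """
    sub = fdp[fdp["species_id"] == species_id]
    if len(sub) == 0:
        raise ValueError(f"no FDP records for species {species_id!r}")
    wide = seasonal.pivot_table(index=["site_id", "water_year"],
                                columns="variable", values="z")
    missing_vars = set(climate.MODEL_WEATHER_VARIABLES) - set(wide.columns)
    if missing_vars:
        raise ValueError(f"seasonal table lacks variables: {sorted(missing_vars)}")
    enso_z = enso.set_index("water_year")["ssta_z"]

    rows, dropped = [], []
    for rec in sub.itertuples(index=False):
        key = (rec.site_id, rec.year)
        if key not in wide.index or rec.year not in enso_z.index:
            dropped.append({"site_id": rec.site_id, "water_year": int(rec.year),
                            "reason": "missing_climate"})
            continue
        weather_z = wide.loc[key, list(climate.MODEL_WEATHER_VARIABLES)].to_numpy()
        if np.isnan(weather_z).any():
            dropped.append({"site_id": rec.site_id, "water_year": int(rec.year),
                            "reason": "missing_climate"})
            continue
        rows.append((rec.site_id, int(rec.year), int(rec.positives),
                     int(rec.visits), weather_z, float(enso_z.loc[rec.year])))
    if not rows:
        raise ValueError(f"no complete design rows for species {species_id!r}")

    site_ids = sorted({r[0] for r in rows})
    site_lookup = {s: i for i, s in enumerate(site_ids)}
    rows.sort(key=lambda r: (site_lookup[r[0]], r[1]))
    n = len(rows)
    X = np.empty((n, N_TERMS))
    site_index = np.empty(n, dtype=int)
    water_year = np.empty(n, dtype=int)
    y = np.empty(n, dtype=int)
    v = np.empty(n, dtype=int)
    for i, (site, wy, yy, vv, wz, ez) in enumerate(rows):
        site_index[i], water_year[i], y[i], v[i] = site_lookup[site], wy, yy, vv
        X[i, :5] = wz
        X[i, 5] = ez
    yrs = water_year.astype(float)
    sd = yrs.std(ddof=0)
    X[:, 6] = (yrs - yrs.mean()) / sd if sd > 0 else 0.0
    return DesignMatrix(species_id=species_id, site_ids=site_ids,
                        site_index=site_index, water_year=water_year,
                        y=y, v=v, X=X, dropped=dropped)


@dataclass
class ModelState:
    """One point in parameter space (site-level and transect-wide)."""

    mu: np.ndarray              # (J,)
    beta: np.ndarray            # (J, 7)
    mu_mu: float
    mu_beta: np.ndarray         # (7,)
    tau_mu: float
    tau_beta: np.ndarray        # (7,)

    @classmethod
    def initial(cls, n_sites: int) -> "ModelState":
        # neutral start on z-scored predictors: everything at 0, precisions 1
        return cls(mu=np.zeros(n_sites), beta=np.zeros((n_sites, N_TERMS)),
                   mu_mu=0.0, mu_beta=np.zeros(N_TERMS),
                   tau_mu=1.0, tau_beta=np.ones(N_TERMS))


def _binom_loglik(alpha: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    # y*log(p) + (v-y)*log(1-p) = y*alpha - v*log(1 + e^alpha), up to binom coef
    return float(np.sum(y * alpha - v * np.logaddexp(0.0, alpha)))


def log_posterior(state: ModelState, design: DesignMatrix) -> float:
    """Unnormalised log posterior density at ``state``.

    Binomial likelihood plus hierarchical normal terms for the site-level
    coefficients plus the vague hyperpriors, up to an additive constant.
    Non-positive precisions return ``-inf`` (rejected state).
    """
    if state.tau_mu <= 0 or np.any(state.tau_beta <= 0):
        return -np.inf
    alpha = state.mu[design.site_index] + np.einsum(
        "nk,nk->n", design.X, state.beta[design.site_index]
    )
    lp = _binom_loglik(alpha, design.y, design.v)
    J = design.n_sites
    lp += 0.5 * J * np.log(state.tau_mu) - 0.5 * state.tau_mu * np.sum(
        (state.mu - state.mu_mu) ** 2
    )
    lp += float(np.sum(
        0.5 * J * np.log(state.tau_beta)
        - 0.5 * state.tau_beta * np.sum((state.beta - state.mu_beta) ** 2, axis=0)
    ))
    lp += -0.5 * HYPER_MEAN_PRECISION * (
        state.mu_mu**2 + float(np.sum(state.mu_beta**2))
    )
    for tau in (state.tau_mu, *state.tau_beta):
        lp += (TAU_SHAPE - 1.0) * np.log(tau) - TAU_RATE * tau
    return lp


def gibbs_hyper_mean(values: np.ndarray, tau: float,
                     rng: np.random.Generator) -> float:
    """Conjugate normal draw for a transect-wide mean given site values."""
    prec = HYPER_MEAN_PRECISION + len(values) * tau
    mean = tau * float(np.sum(values)) / prec
    return mean + rng.standard_normal() / np.sqrt(prec)


def gibbs_hyper_precision(values: np.ndarray, center: float,
                          rng: np.random.Generator) -> float:
    """Conjugate gamma draw for a transect-wide precision given site values."""
    shape = TAU_SHAPE + 0.5 * len(values)
    rate = TAU_RATE + 0.5 * float(np.sum((values - center) ** 2))
    return rng.gamma(shape, 1.0 / rate)


@dataclass
class McmcDraws:
    """Post-burn-in draws from all chains, plus sampler bookkeeping."""

    design: DesignMatrix
    mu_mu: np.ndarray           # (chains, n_kept)
    mu_beta: np.ndarray         # (chains, n_kept, 7)
    tau_mu: np.ndarray
    tau_beta: np.ndarray        # (chains, n_kept, 7)
    site_mu: np.ndarray         # (chains, n_kept, J)
    site_beta: np.ndarray       # (chains, n_kept, J, 7)
    acceptance: np.ndarray      # (chains, J, 8) mean acceptance after burn-in
    n_iter: int
    burn_in: int
    seed: object

    @property
    def n_chains(self) -> int:
        return self.mu_mu.shape[0]

    def scalar_parameters(self) -> dict[str, np.ndarray]:
        """Flat {name: (chains, draws)} view of every scalar parameter."""
        out = {"mu_mu": self.mu_mu, "tau_mu": self.tau_mu}
        for k, term in enumerate(MODEL_TERMS):
            out[f"mu_beta[{term}]"] = self.mu_beta[:, :, k]
            out[f"tau_beta[{term}]"] = self.tau_beta[:, :, k]
        for j, site in enumerate(self.design.site_ids):
            out[f"mu[{site}]"] = self.site_mu[:, :, j]
            for k, term in enumerate(MODEL_TERMS):
                out[f"beta[{site},{term}]"] = self.site_beta[:, :, j, k]
        return out


def _run_chain(design: DesignMatrix, n_iter: int, burn_in: int,
               rng: np.random.Generator, initial_scale: float,
               target_accept: float) -> dict:
    y = design.y.astype(float)
    v = design.v.astype(float)
    X = design.X
    site = design.site_index
    J = design.n_sites
    state = ModelState.initial(J)

    alpha = state.mu[site] + np.einsum("nk,nk->n", X, state.beta[site])
    # per-row log-lik as a function of alpha, summed per site via bincount
    scales = np.full((J, 1 + N_TERMS), initial_scale)
    accept_count = np.zeros((J, 1 + N_TERMS))

    kept = n_iter
    out = {
        "mu_mu": np.empty(kept), "tau_mu": np.empty(kept),
        "mu_beta": np.empty((kept, N_TERMS)), "tau_beta": np.empty((kept, N_TERMS)),
        "site_mu": np.empty((kept, J)), "site_beta": np.empty((kept, J, N_TERMS)),
    }

    total = burn_in + n_iter
    for it in range(total):
        adapting = it < burn_in
        gamma = 2.0 / (1.0 + it) ** 0.6 if adapting else 0.0

        for c in range(1 + N_TERMS):
            if c == 0:
                theta = state.mu
                xcol = None
                prior_mean, prior_tau = state.mu_mu, state.tau_mu
            else:
                k = c - 1
                theta = state.beta[:, k]
                xcol = X[:, k]
                prior_mean, prior_tau = state.mu_beta[k], state.tau_beta[k]
            step = scales[:, c] * rng.standard_normal(J)
            d_alpha = step[site] if xcol is None else step[site] * xcol
            new_alpha = alpha + d_alpha
            d_ll_row = (
                y * d_alpha
                - v * (np.logaddexp(0.0, new_alpha) - np.logaddexp(0.0, alpha))
            )
            d_ll = np.bincount(site, weights=d_ll_row, minlength=J)
            prop = theta + step
            d_prior = -0.5 * prior_tau * ((prop - prior_mean) ** 2
                                          - (theta - prior_mean) ** 2)
            acc = np.log(rng.random(J)) < d_ll + d_prior
            theta += step * acc
            alpha += d_alpha * acc[site]
            if adapting:
                scales[:, c] *= np.exp(gamma * (acc - target_accept))
            else:
                accept_count[:, c] += acc

        # conjugate Gibbs updates for the transect-wide hyperparameters
        state.mu_mu = gibbs_hyper_mean(state.mu, state.tau_mu, rng)
        state.tau_mu = gibbs_hyper_precision(state.mu, state.mu_mu, rng)
        for k in range(N_TERMS):
            state.mu_beta[k] = gibbs_hyper_mean(state.beta[:, k],
                                                state.tau_beta[k], rng)
            state.tau_beta[k] = gibbs_hyper_precision(state.beta[:, k],
                                                      state.mu_beta[k], rng)

        if not adapting:
            t = it - burn_in
            out["mu_mu"][t] = state.mu_mu
            out["tau_mu"][t] = state.tau_mu
            out["mu_beta"][t] = state.mu_beta
            out["tau_beta"][t] = state.tau_beta
            out["site_mu"][t] = state.mu
            out["site_beta"][t] = state.beta
    out["acceptance"] = accept_count / max(n_iter, 1)
    return out


def run_mcmc(design: DesignMatrix, n_iter: int = 30_000, burn_in: int = 1_000,
             chains: int = 2, seed: int | np.random.SeedSequence | None = None,
             initial_scale: float = 0.2,
             target_accept: float = 0.35) -> McmcDraws:
    """Sample the posterior with Gibbs + adaptive random-walk Metropolis.

    ``n_iter`` draws per chain are retained after ``burn_in`` adaptation
    iterations; proposal scales adapt toward ``target_accept`` during
    burn-in only.  The same seed yields bitwise-identical draws.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    if design.n_sites < 2:
        raise ValueError("hierarchical model needs >= 2 sites")
    if chains < 2:
        warnings.warn("fewer than 2 chains: split R-hat will be unavailable")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(chains)
    results = [
        _run_chain(design, n_iter, burn_in, np.random.default_rng(child),
                   initial_scale, target_accept)
        for child in children
    ]
    stack = lambda key: np.stack([r[key] for r in results])
    return McmcDraws(
        design=design,
        mu_mu=stack("mu_mu"), mu_beta=stack("mu_beta"),
        tau_mu=stack("tau_mu"), tau_beta=stack("tau_beta"),
        site_mu=stack("site_mu"), site_beta=stack("site_beta"),
        acceptance=stack("acceptance"),
        n_iter=n_iter, burn_in=burn_in, seed=ss.entropy,
    )


def diagnose(draws: McmcDraws) -> pd.DataFrame:
    """Split R-hat and autocorrelation-based ESS for every scalar parameter."""
    import arviz as az

    params = draws.scalar_parameters()
    single = draws.n_chains < 2
    if single:
        warnings.warn("single chain: R-hat omitted")
    records = []
    for name, arr in params.items():
        ds = az.convert_to_dataset(arr)
        ess = float(az.ess(ds)["x"].values)
        rhat = np.nan if single else float(az.rhat(ds)["x"].values)
        records.append({"parameter": name, "ess": ess, "rhat": rhat})
    return pd.DataFrame(records)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries and the species' response vector."""

    table: pd.DataFrame                 # parameter, mean, sd, q2.5, q97.5, ess, rhat
    response: pd.Series                 # posterior means of mu_beta, by term

    def credible_interval(self, parameter: str) -> tuple[float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["q2.5"]), float(row["q97.5"])


def summarize(draws: McmcDraws, diagnostics: bool = True) -> PosteriorSummary:
    """Posterior mean/sd/quantiles per parameter; transect-wide responses.

    The species climate response is the vector of posterior means of the
    seven transect-wide slopes ``mu_beta``.
    """
    diag = diagnose(draws).set_index("parameter") if diagnostics else None
    records = []
    for name, arr in draws.scalar_parameters().items():
        flat = arr.reshape(-1)
        rec = {
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
        }
        if diag is not None:
            rec["ess"] = float(diag.loc[name, "ess"])
            rec["rhat"] = float(diag.loc[name, "rhat"])
        records.append(rec)
    table = pd.DataFrame(records)
    response = pd.Series(
        draws.mu_beta.reshape(-1, N_TERMS).mean(axis=0), index=list(MODEL_TERMS),
        name=draws.design.species_id,
    )
    return PosteriorSummary(table=table, response=response)
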