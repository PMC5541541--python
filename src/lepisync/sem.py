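"""Structural equation models of interspecific variation in synchrony.

Models are expressed in the reticular (all-variables, "RAM") formulation:
with A the matrix of directed paths (A[i, j] is the coefficient of j -> i),
S the symmetric matrix of (residual) variances and covariances, and F the
selector of observed variables, the model-implied covariance is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F'.

Free parameters are estimated by minimising the Wishart ML discrepancy

    F_ML = log|Sigma| + tr(S_sample Sigma^-1) - log|S_sample| - p

with an analytic gradient; chi-square is (n - 1) F_ML at the optimum,
degrees of freedom p(p+1)/2 minus the number of free parameters, and AIC
uses the full multivariate-normal log-likelihood.  Standard errors come
from the inverse observed information.

Three canned model structures compare drivers of synchrony: a "dispersal"
model (two latent dispersal factors measured by four traits), a "climate"
model (two latent climate-sensitivity factors measured by five weather
responses, with the ENSO response as a standalone observed predictor), and
a "combined" model adding dispersal -> climate links.  Their exact free
parameter sets are tuned so that model degrees of freedom are 4, 9 and 18
respectively.  A "scores" variant replaces each measurement model by
precomputed factor scores entered as observed variables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemSpec", "SemFit", "ExperimentResult", "canned_models", "implied_sigma",
    "fit", "standardize", "r_squared", "simulate_from_spec",
    "exclusion_experiment",
]

# canonical variable names used by the canned models
DISPERSAL_TRAITS = ("wingspan", "geographic_range", "diet_breadth",
                    "elevational_range")
CLIMATE_RESPONSES = ("r_winter_temp", "r_spring_temp", "r_winter_precip",
                     "r_spring_precip", "r_summer_precip")
ENSO_RESPONSE = "r_ssta"
OUTCOMES = ("synchrony", "avg_sites_occupied", "abundance", "trend")


@dataclass(frozen=True)
class Param:
    """One entry of A or S: a directed path or a (co)variance."""

    matrix: str          # 'A' (row <- col path) or 'S' (symmetric)
    row: str
    col: str
    free: bool
    value: float         # fixed value, or starting value if free

    @property
    def label(self) -> str:
        op = "<-" if self.matrix == "A" else "~~"
        return f"{self.row}{op}{self.col}"


class SemSpec:
    """A structural equation model specification.

    Build with :meth:`add_loading`, :meth:`add_path`, :meth:`add_cov` and
    :meth:`add_var`; every latent needs one indicator loading fixed to 1
    (the marker) to set its scale.
    """

    def __init__(self, observed: list[str], latents: list[str] | None = None,
                 name: str = "sem"):
        self.observed = list(observed)
        self.latents = list(latents or [])
        self.name = name
        self.params: list[Param] = []

    # -- construction -------------------------------------------------
    def _check(self, *names: str) -> None:
        for v in names:
            if v not in self.observed and v not in self.latents:
                raise ValueError(f"unknown variable {v!r} in model {self.name!r}")

    def add_path(self, source: str, target: str, free: bool = True,
                 value: float = 0.0) -> "SemSpec":
        self._check(source, target)
        self.params.append(Param("A", target, source, free, value))
        return self

    def add_loading(self, latent: str, indicator: str, fixed: float | None = None,
                    start: float = 0.7) -> "SemSpec":
        self._check(latent, indicator)
        if fixed is not None:
            self.params.append(Param("A", indicator, latent, False, fixed))
        else:
            self.params.append(Param("A", indicator, latent, True, start))
        return self

    def add_var(self, var: str, free: bool = True, value: float = 0.5) -> "SemSpec":
        self._check(var)
        self.params.append(Param("S", var, var, free, value))
        return self

    def add_cov(self, a: str, b: str, free: bool = True,
                value: float = 0.0) -> "SemSpec":
        self._check(a, b)
        self.params.append(Param("S", a, b, free, value))
        return self

    # -- bookkeeping ---------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return self.observed + self.latents

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def free_params(self) -> list[Param]:
        return [p for p in self.params if p.free]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free

    def endogenous(self) -> set[str]:
        """Variables receiving at least one directed path (incl. indicators)."""
        return {p.row for p in self.params if p.matrix == "A"}

    def validate(self) -> None:
        if self.df < 0:
            raise ValueError(f"negative df ({self.df}) in model {self.name!r}")
        seen = {}
        for p in self.params:
            key = (p.matrix, *sorted((p.row, p.col))) if p.matrix == "S" else (
                "A", p.row, p.col)
            if key in seen:
                raise ValueError(f"duplicate parameter {p.label} in {self.name!r}")
            seen[key] = p
        for lat in self.latents:
            markers = [p for p in self.params
                       if p.matrix == "A" and p.col == lat and not p.free
                       and p.row in self.observed]
            loadings = [p for p in self.params
                        if p.matrix == "A" and p.col == lat]
            if loadings and not markers and not any(
                not q.free for q in self.params
                if q.matrix == "S" and q.row == q.col == lat
            ):
                raise ValueError(f"latent {lat!r} has no fixed marker loading")

    # -- matrix assembly ----------------------------------------------
    def _compiled(self) -> dict:
        """Index arrays for vectorised assembly and gradient extraction."""
        idx = {v: i for i, v in enumerate(self.variables)}
        rows = np.array([idx[p.row] for p in self.params], dtype=int)
        cols = np.array([idx[p.col] for p in self.params], dtype=int)
        is_A = np.array([p.matrix == "A" for p in self.params])
        free = np.array([p.free for p in self.params])
        fixed_vals = np.array([0.0 if p.free else p.value
                               for p in self.params])
        cache = {
            "m": len(self.variables), "rows": rows, "cols": cols,
            "is_A": is_A, "free": free, "fixed_vals": fixed_vals,
            "is_diag": rows == cols, "n_params": len(self.params),
        }
        self.__dict__["_compiled_cache"] = cache
        return cache

    def compiled(self) -> dict:
        cache = self.__dict__.get("_compiled_cache")
        if cache is None or cache["n_params"] != len(self.params):
            cache = self._compiled()
        return cache

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Assemble (A, S) from the free-parameter vector ``theta``."""
        c = self.compiled()
        values = c["fixed_vals"].copy()
        values[c["free"]] = theta
        A = np.zeros((c["m"], c["m"]))
        S = np.zeros((c["m"], c["m"]))
        a, s = c["is_A"], ~c["is_A"]
        A[c["rows"][a], c["cols"][a]] = values[a]
        S[c["rows"][s], c["cols"][s]] = values[s]
        S[c["cols"][s], c["rows"][s]] = values[s]
        return A, S

    def start_vector(self, sample_cov: np.ndarray | None = None) -> np.ndarray:
        """Starting values: stored starts, with observed exogenous variances
        and covariances seeded from the sample covariance when available."""
        idx = {v: i for i, v in enumerate(self.observed)}
        out = []
        endo = self.endogenous()
        for p in self.free_params:
            val = p.value
            if sample_cov is not None and p.matrix == "S" and \
                    p.row in idx and p.col in idx:
                if p.row == p.col:
                    sv = sample_cov[idx[p.row], idx[p.row]]
                    val = sv if p.row not in endo else 0.5 * sv
                elif p.row not in endo and p.col not in endo:
                    val = sample_cov[idx[p.row], idx[p.col]]
            out.append(val)
        return np.asarray(out, dtype=float)

    #: smallest admissible free variance; on standardised data this is 1%
    #: of a variable's variance and acts as the Heywood-case guard
    VARIANCE_FLOOR = 1e-2

    def bounds(self) -> list[tuple[float | None, float | None]]:
        # variances bounded away from zero; everything else unconstrained
        return [
            (self.VARIANCE_FLOOR, None) if (p.matrix == "S" and p.row == p.col)
            else (None, None)
            for p in self.free_params
        ]


def implied_sigma(spec: SemSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the observed variables at ``theta``."""
    A, S = spec.matrices(np.asarray(theta, dtype=float))
    m = A.shape[0]
    I = np.eye(m)
    try:
        B = np.linalg.inv(I - A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("(I - A) is singular: non-recursive structure") from exc
    G = B[: spec.n_observed, :]
    return G @ S @ G.T


def _fml_and_grad(spec: SemSpec, theta: np.ndarray, S_samp: np.ndarray,
                  logdet_samp: float) -> tuple[float, np.ndarray]:
    p = spec.n_observed
    A, S = spec.matrices(theta)
    m = A.shape[0]
    B = np.linalg.inv(np.eye(m) - A)
    G = B[:p, :]
    sigma = G @ S @ G.T
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10 + float(np.sum(theta**2)), np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    sigma_inv = np.linalg.inv(sigma)
    fml = logdet + float(np.sum(sigma_inv * S_samp)) - logdet_samp - p

    W = sigma_inv - sigma_inv @ S_samp @ sigma_inv
    GtW = G.T @ W                      # m x p
    P = GtW @ G                        # m x m, for S-parameters
    Q = GtW @ (G @ S @ B.T)            # m x m, for A-parameters
    c = spec.compiled()
    free = c["free"]
    r, col = c["rows"][free], c["cols"][free]
    a_mask = c["is_A"][free]
    diag = c["is_diag"][free]
    grad = np.where(a_mask, 2.0 * Q[r, col],
                    np.where(diag, P[r, col], 2.0 * P[r, col]))
    return fml, grad


@dataclass
class SemFit:
    """A fitted structural equation model."""

    spec: SemSpec
    theta: np.ndarray
    n: int
    sample_cov: np.ndarray
    fml: float
    chi2: float
    df: int
    p_value: float
    aic: float
    log_likelihood: float
    converged: bool
    grad_norm: float
    params: pd.DataFrame = field(repr=False)   # label, estimate, se, z, p, std
    chi2_convention: str = "n-1"
    n_weak_directions: int = 0
    #: False for improper solutions (the residual/latent covariance matrix
    #: S is not positive semi-definite, e.g. a latent block gone degenerate)
    proper: bool = True

    @property
    def sigma(self) -> np.ndarray:
        return implied_sigma(self.spec, self.theta)

    def sigma_all(self) -> np.ndarray:
        """Implied covariance over all variables, latents included."""
        A, S = self.spec.matrices(self.theta)
        B = np.linalg.inv(np.eye(A.shape[0]) - A)
        return B @ S @ B.T

    def estimate(self, label: str) -> float:
        return float(self.params.set_index("label").loc[label, "estimate"])

    def r2(self, variable: str) -> float:
        return r_squared(self, variable)


def fit(spec: SemSpec, data: pd.DataFrame, chi2_convention: str = "n-1",
        max_restarts: int = 3, theta_start: np.ndarray | None = None) -> SemFit:
    """Fit ``spec`` to an n x p species table by maximum likelihood.

    ``chi2_convention`` selects (n-1)*F_ML (default) or n*F_ML.
    ``theta_start`` warm-starts the optimiser (used by the exclusion
    experiments, which refit on subsamples of the same data).  Raises on
    non-convergence (after a few deterministic jittered restarts) or a
    non-positive-definite sample covariance.
    """
    spec.validate()
    missing = [v for v in spec.observed if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    X = data[spec.observed].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    S_samp = np.cov(X, rowvar=False, ddof=1)
    sign, logdet_samp = np.linalg.slogdet(S_samp)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite; "
                         "check for collinear or constant variables")

    fun = lambda th: _fml_and_grad(spec, th, S_samp, logdet_samp)
    theta0 = (np.asarray(theta_start, dtype=float) if theta_start is not None
              else spec.start_vector(S_samp))
    bounds = spec.bounds()
    lower = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])

    def projected_norm(theta: np.ndarray, g: np.ndarray) -> float:
        # at an active variance bound an inward-pointing gradient is optimal
        pg = g.copy()
        pg[(theta <= lower + 1e-8) & (g > 0)] = 0.0
        return float(np.linalg.norm(pg))

    cold = spec.start_vector(S_samp)
    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            start = theta0
        elif attempt == 1 and theta_start is not None:
            start = cold     # warm start may sit in a degenerate basin
        else:
            start = cold + 0.1 * rng.standard_normal(cold.shape)
        start = np.clip(start, lower, np.inf)
        res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 4000, "maxfun": 12000,
                                         "ftol": 1e-15, "gtol": 1e-9})
        theta_r, fml_r = _newton_polish(fun, res.x, float(res.fun), lower)
        g_r = fun(theta_r)[1]
        if best is None or fml_r < best[1]:
            best = (theta_r, fml_r, g_r)
        if fml_r < 1e9 and projected_norm(theta_r, g_r) < 1e-6:
            best = (theta_r, fml_r, g_r)
            break
    theta_hat, fml_hat, grad_hat = best
    grad_norm = projected_norm(theta_hat, grad_hat)

    # convergence by Newton decrement: the predicted F_ML decrease
    # 0.5 g' H^+ g must be negligible.  This is invariant to the wild
    # parameter scaling of near-saturated latent models (curvatures here
    # can span ten orders of magnitude, making a raw gradient norm
    # meaningless); directions with negligible curvature (empirically
    # near-unidentified parameter combinations, along which F_ML is flat)
    # are counted and reported rather than allowed to block convergence
    H_num = _numeric_hessian(fun, theta_hat) if fml_hat < 1e9 else None
    n_weak = 0
    if H_num is not None:
        active = (theta_hat <= lower + 1e-8) & (grad_hat > 0)
        free = ~active
        evals, evecs = np.linalg.eigh(H_num[np.ix_(free, free)])
        keep = evals > 1e-8 * max(float(evals[-1]), 1.0)
        n_weak = int((~keep).sum())
        grad_id = evecs[:, keep].T @ grad_hat[free]
        # 1e-5 in F_ML units keeps chi-square stable to ~1e-3 at n ~ 100
        decrement = 0.5 * float(np.sum(grad_id**2 / evals[keep]))
        converged = bool(decrement < 1e-5 or grad_norm < 1e-4)
    else:
        decrement = np.inf
        converged = False
    if not converged:
        raise RuntimeError(
            f"SEM {spec.name!r} failed to converge: F_ML={fml_hat:.4g}, "
            f"|grad|={grad_norm:.3g}, Newton decrement={decrement:.3g}"
        )
    theta = theta_hat
    fml = float(fml_hat)
    scale = (n - 1) if chi2_convention == "n-1" else n
    chi2 = max(scale * fml, 0.0)
    df = spec.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    sigma = implied_sigma(spec, theta)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    trace_term = float(np.sum(np.linalg.inv(sigma) * S_samp))
    loglik = -0.5 * n * (p * math.log(2 * math.pi) + logdet_m + trace_term)
    aic = -2.0 * loglik + 2.0 * spec.n_free

    acov = np.linalg.pinv(H_num * (n - 1) / 2.0)
    se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    table = _param_table(spec, theta, se)
    # improper solutions: S (hence the implied covariance over all
    # variables, a congruence of S) fails positive semi-definiteness
    _, S_hat = spec.matrices(theta)
    proper = bool(np.linalg.eigvalsh(S_hat).min() > -1e-8)
    fit_obj = SemFit(spec=spec, theta=theta, n=n, sample_cov=S_samp, fml=fml,
                     chi2=chi2, df=df, p_value=p_value, aic=aic,
                     log_likelihood=loglik, converged=converged,
                     grad_norm=grad_norm, params=table,
                     chi2_convention=chi2_convention,
                     n_weak_directions=n_weak, proper=proper)
    fit_obj.params["std_estimate"] = standardize(fit_obj)["std_estimate"]
    return fit_obj


def _numeric_hessian(fun, theta: np.ndarray) -> np.ndarray:
    """Finite-difference Hessian from the analytic gradient (central)."""
    q = len(theta)
    H = np.empty((q, q))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for i in range(q):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        H[i] = (fun(tp)[1] - fun(tm)[1]) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _newton_polish(fun, theta: np.ndarray, fml: float, lower: np.ndarray,
                   max_steps: int = 150) -> tuple[np.ndarray, float]:
    """Active-set damped Newton refinement after the quasi-Newton phase.

    Coordinates pinned at their variance floor with an inward-pointing
    gradient are frozen out of each Newton system (they are KKT-optimal);
    Levenberg-Marquardt damping handles the near-flat directions that make
    these close-to-saturated models slow for first-order methods.
    """
    if fml >= 1e9:
        return theta, fml
    mu = 1e-6
    for _ in range(max_steps):
        f0, g = fun(theta)
        active = (theta <= lower + 1e-9) & (g > 0)
        free = ~active
        if not free.any() or np.linalg.norm(g[free]) < 1e-9:
            break
        H = _numeric_hessian(fun, theta)[np.ix_(free, free)]
        scale = max(float(np.mean(np.abs(np.diag(H)))), 1e-12)
        nf = int(free.sum())
        improved = False
        for _ in range(25):  # Levenberg-Marquardt damping sweep
            try:
                step = np.linalg.solve(H + mu * scale * np.eye(nf), g[free])
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta.copy()
            cand[free] = theta[free] - step
            np.maximum(cand, np.where(np.isfinite(lower), lower + 1e-9,
                                      -np.inf), out=cand)
            f1, _ = fun(cand)
            if f1 < f0 - 1e-15:
                theta, fml, improved = cand, f1, True
                mu = max(mu / 3.0, 1e-10)
                break
            mu *= 10.0
            if mu > 1e10:
                break
        if not improved:
            break
    return theta, fun(theta)[0]


def _param_table(spec: SemSpec, theta: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    rows = []
    it = iter(range(len(theta)))
    for prm in spec.params:
        if prm.free:
            i = next(it)
            est, s = float(theta[i]), float(se[i])
            z = est / s if s > 0 else np.nan
            pv = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        else:
            est, s, z, pv = prm.value, np.nan, np.nan, np.nan
        rows.append({"label": prm.label, "matrix": prm.matrix, "lhs": prm.row,
                     "rhs": prm.col, "free": prm.free, "estimate": est,
                     "se": s, "z": z, "p": pv})
    return pd.DataFrame(rows)


def standardize(fit_obj: SemFit) -> pd.DataFrame:
    """Standardised estimates using model-implied SDs (latents included)."""
    cov_all = fit_obj.sigma_all()
    sd = np.sqrt(np.clip(np.diag(cov_all), 0.0, None))
    if np.any(sd == 0):
        zero = [fit_obj.spec.variables[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero implied variance for {zero}")
    idx = {v: i for i, v in enumerate(fit_obj.spec.variables)}
    table = fit_obj.params.copy()
    std = []
    for rec in table.itertuples(index=False):
        i, j = idx[rec.lhs], idx[rec.rhs]
        if rec.matrix == "A":
            std.append(rec.estimate * sd[j] / sd[i])
        elif rec.lhs == rec.rhs:
            std.append(rec.estimate / cov_all[i, i])
        else:
            std.append(rec.estimate / (sd[i] * sd[j]))
    table["std_estimate"] = std
    return table


def r_squared(fit_obj: SemFit, variable: str) -> float:
    """1 - residual/implied variance for an endogenous variable."""
    spec = fit_obj.spec
    if variable not in spec.endogenous():
        raise ValueError(f"{variable!r} is exogenous; R^2 undefined")
    A, S = spec.matrices(fit_obj.theta)
    i = spec.variables.index(variable)
    total = fit_obj.sigma_all()[i, i]
    return float(1.0 - S[i, i] / total)


def simulate_from_spec(spec: SemSpec, theta: np.ndarray, n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw an n x p observed-data table from the implied covariance."""
    sigma = implied_sigma(spec, np.asarray(theta, dtype=float))
    X = rng.multivariate_normal(np.zeros(spec.n_observed), sigma, size=n,
                                method="cholesky")
    return pd.DataFrame(X, columns=spec.observed)


# ---------------------------------------------------------------------------
# canned model structures


def _measurement_dispersal(spec: SemSpec) -> None:
    # orthogonal latents (the zero covariance anchors the factor rotation,
    # which near-saturated structural parts would otherwise leave free)
    spec.add_loading("Dispersal1", "diet_breadth", fixed=1.0)
    spec.add_loading("Dispersal1", "wingspan")
    spec.add_loading("Dispersal1", "geographic_range")
    spec.add_loading("Dispersal1", "elevational_range")
    spec.add_loading("Dispersal2", "wingspan", fixed=1.0)
    spec.add_loading("Dispersal2", "geographic_range")
    spec.add_loading("Dispersal2", "elevational_range")
    for v in DISPERSAL_TRAITS:
        spec.add_var(v)
    spec.add_var("Dispersal1", value=0.3)
    spec.add_var("Dispersal2", value=0.3)
    spec.add_cov("Dispersal1", "Dispersal2", free=False, value=0.0)


def _measurement_climate(spec: SemSpec) -> None:
    spec.add_loading("Climate1", "r_spring_temp", fixed=1.0)
    spec.add_loading("Climate1", "r_winter_temp")
    spec.add_loading("Climate1", "r_winter_precip")
    spec.add_loading("Climate1", "r_spring_precip")
    spec.add_loading("Climate1", "r_summer_precip")
    spec.add_loading("Climate2", "r_winter_temp", fixed=1.0)
    spec.add_loading("Climate2", "r_spring_temp")
    spec.add_loading("Climate2", "r_winter_precip")
    spec.add_loading("Climate2", "r_spring_precip")
    for v in CLIMATE_RESPONSES:
        spec.add_var(v)
    spec.add_var("Climate1", value=0.3)
    spec.add_var("Climate2", value=0.3)
    spec.add_cov("Climate1", "Climate2", free=False, value=0.0)


def _outcome_block(spec: SemSpec, predictors: list[str]) -> None:
    """Paths from predictors and covariates into the outcome trio.

    The recursive ordering abundance -> avg sites occupied -> synchrony ->
    trend is complete (all six paths present), so the outcome block itself
    is saturated and every model constraint concerns how predictors reach
    the outcomes.
    """
    for src in predictors + ["abundance", "avg_sites_occupied"]:
        spec.add_path(src, "synchrony")
    for src in predictors + ["abundance"]:
        spec.add_path(src, "avg_sites_occupied")
    for src in predictors + ["abundance", "avg_sites_occupied", "synchrony"]:
        spec.add_path(src, "trend")
    for v in ("synchrony", "avg_sites_occupied", "trend"):
        spec.add_var(v)
    spec.add_var("abundance")


def canned_models(which: str, variant: str = "latent") -> SemSpec:
    """Build one of the three comparison models (or its scores variant).

    ``which`` is ``dispersal`` / ``climate`` / ``combined``.  The latent
    variants carry the measurement models inside the SEM with marker
    loadings fixed to 1 and are tuned to 4, 9 and 18 model degrees of
    freedom; the scores variants replace latents by externally computed
    factor scores entered as observed variables.
    """
    if variant == "scores":
        return _scores_variant(which)
    if variant != "latent":
        raise ValueError(f"unknown variant {variant!r}")

    if which == "dispersal":
        spec = SemSpec(
            observed=list(DISPERSAL_TRAITS) + list(OUTCOMES),
            latents=["Dispersal1", "Dispersal2"],
            name="dispersal",
        )
        _measurement_dispersal(spec)
        _outcome_block(spec, ["Dispersal1", "Dispersal2"])
        spec.add_cov("abundance", "Dispersal1")
        spec.add_cov("abundance", "Dispersal2")
        # the doubly-loading trait shares residual variance with the outcomes
        spec.add_cov("abundance", "wingspan")
        spec.add_cov("synchrony", "wingspan")
        spec.add_cov("avg_sites_occupied", "wingspan")
    elif which == "climate":
        spec = SemSpec(
            observed=list(CLIMATE_RESPONSES) + [ENSO_RESPONSE] + list(OUTCOMES),
            latents=["Climate1", "Climate2"],
            name="climate",
        )
        _measurement_climate(spec)
        _outcome_block(spec, ["Climate1", "Climate2", ENSO_RESPONSE])
        spec.add_var(ENSO_RESPONSE)
        spec.add_cov(ENSO_RESPONSE, "Climate1")
        spec.add_cov(ENSO_RESPONSE, "Climate2")
        spec.add_cov(ENSO_RESPONSE, "abundance")
        spec.add_cov("abundance", "Climate1")
        spec.add_cov("abundance", "Climate2")
        # response-level covariances beyond the latent links
        spec.add_cov(ENSO_RESPONSE, "r_winter_precip")
        spec.add_cov(ENSO_RESPONSE, "r_summer_precip")
        spec.add_cov("abundance", "r_winter_temp")
        spec.add_cov("abundance", "r_summer_precip")
        spec.add_cov("synchrony", "r_spring_precip")
        spec.add_cov("avg_sites_occupied", "r_winter_temp")
        spec.add_cov("trend", "r_winter_temp")
    elif which == "combined":
        spec = SemSpec(
            observed=list(DISPERSAL_TRAITS) + list(CLIMATE_RESPONSES)
            + [ENSO_RESPONSE] + list(OUTCOMES),
            latents=["Dispersal1", "Dispersal2", "Climate1", "Climate2"],
            name="combined",
        )
        _measurement_dispersal(spec)
        _measurement_climate(spec)
        _outcome_block(
            spec, ["Dispersal1", "Dispersal2", "Climate1", "Climate2",
                   ENSO_RESPONSE]
        )
        # dispersal propensity shapes climate sensitivity; regional (ENSO)
        # sensitivity feeds the local-weather factors rather than
        # covarying with their residuals
        for d in ("Dispersal1", "Dispersal2"):
            for c in ("Climate1", "Climate2", ENSO_RESPONSE):
                spec.add_path(d, c)
        spec.add_var(ENSO_RESPONSE)
        spec.add_path(ENSO_RESPONSE, "Climate1")
        spec.add_path(ENSO_RESPONSE, "Climate2")
        spec.add_cov("abundance", "Dispersal1")
        spec.add_cov("abundance", "Dispersal2")
        spec.add_cov("abundance", "Climate1")
        # residual covariances spread thinly over the cross-moment rows so
        # no row is saturated and the latent links stay well identified
        spec.add_cov(ENSO_RESPONSE, "wingspan")
        spec.add_cov(ENSO_RESPONSE, "geographic_range")
        spec.add_cov(ENSO_RESPONSE, "r_winter_precip")
        spec.add_cov(ENSO_RESPONSE, "r_summer_precip")
        spec.add_cov("abundance", "wingspan")
        spec.add_cov("abundance", "r_winter_temp")
        spec.add_cov("abundance", "r_summer_precip")
        spec.add_cov("synchrony", "wingspan")
        spec.add_cov("synchrony", "r_spring_precip")
        spec.add_cov("synchrony", "r_spring_temp")
        spec.add_cov("avg_sites_occupied", "wingspan")
        spec.add_cov("avg_sites_occupied", "r_winter_temp")
        spec.add_cov("avg_sites_occupied", "r_spring_precip")
        spec.add_cov("trend", "wingspan")
        spec.add_cov("trend", "r_winter_temp")
        spec.add_cov("trend", "r_spring_temp")
        for v in ("r_winter_temp", "r_spring_temp", "r_winter_precip"):
            spec.add_cov("wingspan", v)
            spec.add_cov("geographic_range", v)
        spec.add_cov("elevational_range", "r_spring_temp")
        spec.add_cov("diet_breadth", "r_spring_temp")
        spec.add_cov("diet_breadth", "r_winter_temp")
    else:
        raise ValueError(f"unknown model {which!r}")
    spec.validate()
    return spec


def _scores_variant(which: str) -> SemSpec:
    if which == "dispersal":
        preds = ["dispersal1", "dispersal2"]
        extra: list[str] = []
    elif which == "climate":
        preds = ["climate1", "climate2", ENSO_RESPONSE]
        extra = []
    elif which == "combined":
        preds = ["dispersal1", "dispersal2", "climate1", "climate2",
                 ENSO_RESPONSE]
        extra = []
    else:
        raise ValueError(f"unknown model {which!r}")
    spec = SemSpec(observed=preds + extra + list(OUTCOMES),
                   name=f"{which}_scores")
    _outcome_block(spec, preds)
    for a, b in itertools.combinations(preds + ["abundance"], 2):
        spec.add_cov(a, b)
    for v in preds:
        spec.add_var(v)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# exclusion experiments


@dataclass
class ExperimentResult:
    """Outcome of a migrant-exclusion or random-removal experiment."""

    label: str
    r2_values: np.ndarray
    mean: float
    interval: tuple[float, float]      # 2.5 / 97.5 percentile
    n_replicates: int
    n_failed: int
    seed: object = None


def exclusion_experiment(spec: SemSpec, data: pd.DataFrame, mode: str,
                         migratory: pd.Series | None = None,
                         n_remove: int = 9, reps: int = 1000,
                         seed: int | None = None,
                         r2_variable: str = "synchrony",
                         exhaustive: bool = False) -> ExperimentResult:
    """Refit the model under species removal and track variance explained.

    ``mode='migrants'`` performs a single refit on the non-migratory
    species (``migratory`` must align with ``data``'s index).
    ``mode='random'`` refits ``reps`` times dropping ``n_remove``
    uniformly sampled species each time (or every possible subset when
    ``exhaustive=True``), reporting the per-replicate R^2 of
    ``r2_variable``, its mean and the 95% percentile interval.
    Non-converging replicates are dropped and counted.
    """
    n = len(data)
    # warm-start every refit from the full-data solution
    try:
        base_theta = fit(spec, data).theta
    except (RuntimeError, ValueError):
        base_theta = None
    if mode == "migrants":
        if migratory is None:
            raise ValueError("mode='migrants' needs the migratory flags")
        keep = data.loc[~migratory.astype(bool).to_numpy()]
        f = fit(spec, keep, theta_start=base_theta)
        r2 = np.array([r_squared(f, r2_variable)])
        return ExperimentResult(label="migrant-exclusion", r2_values=r2,
                                mean=float(r2[0]),
                                interval=(float(r2[0]), float(r2[0])),
                                n_replicates=1, n_failed=0, seed=seed)
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r}")
    if n_remove >= n:
        raise ValueError("cannot remove all (or more) species")

    rng = np.random.default_rng(seed)
    if exhaustive:
        subsets = [np.array(c) for c in
                   itertools.combinations(range(n), n_remove)]
    else:
        subsets = [rng.choice(n, size=n_remove, replace=False)
                   for _ in range(reps)]
    r2s, failed = [], 0
    for drop in subsets:
        keep = data.drop(data.index[list(drop)]) if len(drop) else data
        try:
            f = fit(spec, keep, theta_start=base_theta, max_restarts=0)
            r2 = r_squared(f, r2_variable)
            if not -1e-9 <= r2 <= 1 + 1e-9:
                # degenerate replicate: variance decomposition invalid
                failed += 1
                continue
            r2s.append(r2)
        except (RuntimeError, ValueError):
            failed += 1
    r2 = np.asarray(r2s)
    lo, hi = (np.percentile(r2, [2.5, 97.5]) if len(r2) else (np.nan, np.nan))
    return ExperimentResult(label="random-removal", r2_values=r2,
                            mean=float(r2.mean()) if len(r2) else np.nan,
                            interval=(float(lo), float(hi)),
                            n_replicates=len(subsets), n_failed=failed,
                            seed=seed)
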