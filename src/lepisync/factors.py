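"""Maximum-likelihood factor analysis of species-level variables.

Used twice in the pipeline: to reduce four dispersal-related traits to two
latent "dispersal" factors, and to reduce the five local-weather response
coefficients to two "climate" factors (the ENSO response stays out of the
factor analysis and enters the structural models as a standalone
variable).  Fitting is ML on the correlation matrix via
:class:`statsmodels.multivariate.factor.Factor`; rotation is configurable
(none, varimax, or oblimin-style oblique, the default).  Factors are
canonically oriented so each factor's largest-magnitude loading is
positive, which makes outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

#: smallest admissible uniqueness (Heywood guard)
UNIQUENESS_FLOOR = 0.005


@dataclass
class FactorSolution:
    """An ML factor solution on the correlation scale.

    ``loadings`` are pattern loadings (p x k); for oblique rotations
    ``factor_correlation`` holds Phi and structure loadings are
    ``loadings @ factor_correlation``.  ``proportion_variance`` is the sum
    of squared structure loadings per factor divided by p.
    """

    variables: list
    loadings: np.ndarray                # (p, k)
    uniquenesses: np.ndarray            # (p,)
    factor_correlation: np.ndarray      # (k, k)
    proportion_variance: np.ndarray     # (k,)
    rotation: str
    converged: bool
    heywood: bool
    log_likelihood: float | None
    means: np.ndarray                   # column means of the fitted data
    sds: np.ndarray                     # column sds of the fitted data

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def structure(self) -> np.ndarray:
        return self.loadings @ self.factor_correlation

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings * self.structure, axis=1)

    def reproduced_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Phi Lambda' + Psi."""
        R = self.loadings @ self.factor_correlation @ self.loadings.T
        return R + np.diag(self.uniquenesses)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"factor{i+1}" for i in range(self.n_factors)]
        df = pd.DataFrame(self.loadings, index=self.variables, columns=cols)
        df["uniqueness"] = self.uniquenesses
        return df


def _canonical_signs(loadings: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip factors so the largest-magnitude loading of each is positive."""
    signs = np.ones(loadings.shape[1])
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            signs[k] = -1.0
    D = np.diag(signs)
    return loadings @ D, D @ phi @ D


def fit_ml_factors(data: pd.DataFrame, k: int,
                   rotation: str = "oblimin") -> FactorSolution:
    """Fit a k-factor ML model to an n x p species-by-variable table.

    Variables are standardised internally (the model is fitted to the
    correlation matrix); requires n > p >= k >= 1.  Heywood cases are
    clamped at the uniqueness floor and flagged.  ``rotation`` is one of
    ``none`` / ``varimax`` / ``oblimin``; rotation changes loadings but
    not the fitted likelihood.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    n, p = data.shape
    if not (n > p >= k >= 1):
        raise ValueError(f"need n > p >= k >= 1, got n={n}, p={p}, k={k}")
    X = data.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(ddof=1, axis=0)
    if np.any(sds == 0):
        const = [data.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant variable(s): {const}")

    model = Factor(endog=X, n_factor=k, method="ml")
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - optimizer failure path
        raise RuntimeError(f"ML factor analysis failed to converge: {exc}") from exc

    if rotation != "none" and k > 1:
        res.rotate(rotation)
        loadings = np.asarray(res.loadings)
        T = np.asarray(res.rotation_matrix)
        phi = T.T @ T if rotation == "oblimin" else np.eye(k)
        # guard against tiny asymmetries from the rotation optimiser
        phi = 0.5 * (phi + phi.T)
        np.fill_diagonal(phi, 1.0)
    else:
        loadings = np.asarray(res.loadings)
        phi = np.eye(k)

    loadings, phi = _canonical_signs(loadings, phi)
    uniq = np.asarray(res.uniqueness, dtype=float).copy()
    heywood = bool(np.any(uniq < UNIQUENESS_FLOOR))
    uniq = np.maximum(uniq, UNIQUENESS_FLOOR)

    structure = loadings @ phi
    prop = np.sum(structure**2, axis=0) / p
    loglike = None
    try:
        loglike = float(model.loglike((np.asarray(res.loadings_no_rot), uniq)))
    except Exception:
        pass
    return FactorSolution(
        variables=list(data.columns), loadings=loadings, uniquenesses=uniq,
        factor_correlation=phi, proportion_variance=prop, rotation=rotation,
        converged=True, heywood=heywood, log_likelihood=loglike,
        means=means, sds=sds,
    )


def variance_explained(solution: FactorSolution) -> np.ndarray:
    """Proportion of total (correlation-scale) variance per factor."""
    return solution.proportion_variance


def factor_scores(solution: FactorSolution, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method (Thomson) factor scores for each species.

    Scores are ``Z R^{-1} (Lambda Phi)`` with Z the standardised data and R
    the model-implied correlation matrix; columns are centered at 0.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float),
                            columns=solution.variables)
    if list(data.columns) != list(solution.variables):
        raise ValueError(
            f"variable mismatch: solution has {solution.variables}, "
            f"data has {list(data.columns)}"
        )
    Z = (data.to_numpy(dtype=float) - solution.means) / solution.sds
    R = solution.reproduced_correlation()
    B = np.linalg.solve(R, solution.structure)
    F = Z @ B
    F = F - F.mean(axis=0)
    return pd.DataFrame(F, index=data.index,
                        columns=[f"factor{i+1}" for i in range(solution.n_factors)])
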