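"""Best-subset covariate selection for a binomial GLM under the extended BIC.

The criterion is BIC_gamma = D + k log(n) + 2 gamma log C(p, k), where D is
the residual deviance of the fitted logistic model, k the number of selected
covariates, p the number of candidates, and C(p, k) the binomial
coefficient; gamma = 0 recovers the classical BIC and gamma = 1 the extended
BIC with a uniform prior over models of each fixed size.  All 2^p subsets
are fitted exhaustively (the intercept is always included).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit


@dataclass
class GlmFit:
    """A fitted binomial (logit-link) GLM."""

    coefficients: dict  # name -> log-odds coefficient, includes "intercept"
    deviance: float
    n_obs: int
    converged: bool
    n_iter: int = 0
    cov_unscaled: np.ndarray | None = field(default=None, repr=False)

    @property
    def coef_array(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))


def _binomial_deviance(y, n, p_hat) -> float:
    mu = n * p_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def fit_binomial_glm(
    design_matrix,
    successes,
    trials,
    names=None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GlmFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares.

    ``design_matrix`` must include the intercept column.  Non-convergence
    (e.g. complete separation) is flagged on the returned fit, never
    silent; a rank-deficient design raises.
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if X.shape[0] != len(y) or len(y) != len(n):
        raise ValueError("design, successes and trials must align")
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= trials elementwise")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]

    beta = np.zeros(X.shape[1])
    # sensible intercept start keeps IRLS out of flat regions
    pbar = np.clip(y.sum() / max(n.sum(), 1.0), 1e-6, 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar))
    converged = False
    it = 0
    dev = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(n * p * (1 - p), 1e-12, None)
        z = eta + (y - n * p) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        dev_new = _binomial_deviance(y, n, expit(X @ beta_new))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < 1e-8 or abs(dev - dev_new) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    p = expit(X @ beta)
    w = np.clip(n * p * (1 - p), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return GlmFit(
        coefficients=dict(zip(names, beta)),
        deviance=_binomial_deviance(y, n, p),
        n_obs=len(y),
        converged=converged,
        n_iter=it,
        cov_unscaled=cov,
    )


def ebic(D: float, k: int, n: int, p: int, gamma: float = 1.0) -> float:
    """Extended BIC: D + k log(n) + 2 gamma log C(p, k)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= p:
        raise ValueError("need 0 <= k <= p")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if not math.isfinite(D):
        raise ValueError("deviance must be finite")
    return D + k * math.log(n) + 2.0 * gamma * math.log(math.comb(p, k))


@dataclass
class SelectionResult:
    """Exhaustive-search result: per-subset table and the EBIC minimizer."""

    table: pd.DataFrame  # columns: subset, k, deviance, ebic
    chosen: tuple
    gamma: float
    fits: dict = field(default=None, repr=False)

    @property
    def chosen_score(self) -> float:
        mask = self.table["subset"].apply(lambda s: tuple(s) == self.chosen)
        return float(self.table.loc[mask, "ebic"].iloc[0])


def select_best_subset(
    data: pd.DataFrame,
    candidate_covariates,
    gamma: float = 1.0,
    standardize: bool = True,
) -> SelectionResult:
    """Fit every subset of the candidates and return the EBIC minimizer.

    ``data`` needs columns ``n_wasted``, ``n_examined`` and one column per
    candidate covariate.  Ties break toward smaller subsets, then
    lexicographic order.  A subset whose GLM fails to converge is scored
    +inf and kept in the table for the record.
    """
    candidates = list(candidate_covariates)
    p = len(candidates)
    if p > 20:
        raise ValueError("exhaustive search is limited to 20 candidates")
    missing = [c for c in candidates if c not in data.columns]
    if missing:
        raise KeyError(f"candidate covariates not in data: {missing}")
    y = data["n_wasted"].to_numpy(dtype=float)
    n = data["n_examined"].to_numpy(dtype=float)
    Z = data[candidates].to_numpy(dtype=float)
    if standardize and p:
        Z = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)

    rows = []
    fits = {}
    best = None
    # enumeration in (k, lexicographic) order makes the tie-break the
    # first strict minimum encountered
    for k in range(p + 1):
        for subset in itertools.combinations(range(p), k):
            names = tuple(candidates[j] for j in subset)
            X = np.column_stack([np.ones(len(y))] + [Z[:, j] for j in subset])
            try:
                fit = fit_binomial_glm(
                    X, y, n, names=["intercept"] + list(names)
                )
                score = (
                    ebic(fit.deviance, k, len(y), p, gamma)
                    if fit.converged
                    else math.inf
                )
                dev = fit.deviance
            except ValueError:
                fit, score, dev = None, math.inf, math.nan
            rows.append({"subset": names, "k": k, "deviance": dev, "ebic": score})
            fits[names] = fit
            if best is None or score < best[0]:
                best = (score, names)
    table = pd.DataFrame(rows)
    return SelectionResult(table=table, chosen=best[1], gamma=gamma, fits=fits)
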