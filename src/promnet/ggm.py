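"""Sparse partial-correlation network estimation.

Pipeline: Spearman correlation of the score matrix -> positive-definite
repair -> graphical lasso over a descending log-spaced penalty path ->
Extended BIC model selection -> signed partial-correlation edge weights.

The Extended BIC of a fitted precision matrix Theta with E edges is

    EBIC = -2 L + E log(n) + 4 E gamma log(p),
    L    = (n/2) (log det Theta - trace(S Theta)),

with gamma the sparsity hyperparameter (default 0.25). Lower gamma keeps
more edges, at the cost of possibly including spurious ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import glasso_solve


class EstimationError(RuntimeError):
    """Raised when the glasso solver fails to converge."""


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings of the EBIC-glasso estimator.

    gamma : EBIC sparsity hyperparameter (>= 0); 0 reduces EBIC to BIC.
    n_lambda, lambda_min_ratio : penalty path length and lower endpoint
        relative to lambda_max (the largest off-diagonal |correlation|).
    zero_tol : |Theta_ij| below this counts as an absent edge.
    missing_policy : 'pairwise' (pairwise-complete Spearman) or
        'complete-case' (drop any row with a missing score).
    pd_floor : eigenvalue floor used when repairing an indefinite
        correlation matrix.
    conv_tol, max_iter : solver convergence tolerance and sweep budget.
    """

    gamma: float = 0.25
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    zero_tol: float = 1e-8
    missing_policy: str = "pairwise"
    pd_floor: float = 1e-3
    conv_tol: float = 1e-5
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.missing_policy not in ("pairwise", "complete-case"):
            raise ValueError("missing_policy must be 'pairwise' or 'complete-case'")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation estimate with per-pair sample sizes."""

    labels: list[str]
    values: np.ndarray
    pairwise_n: np.ndarray
    pd_repaired: bool = False


@dataclass
class GlassoFit:
    """One point on the glasso penalty path."""

    lam: float
    precision: np.ndarray
    logdet: float
    trace_s_theta: float
    edge_count: int
    converged: bool
    ebic: float = np.nan


@dataclass
class WeightedNetwork:
    """Signed partial-correlation network (zero diagonal) with provenance."""

    labels: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge_count(self, tol: float = 0.0) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int((np.abs(self.weights[iu]) > tol).sum())


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"V{i}" for i in range(arr.shape[1])]


def spearman_correlation(X, missing_policy: str = "pairwise",
                         labels: list[str] | None = None) -> CorrelationMatrix:
    """Spearman rank correlation matrix (average ranks for ties).

    Under the 'pairwise' policy each pair is ranked over its complete
    observations; 'complete-case' first drops every row with any missing
    value. Pairs with fewer than 3 complete observations are an error.
    """
    arr, inferred = _as_matrix(X)
    labels = list(labels) if labels is not None else inferred
    n, p = arr.shape
    if p < 2:
        raise ValueError("need at least 2 variables")

    if missing_policy == "complete-case":
        arr = arr[~np.isnan(arr).any(axis=1)]
        n = arr.shape[0]

    has_nan = bool(np.isnan(arr).any())
    if not has_nan:
        if n < 3:
            raise ValueError("need at least 3 complete observations")
        rho = stats.spearmanr(arr).statistic
        if p == 2:  # spearmanr returns a scalar for two columns
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pairwise_n = np.full((p, p), n, dtype=int)
    else:
        if missing_policy != "pairwise":
            raise ValueError("missing values present under complete-case policy")
        rho = np.eye(p)
        pairwise_n = np.zeros((p, p), dtype=int)
        np.fill_diagonal(pairwise_n, (~np.isnan(arr)).sum(axis=0))
        for i in range(p):
            for j in range(i + 1, p):
                mask = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
                m = int(mask.sum())
                if m < 3:
                    raise ValueError(
                        f"pair ({labels[i]}, {labels[j]}) has only {m} "
                        "complete observations (need >= 3)"
                    )
                r = stats.spearmanr(arr[mask, i], arr[mask, j]).statistic
                rho[i, j] = rho[j, i] = float(r)
                pairwise_n[i, j] = pairwise_n[j, i] = m

    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(labels=labels, values=rho, pairwise_n=pairwise_n)


def nearest_pd_repair(S: CorrelationMatrix,
                      floor: float = 1e-3) -> CorrelationMatrix:
    """Clip eigenvalues at `floor` and rescale to unit diagonal.

    Pairwise-deleted Spearman matrices can be indefinite; the glasso
    requires a positive-definite input. Idempotent: an already
    positive-definite matrix is returned unchanged with the flag False.
    """
    vals = np.asarray(S.values, dtype=float)
    repaired = False
    for _ in range(20):
        w = np.linalg.eigvalsh(vals)
        if w[0] >= floor - 1e-12:
            break
        repaired = True
        w, V = np.linalg.eigh(vals)
        vals = (V * np.maximum(w, floor)) @ V.T
        d = np.sqrt(np.diag(vals))
        vals = vals / np.outer(d, d)
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(
        labels=list(S.labels), values=vals,
        pairwise_n=np.asarray(S.pairwise_n).copy(),
        pd_repaired=bool(S.pd_repaired or repaired),
    )


def lambda_path(S, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty path from lambda_max to its min_ratio.

    lambda_max is the largest off-diagonal |correlation|, at which the
    estimated network is empty.
    """
    vals = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S)
    p = vals.shape[0]
    off = np.abs(vals[~np.eye(p, dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0.0:
        import warnings

        warnings.warn("all off-diagonal correlations are zero; "
                      "degenerate single-point path", stacklevel=2)
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def glasso_fit(S, lam: float, config: EstimatorConfig = EstimatorConfig(),
               state=None) -> tuple[GlassoFit, tuple]:
    """Solve one L1-penalized precision estimation problem.

    Returns the fit and the warm-start state to reuse for the next
    (smaller) penalty on the same matrix.
    """
    vals = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    theta, state, converged = glasso_solve(
        vals, lam, state=state, tol=config.conv_tol, max_iter=config.max_iter
    )
    if not converged:
        raise EstimationError(
            f"glasso did not converge at lambda={lam:.6g} "
            f"(p={vals.shape[0]}, tol={config.conv_tol}, "
            f"max_iter={config.max_iter})"
        )
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise EstimationError(f"estimated precision not PD at lambda={lam:.6g}")
    iu = np.triu_indices(vals.shape[0], k=1)
    edge_count = int((np.abs(theta[iu]) > config.zero_tol).sum())
    fit = GlassoFit(
        lam=float(lam), precision=theta, logdet=float(logdet),
        trace_s_theta=float(np.sum(vals * theta)), edge_count=edge_count,
        converged=converged,
    )
    return fit, state


def ebic_score(fit: GlassoFit, S, n: int, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix; gamma=0 gives plain BIC."""
    vals = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    p = vals.shape[0]
    L = 0.5 * n * (fit.logdet - float(np.sum(vals * fit.precision)))
    E = fit.edge_count
    return -2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def precision_to_partial(theta: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has a nonpositive diagonal entry")
    scale = np.sqrt(np.outer(d, d))
    partial = -theta / scale
    np.fill_diagonal(partial, 0.0)
    return 0.5 * (partial + partial.T)


def ebicglasso(X, config: EstimatorConfig = EstimatorConfig(),
               labels: list[str] | None = None) -> WeightedNetwork:
    """Estimate a sparse partial-correlation network by EBIC-glasso.

    X is a score matrix (rows = assessments, columns = nodes); a
    DataFrame's column names become node labels. The minimum-EBIC fit on
    the penalty path is selected (ties broken toward the larger penalty,
    i.e. the sparser model); weights are the shrunken partial correlations
    of the selected precision matrix, with no post-selection refit.
    """
    arr, inferred = _as_matrix(X)
    labels = list(labels) if labels is not None else inferred
    n = arr.shape[0]
    if config.missing_policy == "complete-case":
        n = int((~np.isnan(arr).any(axis=1)).sum())

    S = spearman_correlation(arr, missing_policy=config.missing_policy,
                             labels=labels)
    S = nearest_pd_repair(S, floor=config.pd_floor)
    path = lambda_path(S, n_lambda=config.n_lambda,
                       min_ratio=config.lambda_min_ratio)

    best: GlassoFit | None = None
    state = None
    for lam in path:  # descending: first minimum wins ties -> sparser model
        fit, state = glasso_fit(S, float(lam), config, state=state)
        fit.ebic = ebic_score(fit, S, n, config.gamma)
        if best is None or fit.ebic < best.ebic:
            best = fit

    weights = precision_to_partial(best.precision)
    weights[np.abs(weights) <= config.zero_tol] = 0.0
    return WeightedNetwork(
        labels=labels,
        weights=weights,
        provenance={
            "gamma": config.gamma,
            "lambda": best.lam,
            "lambda_max": float(path[0]),
            "n_lambda": int(len(path)),
            "lambda_min_ratio": config.lambda_min_ratio,
            "n": int(n),
            "p": int(arr.shape[1]),
            "ebic": float(best.ebic),
            "edge_count": int(best.edge_count),
            "pd_repaired": bool(S.pd_repaired),
            "missing_policy": config.missing_policy,
        },
    )
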