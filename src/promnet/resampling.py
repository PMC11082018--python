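"""Permutation and bootstrap inference for symptom networks.

Three procedures:

* :func:`nct_global_strength` — permutation-based network comparison test
  of global strength: pooled rows are repeatedly reassigned to two groups
  of the original sizes, both networks re-estimated with the identical
  estimator settings, and the observed |GS_A - GS_B| compared with its
  permutation null. The add-one p-value (1 + #{null >= observed})/(1 + B)
  is never exactly zero, preserving exact validity.
* :func:`edge_bootstrap` — nonparametric row bootstrap of the edge
  weights with per-edge quantile confidence intervals (edge-weight
  accuracy).
* :func:`case_dropping_stability` — node-strength stability under case
  dropping, summarized by the correlation-stability (CS) coefficient: the
  largest drop proportion at which at least 95% of replicates still
  correlate >= 0.7 with the full-sample node strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import EstimationError, EstimatorConfig, ebicglasso
from .metrics import global_strength, node_strength

DEFAULT_DROP_PROPORTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

CS_CORRELATION_THRESHOLD = 0.7
CS_PROBABILITY = 0.95


@dataclass
class NCTResult:
    gs_A: float
    gs_B: float
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    B: int
    seed: int
    n_A: int
    n_B: int
    permutations: np.ndarray = field(repr=False, default=None)

    def report(self) -> str:
        return (f"GS = {self.gs_A:.2f} vs. GS = {self.gs_B:.2f}, "
                f"p = {self.p_value:.3g}")


@dataclass
class EdgeBootstrapResult:
    labels: list[str]
    point_estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    replicates: np.ndarray = field(repr=False, default=None)
    B: int = 0
    ci_level: float = 0.95
    seed: int = 0


@dataclass
class StabilityResult:
    drop_proportions: np.ndarray
    correlations: np.ndarray  # (n_proportions, B)
    cs_coefficient: float
    full_strength: np.ndarray = field(repr=False, default=None)
    B: int = 0
    seed: int = 0


def _scores(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"V{i}" for i in range(arr.shape[1])]


def nct_global_strength(XA, XB, config: EstimatorConfig = EstimatorConfig(),
                        B: int = 1000, seed: int = 0,
                        max_retries: int = 10) -> NCTResult:
    """Permutation test of the global-strength difference between groups.

    Patients appearing in both groups violate the exchangeability
    assumption; a warning is emitted when group sizes fall below the node
    count, and the cross-subgroup deduplication in the cohort module is
    the supported remedy for shared patients.
    """
    A, labels_a = _scores(XA)
    Bm, labels_b = _scores(XB)
    if labels_a != labels_b:
        raise ValueError("groups must share identical node columns")
    nA, nB = A.shape[0], Bm.shape[0]
    p = A.shape[1]
    if min(nA, nB) < p:
        warnings.warn(f"group size ({min(nA, nB)}) below node count ({p}); "
                      "estimates may be unstable", stacklevel=2)

    net_a = ebicglasso(A, config, labels=labels_a)
    net_b = ebicglasso(Bm, config, labels=labels_b)
    gs_a, gs_b = global_strength(net_a), global_strength(net_b)
    observed = abs(gs_a - gs_b)

    pooled = np.vstack([A, Bm])
    n = nA + nB
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    perms = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(n)
            try:
                ga = global_strength(
                    ebicglasso(pooled[perm[:nA]], config, labels=labels_a))
                gb = global_strength(
                    ebicglasso(pooled[perm[nA:]], config, labels=labels_a))
                break
            except EstimationError:
                if attempt == max_retries:
                    raise
        null[b] = abs(ga - gb)
        perms[b] = perm
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + B)
    return NCTResult(
        gs_A=gs_a, gs_B=gs_b, observed_diff=observed, null_diffs=null,
        p_value=float(p_value), B=B, seed=seed, n_A=nA, n_B=nB,
        permutations=perms,
    )


def edge_bootstrap(X, config: EstimatorConfig = EstimatorConfig(),
                   B: int = 1000, ci_level: float = 0.95, seed: int = 0,
                   max_retries: int = 10) -> EdgeBootstrapResult:
    """Row bootstrap of edge weights with per-edge quantile intervals."""
    arr, labels = _scores(X)
    n, p = arr.shape
    if n < 3:
        raise ValueError("need at least 3 rows to bootstrap")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    point = ebicglasso(arr, config, labels=labels).weights
    rng = np.random.default_rng(seed)
    reps = np.empty((B, p, p))
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(n, size=n)
            try:
                reps[b] = ebicglasso(arr[idx], config, labels=labels).weights
                break
            except EstimationError:
                if attempt == max_retries:
                    raise
    alpha = (1.0 - ci_level) / 2.0
    ci_low = np.quantile(reps, alpha, axis=0)
    ci_high = np.quantile(reps, 1.0 - alpha, axis=0)
    return EdgeBootstrapResult(
        labels=labels, point_estimates=point, ci_low=ci_low, ci_high=ci_high,
        replicates=reps, B=B, ci_level=ci_level, seed=seed,
    )


def _cs_coefficient(proportions: np.ndarray, correlations: np.ndarray,
                    threshold: float = CS_CORRELATION_THRESHOLD,
                    probability: float = CS_PROBABILITY) -> float:
    """Largest drop proportion whose replicate correlations stay above the
    threshold with the required probability (0 if none)."""
    cs = 0.0
    for q, row in zip(proportions, correlations):
        ok = np.mean(np.nan_to_num(row, nan=-1.0) >= threshold)
        if ok >= probability:
            cs = float(q)
    return cs


def case_dropping_stability(
    X, config: EstimatorConfig = EstimatorConfig(),
    proportions=DEFAULT_DROP_PROPORTIONS, B: int = 250, seed: int = 0,
) -> StabilityResult:
    """Node-strength stability under case-dropping subsampling.

    For each drop proportion q, B replicates drop floor(q*n) random rows,
    re-estimate the network, and correlate (Spearman) replicate node
    strengths with the full-sample strengths.
    """
    arr, labels = _scores(X)
    n, p = arr.shape
    props = np.asarray(sorted(proportions), dtype=float)
    if np.any(props <= 0) or np.any(props >= 0.95):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    if n - int(np.floor(props[-1] * n)) < p:
        raise ValueError("too few rows remain at the largest drop proportion")

    full = node_strength(ebicglasso(arr, config, labels=labels))
    rng = np.random.default_rng(seed)
    corr = np.empty((len(props), B))
    for i, q in enumerate(props):
        keep = n - int(np.floor(q * n))
        for b in range(B):
            idx = rng.permutation(n)[:keep]
            sub = node_strength(ebicglasso(arr[idx], config, labels=labels))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant strengths -> NaN
                corr[i, b] = stats.spearmanr(full, sub).statistic
    cs = _cs_coefficient(props, corr)
    return StabilityResult(
        drop_proportions=props, correlations=corr, cs_coefficient=cs,
        full_strength=full, B=B, seed=seed,
    )
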