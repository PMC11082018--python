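"""Node strength, global strength, and between-network edge similarity.

Node strength s_i is the sum of the absolute weights of the edges incident
to node i. Global strength GS is the sum of absolute edge weights over
unique node pairs, i.e. half the sum of node strengths; it measures how
tightly the symptoms in a network are interconnected. A mean-per-node
variant is exposed separately as :func:`global_strength_mean`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ggm import WeightedNetwork


@dataclass
class StrengthReport:
    labels: list[str]
    strength: np.ndarray
    global_strength: float


def node_strength(net: WeightedNetwork) -> np.ndarray:
    """Per-node sum of absolute incident edge weights."""
    return np.abs(net.weights).sum(axis=1)


def global_strength(net: WeightedNetwork) -> float:
    """Sum of absolute edge weights over unique node pairs."""
    iu = np.triu_indices(net.n_nodes, k=1)
    return float(np.abs(net.weights[iu]).sum())


def global_strength_mean(net: WeightedNetwork) -> float:
    """Average node strength (global strength scaled by 2/p)."""
    return float(node_strength(net).mean())


def strength_report(net: WeightedNetwork) -> StrengthReport:
    return StrengthReport(
        labels=list(net.labels),
        strength=node_strength(net),
        global_strength=global_strength(net),
    )


def edge_similarity(netA: WeightedNetwork, netB: WeightedNetwork,
                    support_union: bool = False) -> float:
    """Spearman correlation between the two networks' edge weights.

    Compares the vectorized upper triangles over identical node sets
    (zeros included by default; `support_union` restricts to pairs with a
    nonzero weight in at least one network).
    """
    if list(netA.labels) != list(netB.labels):
        raise ValueError("networks have different node labels or ordering")
    iu = np.triu_indices(netA.n_nodes, k=1)
    a, b = netA.weights[iu], netB.weights[iu]
    if support_union:
        keep = (a != 0) | (b != 0)
        a, b = a[keep], b[keep]
    import warnings

    with warnings.catch_warnings():
        # a fully empty network has constant edge weights; the rank
        # correlation is undefined and reported as NaN
        warnings.simplefilter("ignore")
        return float(stats.spearmanr(a, b).statistic)
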