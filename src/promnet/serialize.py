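"""Serialization of networks and reports: CSV adjacency, JSON, GraphML."""

from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import WeightedNetwork
from .metrics import StrengthReport


def network_to_csv(net: WeightedNetwork, path) -> None:
    """Labelled adjacency matrix of signed partial correlations."""
    pd.DataFrame(net.weights, index=net.labels, columns=net.labels).to_csv(path)


def network_from_csv(path) -> WeightedNetwork:
    df = pd.read_csv(path, index_col=0)
    return WeightedNetwork(labels=[str(c) for c in df.columns],
                           weights=df.to_numpy(dtype=float))


def network_to_json(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "labels": list(net.labels),
                "weights": np.asarray(net.weights).tolist(),
                "provenance": net.provenance,
            },
            fh, indent=2, sort_keys=True,
        )


def network_from_json(path) -> WeightedNetwork:
    with open(path) as fh:
        d = json.load(fh)
    return WeightedNetwork(labels=list(d["labels"]),
                           weights=np.asarray(d["weights"], dtype=float),
                           provenance=d.get("provenance", {}))


def network_to_graphml(net: WeightedNetwork, path) -> None:
    """Undirected graph with a signed `weight` attribute per edge."""
    g = nx.Graph()
    g.add_nodes_from(net.labels)
    p = net.n_nodes
    for i in range(p):
        for j in range(i + 1, p):
            w = float(net.weights[i, j])
            if w != 0.0:
                g.add_edge(net.labels[i], net.labels[j], weight=w)
    nx.write_graphml(g, path)


def strength_to_csv(report: StrengthReport, path) -> None:
    pd.DataFrame(
        {"label": report.labels, "strength": report.strength}
    ).to_csv(path, index=False)
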