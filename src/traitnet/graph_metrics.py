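"""Node- and graph-level metrics with NodeXL-compatible conventions.

The conventions matter more than the metrics themselves, because the printed
reference values assume them:

* betweenness counts each unordered pair once, endpoints excluded, with
  fractional credit over equal-length shortest paths (raw pair-dependency,
  not normalized);
* closeness is the reciprocal of the *sum* of geodesic distances to the
  other nodes (not of their mean);
* eigenvector centrality is the principal eigenvector normalized to sum 1
  within each connected component;
* PageRank uses damping 0.85 and is scaled so the mean over nodes is 1;
* the average geodesic distance averages over all ordered pairs *including*
  self-pairs at distance 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from traitnet.community_detection import Partition, modularity


class GraphMetricsError(ValueError):
    """Raised when a metric is undefined on the supplied graph."""


NODE_METRIC_COLUMNS = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "pagerank",
    "clustering",
)


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node metric table with columns :data:`NODE_METRIC_COLUMNS`.

    Disconnected graphs are handled per component: closeness sums distances
    within the node's component, and eigenvector centralities are normalized
    to sum 1 within each component.
    """
    if graph.number_of_nodes() < 2:
        raise GraphMetricsError("node metrics need at least 2 nodes")
    nodes = list(graph.nodes)
    degree = dict(graph.degree)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness: dict = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        for node in comp:
            if len(comp) == 1:
                closeness[node] = 0.0
                continue
            total = sum(nx.single_source_shortest_path_length(sub, node).values())
            closeness[node] = 1.0 / total
    eigenvector: dict = {}
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            eigenvector[next(iter(comp))] = 1.0
            continue
        sub = graph.subgraph(comp)
        comp_nodes = list(sub.nodes)
        # Dense principal eigenvector (deterministic, unlike ARPACK's random start).
        A = nx.to_numpy_array(sub, nodelist=comp_nodes, weight=None)
        evals, evecs = np.linalg.eigh(A)
        principal = np.abs(evecs[:, -1])  # Perron-Frobenius: nonnegative up to sign
        principal = principal / principal.sum()
        for node, val in zip(comp_nodes, principal):
            eigenvector[node] = float(val)
    pagerank = nx.pagerank(graph, alpha=0.85, weight=None)
    n = len(nodes)
    pagerank = {node: val * n for node, val in pagerank.items()}  # mean 1
    clustering = nx.clustering(graph)
    return pd.DataFrame(
        {
            "degree": [degree[n_] for n_ in nodes],
            "betweenness": [betweenness[n_] for n_ in nodes],
            "closeness": [closeness[n_] for n_ in nodes],
            "eigenvector": [eigenvector[n_] for n_ in nodes],
            "pagerank": [pagerank[n_] for n_ in nodes],
            "clustering": [clustering[n_] for n_ in nodes],
        },
        index=nodes,
    )


def average_geodesic_distance(graph: nx.Graph) -> float:
    """Mean geodesic over all ordered reachable pairs, self-pairs included.

    On a connected graph this is (sum of all pairwise distances) / n^2 — the
    convention under which a 6-node, 13-edge graph scores 34/36 = 0.9444.
    """
    n = graph.number_of_nodes()
    total = 0
    count = 0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        total += sum(lengths.values())
        count += len(lengths)  # includes the self-pair at distance 0
    return total / count if count else 0.0


def small_worldness(graph: nx.Graph) -> float:
    """Humphries-Gurney small-world coefficient S.

    S = (C / C_rand) / (L / L_rand) with C_rand = k/n and L_rand = ln n/ln k,
    where C is the mean local clustering coefficient, L the mean shortest
    path length over distinct reachable pairs, k the mean degree and n the
    node count. S > 1 indicates small-world topology (clustered like a
    lattice, short paths like a random graph). Requires a connected graph
    with mean degree above 1.
    """
    if not nx.is_connected(graph):
        raise GraphMetricsError("small-worldness requires a connected graph")
    n = graph.number_of_nodes()
    k = 2.0 * graph.number_of_edges() / n
    if k <= 1.0:
        raise GraphMetricsError("small-worldness requires mean degree > 1")
    C = float(np.mean(list(nx.clustering(graph).values())))
    L = nx.average_shortest_path_length(graph)  # distinct unordered pairs
    c_rand = k / n
    l_rand = math.log(n) / math.log(k)
    return (C / c_rand) / (L / l_rand)


def overall_metrics(
    graph: nx.Graph, partition: Partition | None = None
) -> dict[str, float]:
    """Whole-graph summary: counts, distances, density, node-metric summaries.

    Returns a flat mapping (Table-style row names). Includes modularity when a
    partition is supplied and small-worldness when the graph is connected
    with mean degree > 1 (NaN otherwise).
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise GraphMetricsError("overall metrics need at least 2 nodes")
    m = graph.number_of_edges()
    components = list(nx.connected_components(graph))
    finite_ecc = []
    for comp in components:
        if len(comp) > 1:
            finite_ecc.append(nx.diameter(graph.subgraph(comp)))
    out: dict[str, float] = {
        "vertices": float(n),
        "unique_edges": float(m),
        "self_loops": float(nx.number_of_selfloops(graph)),
        "connected_components": float(len(components)),
        "single_vertex_components": float(sum(1 for c in components if len(c) == 1)),
        "max_vertices_in_component": float(max(len(c) for c in components)),
        "diameter": float(max(finite_ecc)) if finite_ecc else 0.0,
        "average_geodesic_distance": average_geodesic_distance(graph),
        "graph_density": 2.0 * m / (n * (n - 1)),
    }
    metrics = node_metrics(graph)
    for col in NODE_METRIC_COLUMNS:
        series = metrics[col]
        out[f"min_{col}"] = float(series.min())
        out[f"max_{col}"] = float(series.max())
        out[f"average_{col}"] = float(series.mean())
        out[f"median_{col}"] = float(series.median())
    if partition is not None:
        out["modularity"] = modularity(graph, partition)
    try:
        out["small_worldness"] = small_worldness(graph)
    except GraphMetricsError:
        out["small_worldness"] = float("nan")
    return out


@dataclass(frozen=True)
class TopDecile:
    """Top-10% nodes by a metric; ``boundary_tie`` flags extra tied nodes."""

    nodes: frozenset
    boundary_tie: bool


def top_decile(metrics: pd.DataFrame, metric_name: str) -> TopDecile:
    """The ceil(n/10) nodes with the largest value of one metric.

    Nodes tied with the boundary value are all included and flagged, so the
    returned set can exceed ceil(n/10). Intended for hub identification
    (degree, betweenness) on networks of 10+ nodes.
    """
    if metric_name not in metrics.columns:
        raise GraphMetricsError(
            f"unknown metric {metric_name!r}; have {list(metrics.columns)}"
        )
    n = len(metrics)
    if n < 10:
        warnings.warn("top decile of fewer than 10 nodes is a single node", stacklevel=2)
    k = max(1, math.ceil(n / 10))
    ordered = metrics[metric_name].sort_values(ascending=False, kind="stable")
    boundary = ordered.iloc[k - 1]
    chosen = ordered[ordered >= boundary]
    return TopDecile(frozenset(chosen.index), boundary_tie=len(chosen) > k)
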