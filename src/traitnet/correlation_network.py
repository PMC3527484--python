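"""Correlation tables, correlation graphs and the incremental-pruning sweep.

A link in a correlation network carries a probability of being spurious: the
one-tailed p of its Pearson r at the study's sample size. Incremental pruning
removes links one at a time from least to most significant (increasing |r|),
yielding a nested family of subgraphs whose community structure can be
matched against factor templates. Strong negative links rank late in the
schedule — the sign travels along as metadata and never affects pruning
order or community detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from traitnet.scale_data import ScoreMatrix


class CorrelationError(ValueError):
    """Raised for degenerate inputs to correlation-network construction."""


_P_FLOOR = np.nextafter(0.0, 1.0)  # |r| -> 1 underflows; clamp to smallest positive


def one_tailed_p(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """One-tailed significance of a Pearson correlation at sample size n.

    Uses t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom, evaluated
    on |r|, so the p-value is symmetric in the sign of the correlation and
    strictly decreasing in |r|.
    """
    if n < 3:
        raise CorrelationError("need at least 3 subjects for a p-value")
    r = np.abs(np.asarray(r, dtype=float))
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 0.0, None))
    p = stats.t.sf(t, n - 2)
    p = np.where(p <= 0.0, _P_FLOOR, p)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class CorrelationTable:
    """All-pairs Pearson r and one-tailed p over a set of variables."""

    variables: tuple[str, ...]
    r: np.ndarray  # (v, v) symmetric, unit diagonal
    p: np.ndarray  # (v, v) symmetric, one-tailed
    n_subjects: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        v = len(self.variables)
        if r.shape != (v, v) or p.shape != (v, v):
            raise CorrelationError("correlation matrices must be square over variables")
        if not np.allclose(r, r.T, atol=1e-12):
            raise CorrelationError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise CorrelationError("|r| must be <= 1")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)

    def pair(self, u: str, v: str) -> tuple[float, float]:
        i, j = self.variables.index(u), self.variables.index(v)
        return float(self.r[i, j]), float(self.p[i, j])

    def iter_pairs(self) -> Iterator[tuple[str, str, float, float]]:
        for i in range(len(self.variables)):
            for j in range(i + 1, len(self.variables)):
                yield (
                    self.variables[i],
                    self.variables[j],
                    float(self.r[i, j]),
                    float(self.p[i, j]),
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"u": u, "v": v, "r": r, "p": p} for u, v, r, p in self.iter_pairs()
        ]
        return pd.DataFrame(rows)


def correlation_table(scores: ScoreMatrix) -> CorrelationTable:
    """Pearson r and one-tailed p for every variable pair of a score matrix."""
    if scores.n_subjects < 3:
        raise CorrelationError("need at least 3 subjects")
    X = np.asarray(scores.scores, dtype=float)
    sd = X.std(axis=0, ddof=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        names = [scores.variables[i] for i in flat]
        raise CorrelationError(f"constant (zero-variance) columns: {names}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    p = one_tailed_p(r, scores.n_subjects)
    np.fill_diagonal(p, _P_FLOOR)
    return CorrelationTable(scores.variables, r, np.asarray(p), scores.n_subjects)


class ScheduledEdge(NamedTuple):
    u: str
    v: str
    r: float
    p: float


@dataclass(frozen=True)
class PruningSchedule:
    """Edges ordered least significant first (ascending |r|, then node pair)."""

    edges: tuple[ScheduledEdge, ...]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[ScheduledEdge]:
        return iter(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["u", "v", "r", "p"])


def build_graph(correlations: CorrelationTable, min_abs_r: float = 0.0) -> nx.Graph:
    """Weighted undirected graph with an edge wherever |r| > min_abs_r.

    Edge attributes carry the signed correlation (``weight``/``r``) and its
    one-tailed significance (``p``).
    """
    g = nx.Graph(n_subjects=correlations.n_subjects)
    g.add_nodes_from(correlations.variables)
    for u, v, r, p in correlations.iter_pairs():
        if abs(r) > min_abs_r:
            g.add_edge(u, v, weight=r, r=r, p=p)
    return g


def pruning_schedule(correlations: CorrelationTable) -> PruningSchedule:
    """Sort all pairs by ascending |r| (descending p); ties by node-pair order."""
    edges = sorted(
        (
            ScheduledEdge(u, v, r, p)
            for u, v, r, p in correlations.iter_pairs()
        ),
        key=lambda e: (abs(e.r), e.u, e.v),
    )
    return PruningSchedule(tuple(edges))


class SweepStep(NamedTuple):
    """One pruning step: the link just removed and the surviving graph."""

    step: int  # 1-based count of removed links
    r: float  # signed r of the removed link (the current threshold)
    p: float  # one-tailed p of the removed link
    graph: nx.Graph


def prune_sweep(
    graph: nx.Graph, schedule: PruningSchedule, copy: bool = False
) -> Iterator[SweepStep]:
    """Remove scheduled links one at a time, yielding the subgraph after each.

    The yielded graph is the live, progressively pruned object unless
    ``copy=True`` (snapshots are costly on dense networks). Edges listed in
    the schedule but already absent from the graph (e.g. filtered at build
    time) are skipped without emitting a step, so step k always has exactly
    ``initial_edges - k`` edges.
    """
    g = graph.copy()
    step = 0
    for u, v, r, p in schedule:
        if not g.has_edge(u, v):
            continue
        g.remove_edge(u, v)
        step += 1
        yield SweepStep(step, r, p, g.copy() if copy else g)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list: source, target, r, p."""
    rows = [
        {
            "source": u,
            "target": v,
            "r": data.get("r", data.get("weight", np.nan)),
            "p": data.get("p", np.nan),
        }
        for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
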