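"""Synthetic Likert data with planted factor structure, plus benchmark graphs.

The generator emulates the shape of a five-factor questionnaire study:
latent factor scores per subject, items loading on exactly one factor,
independent Gaussian item noise, and equal-probability discretization onto
an integer Likert scale. Facets are item groupings only by default — no
facet-level latent — with an optional nested facet latent for experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from traitnet.scale_data import ItemScoreMatrix, ScaleDefinition, ScoreMatrix


class SyntheticDataError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the planted factor model.

    Defaults reproduce the shape of a 434-subject NEO-PI-R-like study:
    5 factors x 6 facets x 8 items = 240 items on a six-point (0-5) scale,
    primary loadings drawn uniformly from 0.6-0.8 with item noise SD 0.5.
    """

    n_subjects: int = 434
    n_factors: int = 5
    facets_per_factor: int = 6
    items_per_facet: int = 8
    loading_range: tuple[float, float] = (0.6, 0.8)
    noise_sd: float = 0.5
    reversed_fraction: float = 0.0
    likert_levels: Optional[int] = 6  # None -> continuous scores, no discretization
    facet_loading: Optional[float] = None  # optional nested facet latent
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_factors", "facets_per_factor", "items_per_facet"):
            if getattr(self, name) < 1:
                raise SyntheticDataError(f"{name} must be >= 1")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise SyntheticDataError("loading_range must satisfy 0 < lo <= hi <= 1")
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be >= 0")
        if not 0.0 <= self.reversed_fraction <= 1.0:
            raise SyntheticDataError("reversed_fraction must be in [0, 1]")
        if self.likert_levels is not None and self.likert_levels < 2:
            raise SyntheticDataError("likert_levels must be >= 2 (or None)")

    @property
    def n_items(self) -> int:
        return self.n_factors * self.facets_per_factor * self.items_per_facet


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth membership and the generating loading matrix."""

    item_factor: dict[str, str]
    item_facet: dict[str, str]
    loadings: pd.DataFrame  # items x factors, signed primary loadings

    def factor_members(self, factor: str) -> frozenset[str]:
        return frozenset(i for i, f in self.item_factor.items() if f == factor)

    def as_template_assignment(self) -> dict[str, str]:
        return dict(self.item_factor)


def generate_planted_scores(
    cfg: SynthConfig,
) -> tuple[ItemScoreMatrix | ScoreMatrix, ScaleDefinition, PlantedTruth]:
    """Draw a score matrix from the planted one-factor-per-item model.

    Per subject, factor scores are i.i.d. standard normal. Each item value is
    ``loading * factor_score (+ facet_loading * facet_score) + noise``, with the
    loading negated for reversed items. With ``likert_levels`` set, values are
    discretized by equal-probability thresholds of the item's own (analytic)
    marginal normal distribution, so each response level is equally likely and
    the per-item rank order of the continuous values is preserved.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_items = cfg.n_items

    factors = [f"F{k + 1}" for k in range(cfg.n_factors)]
    items: list[str] = []
    item_factor: dict[str, str] = {}
    item_facet: dict[str, str] = {}
    facet_of: dict[str, str] = {}
    factor_of: dict[str, str] = {}
    for k, factor in enumerate(factors):
        for j in range(cfg.facets_per_factor):
            facet = f"f{k + 1}_{j + 1}"
            factor_of[facet] = factor
            for it in range(cfg.items_per_facet):
                item = f"{facet}_i{it + 1}"
                items.append(item)
                facet_of[item] = facet
                item_factor[item] = factor
                item_facet[item] = facet
    scale = ScaleDefinition(tuple(items), facet_of, factor_of)

    loadings = rng.uniform(*cfg.loading_range, size=n_items)
    reversed_mask = rng.random(n_items) < cfg.reversed_fraction
    loadings = np.where(reversed_mask, -loadings, loadings)

    factor_scores = rng.standard_normal((cfg.n_subjects, cfg.n_factors))
    factor_idx = np.array([factors.index(item_factor[i]) for i in items])
    values = loadings * factor_scores[:, factor_idx]

    var = loadings**2 + cfg.noise_sd**2
    if cfg.facet_loading is not None:
        facets = scale.facets
        facet_scores = rng.standard_normal((cfg.n_subjects, len(facets)))
        facet_idx = np.array([facets.index(item_facet[i]) for i in items])
        values = values + cfg.facet_loading * facet_scores[:, facet_idx]
        var = var + cfg.facet_loading**2
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    loading_frame = pd.DataFrame(0.0, index=items, columns=factors)
    for i, item in enumerate(items):
        loading_frame.loc[item, item_factor[item]] = loadings[i]
    truth = PlantedTruth(item_factor, item_facet, loading_frame)

    subjects = tuple(f"s{i + 1}" for i in range(cfg.n_subjects))
    if cfg.likert_levels is None:
        matrix: ItemScoreMatrix | ScoreMatrix = ScoreMatrix(subjects, tuple(items), values)
        return matrix, scale, truth

    # Equal-probability thresholds on the analytic marginal N(0, var):
    # level = #{quantile thresholds below the standardized value}.
    z = values / np.sqrt(var)
    qs = stats.norm.ppf(np.arange(1, cfg.likert_levels) / cfg.likert_levels)
    levels = (z[..., None] > qs).sum(axis=-1).astype(np.int64)
    matrix = ItemScoreMatrix(
        subjects, tuple(items), levels, likert_range=(0, cfg.likert_levels - 1)
    )
    return matrix, scale, truth


def six_node_reference_graph() -> nx.Graph:
    """The unique simple graph with degree sequence (3, 4, 4, 5, 5, 5).

    Three hub nodes (degree 5) are adjacent to every other node; the two
    degree-4 nodes connect to the hubs and to each other; the degree-3 node
    connects only to the hubs. This 13-edge graph is the reference fixture
    for the node- and graph-metric conventions (betweenness 2/3 on the hubs,
    closeness 1/7 on the low node, clustering 0.8 on the hubs, mean geodesic
    34/36 over ordered pairs including self-pairs, density 13/15).
    """
    g = nx.Graph()
    hubs, mids, low = ["h1", "h2", "h3"], ["m1", "m2"], "low"
    nodes = hubs + mids + [low]
    g.add_nodes_from(nodes)
    for h in hubs:
        g.add_edges_from((h, other) for other in nodes if other != h)
    g.add_edge("m1", "m2")
    return g


def generate_benchmark_graph(kind: str, seed: int | None = None, **params) -> nx.Graph:
    """Reproducible simple undirected test graphs.

    Kinds
    -----
    ``two_cliques_bridge(k)``
        two K_k cliques joined by a single bridge edge; the canonical
        well-separated two-community fixture.
    ``ring_lattice(n, k)``
        ring of n nodes each tied to its k nearest neighbours (k even).
    ``erdos_renyi(n, p)``
        G(n, p) random graph.
    ``planted_partition(groups, group_size, p_in, p_out)``
        groups of equal size with dense intra- and sparse inter-group edges.
    """
    if kind == "two_cliques_bridge":
        k = int(params["k"])
        if k < 2:
            raise SyntheticDataError("two_cliques_bridge needs k >= 2")
        g: nx.Graph = nx.complete_graph(k)
        g = nx.disjoint_union(g, nx.complete_graph(k))
        g.add_edge(0, k)  # bridge between the two cliques
        return g
    if kind == "ring_lattice":
        n, k = int(params["n"]), int(params["k"])
        if k % 2 != 0:
            raise SyntheticDataError("ring_lattice degree k must be even")
        if not 0 < k < n:
            raise SyntheticDataError("ring_lattice needs 0 < k < n")
        return nx.watts_strogatz_graph(n, k, 0.0)
    if kind == "erdos_renyi":
        n, p = int(params["n"]), float(params["p"])
        if not 0.0 <= p <= 1.0:
            raise SyntheticDataError("erdos_renyi needs p in [0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed)
    if kind == "planted_partition":
        groups = int(params["groups"])
        size = int(params["group_size"])
        p_in, p_out = float(params["p_in"]), float(params["p_out"])
        if min(p_in, p_out) < 0 or max(p_in, p_out) > 1:
            raise SyntheticDataError("planted_partition probabilities must be in [0, 1]")
        return nx.planted_partition_graph(groups, size, p_in, p_out, seed=seed)
    raise SyntheticDataError(f"unknown benchmark graph kind {kind!r}")
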