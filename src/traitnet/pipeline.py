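"""End-to-end orchestration: scores -> templates -> sweep -> winning network.

The pipeline reproduces the full analysis workflow at item or facet level:

1. load item scores (and the scale definition), aggregate facet scores if
   requested;
2. build membership templates — a *standard* template from the scale's
   a-priori item->factor map (or a supplied file), a *confirmatory*
   forced-choice PCA template at a fixed component count, and an
   *exploratory* one at the Kaiser criterion;
3. compute the all-pairs correlation table with one-tailed p-values, plus
   sampling adequacy (KMO, Bartlett);
4. prune the correlation network link by link in order of increasing |r|,
   detecting greedy-modularity communities at every (strided) step and
   scoring the normalized mismatch against every template;
5. pick the best-matching threshold per template, breaking exact ties by the
   explained-variance criterion, and declare the winning template/structure;
6. compute node and overall metrics of the winning graph, then the
   cluster-level correlation graph of cluster scores at a
   Bonferroni-corrected significance cutoff, discarding isolate clusters.

Everything is deterministic: the only randomness in the package lives in the
synthetic-data generator, and the pipeline records the seed it was given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from traitnet import community_detection, correlation_network, factor_analysis
from traitnet.community_detection import Partition, greedy_modularity_communities
from traitnet.correlation_network import (
    CorrelationTable,
    build_graph,
    correlation_table,
    prune_sweep,
    pruning_schedule,
    write_edge_list,
    write_graphml,
)
from traitnet.factor_analysis import (
    MembershipTemplate,
    bartlett_sphericity,
    component_scores,
    forced_choice_template,
    kmo,
    pca_loadings,
    varimax_rotate,
)
from traitnet.graph_metrics import node_metrics, overall_metrics
from traitnet.scale_data import (
    ItemScoreMatrix,
    ScaleDefinition,
    ScoreMatrix,
    aggregate_facet_scores,
    load_item_scores,
    load_scale_definition,
)
from traitnet.structure_matching import (
    MatchTrace,
    cluster_scores,
    explained_variance_tiebreak,
    match_sweep,
    stability_runs,
)

logger = logging.getLogger("traitnet.pipeline")


class PipelineError(ValueError):
    """Raised with stage context when any pipeline stage fails."""


@dataclass
class PipelineConfig:
    """Run configuration; see module docstring for the stages it drives."""

    scores_path: str
    scale_path: Optional[str] = None
    level: str = "facet"  # "item" | "facet"
    likert_range: tuple[int, int] = (0, 5)
    standard_template_path: Optional[str] = None  # CSV: variable,factor
    confirmatory_k: Optional[int] = 5
    exploratory: bool = True  # Kaiser-criterion PCA template
    min_abs_r: float = 0.0
    stride: int = 1  # detect communities every s-th pruned link
    tiebreak_p: float = 0.01
    cluster_graph_p: float = 0.01  # Bonferroni-corrected over cluster pairs
    isolate_max_size: int = 2  # clusters this small are isolates
    outdir: str = "traitnet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in {"item", "facet"}:
            raise PipelineError(f"level must be 'item' or 'facet', got {self.level!r}")
        if self.stride < 1:
            raise PipelineError("stride must be >= 1")
        if self.confirmatory_k is not None and self.confirmatory_k < 2:
            raise PipelineError("confirmatory_k must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineError(f"{path}: expected a mapping of config keys")
        if "likert_range" in raw:
            raw["likert_range"] = tuple(raw["likert_range"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory summary of a run; files land under ``config.outdir``."""

    config: PipelineConfig
    templates: dict[str, MembershipTemplate]
    trace: MatchTrace
    winning_template: str
    winning_partition: Partition
    winning_threshold: tuple[float, float]  # (r, p) of the last removed link
    best_overall_mismatch: float
    overall: dict[str, float]
    node_table: pd.DataFrame
    isolates: tuple[int, ...]
    summary: dict


def _build_templates(
    config: PipelineConfig,
    scores: ScoreMatrix,
    scale: Optional[ScaleDefinition],
) -> dict[str, MembershipTemplate]:
    templates: dict[str, MembershipTemplate] = {}
    if config.standard_template_path:
        df = pd.read_csv(config.standard_template_path, dtype=str)
        if not {"variable", "factor"}.issubset(df.columns):
            raise PipelineError("standard template CSV needs columns variable,factor")
        templates["standard"] = MembershipTemplate.from_mapping(
            dict(zip(df["variable"], df["factor"]))
        )
    elif scale is not None:
        mapping = (
            scale.item_factor_map()
            if config.level == "item"
            else {f: scale.factor_of[f] for f in scale.facets}
        )
        templates["standard"] = MembershipTemplate.from_mapping(mapping)
    if config.confirmatory_k:
        lm = varimax_rotate(pca_loadings(scores, config.confirmatory_k))
        templates["confirmatory"] = forced_choice_template(lm)
    if config.exploratory:
        lm = varimax_rotate(pca_loadings(scores, "kaiser"))
        templates["exploratory"] = forced_choice_template(lm)
    if not templates:
        raise PipelineError("no templates configured")
    return templates


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("loading scores from %s", config.scores_path)

    items = _stage("load")(load_item_scores)(config.scores_path, config.likert_range)
    scale = (
        _stage("load")(load_scale_definition)(config.scale_path)
        if config.scale_path
        else None
    )
    if config.level == "facet":
        if scale is None:
            raise PipelineError("facet level requires a scale definition")
        scores = _stage("aggregate")(aggregate_facet_scores)(items, scale)
    else:
        scores = items.to_score_matrix()
    logger.info(
        "%d subjects x %d %s-level variables", scores.n_subjects, scores.n_variables, config.level
    )

    templates = _stage("templates")(_build_templates)(config, scores, scale)
    ct = _stage("correlations")(correlation_table)(scores)
    adequacy = {
        "kmo": _stage("adequacy")(kmo)(ct),
        "bartlett": dict(
            zip(("chi2", "df", "p"), _stage("adequacy")(bartlett_sphericity)(ct, ct.n_subjects))
        ),
    }

    graph = _stage("graph")(build_graph)(ct, config.min_abs_r)
    schedule = _stage("graph")(pruning_schedule)(ct)
    logger.info("sweeping %d links (stride %d)", graph.number_of_edges(), config.stride)
    trace = _stage("sweep")(match_sweep)(
        prune_sweep(graph, schedule), templates, stride=config.stride
    )

    # Best threshold per template; ties broken by explained variance.
    per_template: dict[str, dict] = {}
    for name, template in templates.items():
        ties = trace.best_overall(name)
        candidates: list[Partition] = []
        for rec in ties:
            if not any(rec.partition.same_clustering(c) for c in candidates):
                candidates.append(rec.partition)
        fscores = component_scores(scores, template)
        winner, totals = _stage("tiebreak")(explained_variance_tiebreak)(
            candidates, scores, fscores, config.tiebreak_p
        )
        win_rec = next(r for r in ties if r.partition.same_clustering(winner))
        per_template[name] = {
            "record": win_rec,
            "overall_mismatch": win_rec.matches[name].overall,
            "per_factor": win_rec.matches[name].per_factor,
            "n_tied_steps": len(ties),
            "n_candidate_structures": len(candidates),
            "explained_variance_totals": totals,
        }
    winning_template = min(
        per_template, key=lambda nm: per_template[nm]["overall_mismatch"]
    )
    win = per_template[winning_template]["record"]
    logger.info(
        "winning template %s at r=%.4f (overall mismatch %.4f)",
        winning_template, win.r, per_template[winning_template]["overall_mismatch"],
    )

    # Replay the sweep to the winning step to recover the winning subgraph.
    win_graph = None
    for step in prune_sweep(graph, schedule):
        if step.step == win.step:
            win_graph = step.graph.copy()
            break
    assert win_graph is not None

    longest_run, _runs = stability_runs(trace)
    node_table = _stage("metrics")(node_metrics)(win_graph)
    overall = _stage("metrics")(overall_metrics)(win_graph, win.partition)

    # Cluster-level graph from cluster scores; isolates drop out first.
    kept = [
        (cid, comm)
        for cid, comm in enumerate(win.partition.communities, 1)
        if len(comm) > config.isolate_max_size
    ]
    isolates = tuple(
        cid
        for cid, comm in enumerate(win.partition.communities, 1)
        if len(comm) <= config.isolate_max_size
    )
    if isolates:
        logger.info(
            "discarding %d isolate cluster(s) (size <= %d) from cluster-level analysis: %s",
            len(isolates), config.isolate_max_size, list(isolates),
        )
    cluster_level: dict = {"isolates_discarded": list(isolates)}
    if len(kept) >= 2:
        kept_part = Partition(tuple(c for _, c in kept), float("nan"))
        cs = _stage("cluster_graph")(cluster_scores)(scores, kept_part)
        cct = _stage("cluster_graph")(correlation_table)(cs)
        n_pairs = cs.n_variables * (cs.n_variables - 1) // 2
        corrected_p = config.cluster_graph_p / n_pairs  # Bonferroni
        cg = build_graph(cct)
        cg.remove_edges_from(
            [(u, v) for u, v, d in cg.edges(data=True) if d["p"] >= corrected_p]
        )
        write_graphml(cg, outdir / "cluster_graph.graphml")
        write_edge_list(cg, outdir / "cluster_graph.tsv")
        cluster_level.update(
            {
                "n_clusters": len(kept),
                "corrected_p_cutoff": corrected_p,
                "edges": cg.number_of_edges(),
            }
        )
        if cg.number_of_nodes() >= 2:
            cluster_level["overall_metrics"] = overall_metrics(cg)
            node_metrics(cg).to_csv(outdir / "cluster_node_metrics.csv")

    # Artifact bundle.
    write_graphml(win_graph, outdir / "winning_graph.graphml")
    write_edge_list(win_graph, outdir / "winning_graph.tsv")
    trace.to_frame().to_csv(outdir / "match_trace.csv", index=False)
    win.partition.to_frame().to_csv(outdir / "winning_membership.csv", index=False)
    node_table.to_csv(outdir / "node_metrics.csv")
    for name, template in templates.items():
        template.to_frame().to_csv(outdir / f"template_{name}.csv", index=False)

    summary = {
        "config": {**asdict(config), "likert_range": list(config.likert_range)},
        "n_subjects": scores.n_subjects,
        "n_variables": scores.n_variables,
        "adequacy": adequacy,
        "templates": {
            name: {
                "overall_mismatch": info["overall_mismatch"],
                "per_factor_mismatch": info["per_factor"],
                "threshold_r": info["record"].r,
                "threshold_p": info["record"].p,
                "n_tied_steps": info["n_tied_steps"],
                "n_candidate_structures": info["n_candidate_structures"],
            }
            for name, info in per_template.items()
        },
        "winning_template": winning_template,
        "winning_threshold_r": win.r,
        "winning_threshold_p": win.p,
        "winning_n_clusters": win.partition.n_clusters,
        "winning_modularity": win.partition.q,
        "longest_stable_run": longest_run,
        "overall_metrics": overall,
        "cluster_level": cluster_level,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return PipelineResult(
        config=config,
        templates=templates,
        trace=trace,
        winning_template=winning_template,
        winning_partition=win.partition,
        winning_threshold=(win.r, win.p),
        best_overall_mismatch=per_template[winning_template]["overall_mismatch"],
        overall=overall,
        node_table=node_table,
        isolates=isolates,
        summary=summary,
    )
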