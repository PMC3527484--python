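"""Matching network community structure to factor structure.

The core statistic: for a factor's member set F and a cluster's member set C,
the normalized mismatch is |F symmetric-difference C| / (|F| + |C|) — zero for
identical sets, one for disjoint sets, and insensitive to absolute set sizes.
Clusters are paired with factors by the optimal one-to-one assignment that
minimizes total mismatch; surplus clusters are reported unmatched, and
factors left without a cluster score a mismatch of 1.

Sweeping this match over the incrementally pruned subgraphs locates the
pruning threshold at which the community structure best reproduces a factor
template, with an explained-variance criterion breaking exact ties between
equally good thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from traitnet.community_detection import Partition, greedy_modularity_communities
from traitnet.correlation_network import SweepStep, one_tailed_p
from traitnet.factor_analysis import MembershipTemplate
from traitnet.scale_data import ScoreMatrix


class MatchingError(ValueError):
    """Raised for incomparable partitions/templates or empty inputs."""


def normalized_mismatch(factor_members: Iterable, cluster_members: Iterable) -> float:
    """|symmetric difference| / (|factor| + |cluster|), in [0, 1]."""
    f = frozenset(factor_members)
    c = frozenset(cluster_members)
    if not f or not c:
        raise MatchingError("mismatch is undefined for empty sets")
    return len(f ^ c) / (len(f) + len(c))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of pairing one partition against one membership template."""

    cluster_to_factor: dict[int, str]  # 1-based cluster id -> factor label
    per_factor: dict[str, float]  # normalized mismatch per template factor
    overall: float  # unweighted mean over template factors
    surplus_clusters: tuple[int, ...] = ()  # cluster ids left unmatched
    unmatched_factors: tuple[str, ...] = ()  # factors with no cluster (mismatch 1)
    threshold_r: float | None = None
    threshold_p: float | None = None


def assign_clusters_to_factors(
    partition: Partition, template: MembershipTemplate
) -> MatchResult:
    """Optimal one-to-one cluster/factor pairing minimizing total mismatch.

    The partition and template must cover the same variable universe.
    With more clusters than factors the surplus clusters are reported; with
    fewer, unmatched factors are flagged and scored as complete mismatch.
    """
    universe = frozenset(template.variables)
    if partition.nodes != universe:
        raise MatchingError(
            "partition and template cover different variable universes "
            f"({len(partition.nodes)} vs {len(universe)} variables)"
        )
    factors = list(template.factors)
    clusters = list(partition.communities)
    cost = np.empty((len(factors), len(clusters)))
    for fi, factor in enumerate(factors):
        members = template.members(factor)
        if not members:
            raise MatchingError(f"template factor {factor!r} is empty")
        for ci, cluster in enumerate(clusters):
            cost[fi, ci] = normalized_mismatch(members, cluster)
    rows, cols = linear_sum_assignment(cost)
    cluster_to_factor = {int(c) + 1: factors[int(f)] for f, c in zip(rows, cols)}
    per_factor = {factors[int(f)]: float(cost[f, c]) for f, c in zip(rows, cols)}
    unmatched = tuple(f for f in factors if f not in per_factor)
    for f in unmatched:
        per_factor[f] = 1.0
    surplus = tuple(
        cid for cid in range(1, len(clusters) + 1) if cid not in cluster_to_factor
    )
    overall = float(np.mean([per_factor[f] for f in factors]))
    return MatchResult(
        cluster_to_factor=cluster_to_factor,
        per_factor={f: per_factor[f] for f in factors},
        overall=overall,
        surplus_clusters=surplus,
        unmatched_factors=unmatched,
    )


@dataclass(frozen=True)
class TraceRecord:
    """One pruning step: threshold, detected partition, match per template."""

    step: int
    r: float
    p: float
    partition: Partition
    matches: dict[str, MatchResult]  # template name -> result


@dataclass(frozen=True)
class MatchTrace:
    """Full record of the pruning sweep against one or more templates."""

    records: tuple[TraceRecord, ...]
    template_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    def best_overall(self, template: str) -> tuple[TraceRecord, ...]:
        """All records tied at the minimum overall mismatch for a template."""
        best = min(rec.matches[template].overall for rec in self.records)
        return tuple(
            rec
            for rec in self.records
            if abs(rec.matches[template].overall - best) < 1e-12
        )

    def best_per_factor(self, template: str) -> dict[str, TraceRecord]:
        """Per factor, the record minimizing that factor's mismatch alone.

        Ties resolve to the earliest step, i.e. the least-pruned subgraph.
        """
        out: dict[str, TraceRecord] = {}
        factors = self.records[0].matches[template].per_factor
        for factor in factors:
            out[factor] = min(
                self.records, key=lambda rec: (rec.matches[template].per_factor[factor], rec.step)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict = {"step": rec.step, "r": rec.r, "p": rec.p,
                         "n_clusters": rec.partition.n_clusters}
            for name in self.template_names:
                res = rec.matches[name]
                row[f"{name}_overall"] = res.overall
                for factor, mm in res.per_factor.items():
                    row[f"{name}_{factor}"] = mm
            rows.append(row)
        return pd.DataFrame(rows)


def match_sweep(
    sweep: Iterable[SweepStep],
    templates: Mapping[str, MembershipTemplate],
    detect: Callable[..., Partition] = greedy_modularity_communities,
    stride: int = 1,
) -> MatchTrace:
    """Run community detection along a pruning sweep and match every template.

    ``stride`` evaluates only every s-th removal (the intermediate subgraphs
    are still pruned, just not scored), trading resolution of the mismatch
    curve for speed on dense networks.
    """
    if stride < 1:
        raise MatchingError("stride must be >= 1")
    if not templates:
        raise MatchingError("need at least one template")
    records = []
    for step in sweep:
        if step.step % stride:
            continue
        part = detect(step.graph)
        matches = {
            name: replace(
                assign_clusters_to_factors(part, tmpl),
                threshold_r=step.r,
                threshold_p=step.p,
            )
            for name, tmpl in templates.items()
        }
        records.append(TraceRecord(step.step, step.r, step.p, part, matches))
    if not records:
        raise MatchingError("empty sweep: nothing to match")
    return MatchTrace(tuple(records), tuple(templates))


def cluster_scores(scores: ScoreMatrix, partition: Partition) -> ScoreMatrix:
    """Cluster score = per-subject mean of the cluster's member variables.

    Columns are labelled ``cluster1..clusterK`` in the partition's canonical
    (descending-size) order — the same formula as factor component scores,
    applied to detected clusters.
    """
    frame = scores.to_frame()
    cols = {}
    for cid, comm in enumerate(partition.communities, 1):
        members = sorted(map(str, comm))
        missing = [v for v in members if v not in frame.columns]
        if missing:
            raise MatchingError(f"cluster {cid} members missing from scores: {missing}")
        cols[f"cluster{cid}"] = frame[members].mean(axis=1).to_numpy()
    return ScoreMatrix(scores.subjects, tuple(cols), np.column_stack(list(cols.values())))


def explained_variance_tiebreak(
    candidates: Sequence[Partition],
    scores: ScoreMatrix,
    factor_scores: ScoreMatrix,
    p_cutoff: float = 0.01,
) -> tuple[Partition, list[float]]:
    """Pick the candidate whose cluster scores explain most factor-score variance.

    For each candidate, cluster scores are correlated with every factor score;
    r^2 of the significant correlations (one-tailed p < ``p_cutoff``) are
    summed. The candidate with the largest total wins; ties (and a single
    candidate) resolve to the earliest in the list.
    """
    if not candidates:
        raise MatchingError("no candidate partitions")
    totals: list[float] = []
    n = scores.n_subjects
    for cand in candidates:
        cs = cluster_scores(scores, cand)
        total = 0.0
        for ci in range(cs.n_variables):
            for fi in range(factor_scores.n_variables):
                r = float(
                    np.corrcoef(cs.scores[:, ci], factor_scores.scores[:, fi])[0, 1]
                )
                if one_tailed_p(r, n) < p_cutoff:
                    total += r * r
        totals.append(total)
    winner = candidates[int(np.argmax(totals))]
    return winner, totals


def stability_runs(trace: MatchTrace) -> tuple[int, list[tuple[Partition, int, int]]]:
    """Run lengths of identical consecutive partitions along the sweep.

    Returns the maximal run length and, per run, ``(partition, first_step,
    length)``. A community structure that persists across many consecutive
    pruning steps is robust to the exact choice of threshold.
    """
    if not trace.records:
        raise MatchingError("empty trace")
    runs: list[tuple[Partition, int, int]] = []
    prev = None
    for rec in trace.records:
        if prev is not None and rec.partition.same_clustering(prev[0]):
            runs[-1] = (prev[0], prev[1], runs[-1][2] + 1)
        else:
            runs.append((rec.partition, rec.step, 1))
            prev = (rec.partition, rec.step)
    longest = max(run[2] for run in runs)
    return longest, runs
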