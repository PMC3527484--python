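"""Incremental pruning of a correlation network, matched to a template.

Builds the all-pairs correlation graph of planted Likert data, removes links
one at a time from least to most significant, detects greedy-modularity
communities at every step, and scores each community structure against the
planted membership template. The printed optimum is the pruning threshold
(r, one-tailed p) at which the network's community structure best reproduces
the factor structure — on planted data, perfectly.
"""

from traitnet import (
    MembershipTemplate,
    SynthConfig,
    build_graph,
    correlation_table,
    generate_planted_scores,
    match_sweep,
    prune_sweep,
    pruning_schedule,
    stability_runs,
)

cfg = SynthConfig(
    n_subjects=300, n_factors=3, facets_per_factor=2, items_per_facet=4,
    loading_range=(0.6, 0.8), noise_sd=0.5, seed=7,
)
matrix, scale, truth = generate_planted_scores(cfg)
template = MembershipTemplate.from_mapping(truth.as_template_assignment())

table = correlation_table(matrix.to_score_matrix())
graph = build_graph(table)
schedule = pruning_schedule(table)
print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} links "
      f"(all {matrix.n_variables * (matrix.n_variables - 1) // 2} pairs)")

trace = match_sweep(prune_sweep(graph, schedule), {"planted": template}, stride=2)
best = trace.best_overall("planted")
first = best[0]
print(f"best overall mismatch: {100 * first.matches['planted'].overall:.1f}% "
      f"at r = {first.r:.3f} (one-tailed p = {first.p:.2e})")
print(f"{len(best)} sweep steps tie at this optimum; "
      f"{first.partition.n_clusters} clusters at the first of them")

longest, _ = stability_runs(trace)
print(f"longest run of identical community structures: {longest} consecutive "
      "evaluated steps (robustness to the exact threshold)")
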