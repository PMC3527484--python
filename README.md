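# traitnet

Correlation-network community detection matched to factor structure, for
multivariate questionnaire data.

## The problem

Hierarchical questionnaires such as the NEO-PI-R (240 items nested in 30
facets nested in the five factors N, E, O, A, C) are conventionally analysed
with principal component analysis: items are grouped by the factor they load
on. Network analysis offers an alternative and richer view: treat every item
or facet as a node, every significant pairwise correlation as a link, and
extract *communities* — groups of nodes more densely connected among
themselves than to the rest — with a greedy modularity-maximizing
agglomeration (Clauset–Newman–Moore style, non-weighted and non-signed).

The catch is that a correlation network has no natural link threshold. This
package implements **incremental pruning**: remove links one at a time in
order of increasing significance (increasing |r|, i.e. decreasing one-tailed
p at the study's sample size), re-detect the community structure after every
removal, and score each structure against PCA-derived factor templates with
a **normalized mismatch** statistic

```
mismatch(F, C) = |F Δ C| / (|F| + |C|)
```

where F is a factor's member set, C a cluster's member set, and Δ the
symmetric difference (0 = identical, 1 = disjoint). Clusters are paired to
factors by the optimal one-to-one assignment; the overall mismatch is the
unweighted mean over template factors. The pruning threshold minimizing the
overall mismatch defines the "winning" network; exact ties between
thresholds are broken by the total variance in factor scores explained by
cluster scores (sum of r² over significantly correlated cluster–factor
score pairs). The winning network is then characterized with degree,
betweenness, closeness, eigenvector centrality, PageRank, clustering
coefficients, and the Humphries–Gurney small-world coefficient
`S = (C / (k/n)) / (L / (ln n / ln k))`.

Because raw multi-subject personality datasets are rarely shareable, the
package includes a first-class synthetic-data generator that plants a known
factor structure in Likert data (latent factor scores, one loading per item,
Gaussian noise, equal-probability discretization), so every stage — PCA
templates, pruning, community detection, matching — can be validated by
parameter recovery.

## Worked example

```python
from traitnet import (SynthConfig, generate_planted_scores, MembershipTemplate,
                      correlation_table, build_graph, pruning_schedule,
                      prune_sweep, match_sweep)

cfg = SynthConfig(n_subjects=300, n_factors=3, facets_per_factor=2,
                  items_per_facet=4, loading_range=(0.6, 0.8),
                  noise_sd=0.5, seed=7)
matrix, scale, truth = generate_planted_scores(cfg)
template = MembershipTemplate.from_mapping(truth.as_template_assignment())

table = correlation_table(matrix.to_score_matrix())
trace = match_sweep(prune_sweep(build_graph(table), pruning_schedule(table)),
                    {"planted": template}, stride=2)
best = trace.best_overall("planted")[0]
print(best.matches["planted"].overall, best.r, best.p)
```

prints

```
0.0 0.15001341138235955 0.004631353051592394
```

i.e. at the pruning threshold r ≈ 0.150 (one-tailed p ≈ 4.6e-3) the detected
community structure reproduces the planted 3-factor membership exactly
(overall mismatch 0%). The `examples/` directory has one short narrative
script per capability — PCA template recovery, the pruning/matching sweep,
the graph-metric conventions on a 6-node reference graph, and the full
pipeline — each printing the numbers it computes and what they mean. A thin
CLI (`traitnet simulate | pca | sweep | metrics | run`) wraps the same
functions for shell use.

## Metric conventions

Printed reference values pin down several conventions that differ between
tools, so they are explicit here: betweenness is the raw pair-dependency
(each unordered pair counted once, endpoints excluded, equal-length paths
credited fractionally); closeness is 1/(sum of geodesic distances);
eigenvector centrality is normalized to sum 1 per component; PageRank uses
damping 0.85 scaled to mean 1; the average geodesic distance is taken over
all ordered pairs *including* self-pairs at distance 0.

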