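# Methods

## Data model

Input is a subjects × variables matrix of integer Likert responses with a
scale definition mapping items → facets → factors. Responses are coded 0–5
by default (six points); the bound is configurable, and every statistic in
the package is invariant to affine recoding of the response scale. Missing
cells are rejected at load time — no stage downstream defines behaviour for
them, and imputation is out of scope. Facet scores are the arithmetic means
of their member items per subject, factor (component) scores the means of a
template's member variables, cluster scores the means of a detected
cluster's members: one formula at three levels of aggregation.

## Factor templates

Components come from the eigendecomposition of the correlation matrix:
loadings are eigenvectors scaled by √eigenvalue, percent variance is
eigenvalue / n_variables. Retention is either the Kaiser criterion
(eigenvalue > 1; a warning is emitted when eigenvalues crowd the cutoff,
where retention counts are unstable) or an explicit component count for
confirmatory runs. Varimax rotation is performed with Kaiser row
normalization (rows scaled to unit communality before rotating), delegating
the orthogonal rotation itself to `statsmodels`; communalities are preserved
to 1e-8 and each column's sign is fixed so its largest-|loading| entry is
positive, making output reproducible across platforms.

Templates for matching are *forced-choice*: every variable is assigned to
the factor with its largest absolute loading. Absolute value matters — a
variable loading .59 on one factor and −.57 on another belongs with the
first. The conventional 0.40 reporting cutoff never excludes a variable
(the template must partition the whole variable universe to be comparable
with a community partition); sub-threshold assignments are only flagged.
Exact |loading| ties break to the lowest factor index, with a warning.

Sampling adequacy: KMO = Σr² / (Σr² + Σq²) over off-diagonal entries, with
q the anti-image partial correlations from the inverse correlation matrix;
Bartlett's sphericity χ² = −(n − 1 − (2v+5)/6)·ln det R with v(v−1)/2
degrees of freedom. Both are implemented directly from these formulas.

## Correlation network and incremental pruning

All-pairs Pearson correlations carry a one-tailed significance
p = P(T ≥ |r|·√((n−2)/(1−r²))) on n−2 degrees of freedom. The one-tailed
convention is deliberate: it is the convention under which the published
threshold pairs (r = 0.271 → p ≈ 4.9e-9; r = 0.164 → p ≈ 3.1e-4 at n = 434)
are reproduced; the two-tailed p is a factor 2 away. p is computed from |r|,
so it is symmetric in sign and strictly decreasing in |r|.

The pruning schedule orders all pairs by ascending |r| (descending p), ties
broken by lexicographic node pair, so strong *negative* correlations
survive pruning as long as strong positive ones; the sign travels as edge
metadata and never influences pruning order or clustering. The sweep
removes one link per step and re-detects communities on the remainder. A
`stride` parameter evaluates only every s-th removal when the full
resolution is not needed; a coarser stride can only miss optima, never
invent them (the evaluated steps are a subset), which the tests assert.

## Community detection

The detector is the bottom-up greedy modularity agglomeration: start from
singletons and repeatedly apply the merge with the largest modularity gain
ΔQ = e_ij/m − 2a_i a_j, stopping when no gain is positive. Edges are
treated as unweighted and unsigned — the variant used here deliberately
omits the consolidation-ratio heuristics that balance community growth in
Wakita–Tsurumi's original formulation, reducing it to classic CNM
behaviour. Equal gains break toward the lexicographically smallest
community pair (communities keyed by their smallest node label), making
results identical across runs, platforms and node orderings; a lazy
max-heap with staleness checks keeps each detection near-linear in practice
even on the initial complete graph. Isolated nodes remain singleton
clusters; an edgeless graph yields all singletons with Q = NaN and a
warning, since modularity is undefined without edges.

An exhaustive oracle (`brute_force_max_modularity`) enumerates all set
partitions for graphs of ≤ 10 nodes and is used in tests to bound the
greedy result (greedy Q ≤ exhaustive Qmax on 200 random graphs, equality on
cleanly separated fixtures). `networkx`'s own modularity and CNM
implementations serve as independent cross-checks, never as the
implementation.

## Matching and tie-breaking

Normalized mismatch |F Δ C| / (|F| + |C|) is computed for every
factor/cluster pair and clusters are assigned to factors by optimal
one-to-one assignment (Hungarian algorithm on the mismatch matrix) — greedy
pairing would be order-dependent. Surplus clusters are reported unmatched;
factors left without a cluster score mismatch 1 and are flagged. The
overall mismatch is the unweighted mean over template factors, so it is
invariant to cluster relabeling.

All sweep steps tying at the minimal overall mismatch are retained. Ties
between *distinct* community structures are broken by the explained-variance
criterion: per candidate, cluster scores are correlated with factor scores
and the r² of pairs significant at one-tailed p < 0.01 are summed; the
largest total wins. A caveat discovered in simulation and worth stating
plainly: because the criterion sums r² over all significant pairs, clusters
that straddle two factors pick up significant cross-correlations, and a
mildly contaminated partition can out-total a perfectly aligned one. The
criterion is therefore meaningful only in the situation it is used in —
discriminating between near-identical structures that tie on mismatch —
and is not a general alignment measure. Run lengths of identical
consecutive structures along the sweep (`stability_runs`) quantify
robustness of a solution to the exact threshold.

## Graph metrics

Conventions are chosen to match the NodeXL-style reference values and are
asserted against a 6-node fixture (the unique simple graph with degree
sequence 3, 4, 4, 5, 5, 5):

* betweenness: raw pair-dependency, unordered pairs counted once, endpoints
  excluded, fractional credit over equal-length paths (hub value 2/3 on the
  fixture);
* closeness: 1/(sum of geodesics to the other nodes), not the reciprocal of
  the mean (low-degree node: 1/7);
* eigenvector centrality: dense principal eigenvector (deterministic, unlike
  ARPACK iteration), normalized to sum 1 per connected component;
* PageRank: damping 0.85, scaled to mean 1 over nodes (fixture values
  0.730 / 0.928 / 1.138; the mid-node's exact 0.92756 appears truncated to
  0.927 in the reference table);
* average geodesic distance: mean over all ordered pairs *including*
  self-pairs at distance 0 (fixture: 34/36 = 0.9444) — the only convention
  that reproduces the reference value;
* small-worldness: Humphries–Gurney S = (C/(k/n)) / (L/(ln n/ln k)), with C
  the mean local clustering coefficient and L the mean shortest path over
  distinct pairs, requiring a connected graph with mean degree > 1. The
  published S values for the original facet- and item-level networks are
  internally inconsistent (the text and table disagree with each other and
  with this formula), so S is validated behaviourally instead: S > 1 on
  rewired ring lattices, S ≈ 1 on matched Erdős–Rényi graphs.

Hubs are reported as the top decile (ceil(n/10) nodes) of a chosen metric,
boundary ties included and flagged.

## Synthetic data generator

The generator emulates the shape of a 434-subject, 240-item five-factor
study: per subject, factor scores are i.i.d. standard normal; each item
loads on exactly one factor with a loading drawn uniformly from
`loading_range` (default 0.6–0.8), negated for a `reversed_fraction` of
items (default 0 — reversal is off unless studied explicitly); independent
Gaussian item noise with `noise_sd` (default 0.5) is added; values are
discretized onto `likert_levels` (default 6) by equal-probability
thresholds of the item's analytic marginal distribution, so response levels
are uniform and the per-item rank order of the underlying continuous values
is preserved. Facets are item groupings only — no facet-level latent — by
default, consistent with treating facets as nominal structure; an optional
nested facet latent (`facet_loading`) exists for experiments. With defaults,
within-factor item correlations are ≈ 0.4–0.6 and between-factor
correlations ≈ 0, a regime in which both PCA forced choice and the pruning
sweep recover the planted membership exactly (the package's end-to-end
acceptance experiment, seed 1, stride 20 over all 28,680 links).

What the generator does *not* emulate: acquiescence and other response
styles, skewed marginals, correlated factors, item-specific thresholds
(graded-response IRT), and real facet-level dependence. Passing recovery
tests therefore demonstrates correctness of the machinery under the stated
factor model, not performance guarantees on real questionnaire data.

## Pipeline

`run_pipeline` chains the stages at item or facet level: load → (facet
aggregation) → templates (standard from the scale's a-priori map or a file;
confirmatory PCA at fixed k; exploratory PCA at the Kaiser criterion) →
correlation table with KMO/Bartlett → pruning sweep with per-step matching
→ per-template best thresholds with explained-variance tie-break → winning
graph metrics → cluster-level analysis. For the cluster-level graph,
clusters of ≤ 2 variables ("isolates") are discarded with a log record,
cluster scores are correlated, and links are kept at p < 0.01 with
Bonferroni correction over the cluster-score pairs (the correction method
is a package choice; only "corrected" is inherited). Outputs (GraphML and
TSV edge lists, membership and trace CSVs, metrics, a summary JSON) are
byte-identical across repeated runs; the pipeline itself uses no
randomness, and the recorded seed governs only synthetic input generation.

## Numerical and scale choices

Problem sizes in the test suite are chosen to exercise every code path
quickly: unit tests use 3-factor, 24-item planted data at n = 250–300;
the full-scale recovery test uses the complete 434 × 240 design with the
sweep evaluated every 20th link. The oracle-equivalence test draws 200
G(n, p) graphs with 3–8 nodes (Bell-number enumeration keeps the exhaustive
search exact). Comparisons against printed reference values use the
precision of the printed figure; significance thresholds printed from
unrounded correlations are checked both pointwise (2.5% relative) and by
interval containment under the rounding of r to three decimals.

## Known limitations

* Greedy agglomeration is a heuristic: on some graphs its Q falls short of
  the exhaustive optimum (observed gaps up to ~0.08 on small random
  graphs); the tests bound it but do not require global optimality except
  on cleanly separated fixtures.
* The explained-variance tie-break is not an alignment measure (see above).
* Oblique rotations, maximum-likelihood factor analysis, parallel analysis,
  weighted/signed/hierarchical community detection and disparity-filter
  thresholding are out of scope.
* Reverse-keyed item handling (re-keying before aggregation) is not
  implemented; the generator's reversed items exercise the |r|-based
  pruning and unsigned clustering paths instead.
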