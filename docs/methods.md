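# Methods

## Rank values

Each inference algorithm emits a list of candidate edges sorted by
non-increasing confidence. Because confidence scales are heterogeneous
across algorithms, all aggregation happens on *rank values*: position 1 is
the most confident edge, tied scores share the midrank (the mean of the
positions they occupy, so fractional values such as 3.5 occur), and when
a list is truncated to its top L edges the T − L unlisted edges all
receive the fill rank (L + 1 + T)/2 — the midrank of positions L+1..T.
Every rank vector over a T-edge universe therefore sums to T(T+1)/2, a
conservation law the tests enforce throughout.

The candidate-edge universe is every ordered (regulator, target) pair
without self-loops (or every unordered pair in undirected mode), sorted
lexicographically so that matrices are reproducible across runs. Distance
computations on undirected universes automatically run over unordered
pairs only, since each unordered pair appears once in the universe.

## Consensus rules

Given the M × T rank matrix of an ensemble:

* **TopkNet(k)**: consensus value of an edge = k-th smallest of its M
  rank values. "k-th best" is the numerically smallest rank, which is the
  interpretation forced by the worked example (Top1Net picks 1 from
  {1, 3.5, 10, 10.5, 12}). Values are element-wise non-decreasing in k;
  k=1 and k=M are the min and max.
* **Community prediction**: consensus value = arithmetic mean of the M
  rank values (7.4 for the quintet above). The mean, not the median, is
  used for all M, including even M.

Consensus values are finalized by midranking them into final ranks 1..T
and exporting confidence 1 − (rank − 1)/T ∈ (0, 1], so results round-trip
through the standard 3-column prediction format. No resampling is
performed anywhere: the "bagging" flavour of the framework is exactly the
order-statistic/mean aggregation above.

All T universe edges receive consensus values; edges listed by no
algorithm simply tie at the bottom via their fill ranks.

## Evaluation

Edges ranked at or better than a threshold are called positive; sweeping
the threshold over every distinct rank value yields confusion counts
(TP + FP + TN + FN = T), precision TP/(TP+FP), recall TP/(TP+FN), and the
PR and ROC staircases. Tied ranks enter as one block, so no ordering
credit accrues within a tie; with this convention the trapezoidal AUC-ROC
equals the tie-adjusted Mann–Whitney probability that a random true edge
outranks a random false edge (verified against an exhaustive
pair-enumeration oracle). Precision at zero calls is anchored at 1 for
curve construction only. Max F-score is the best harmonic mean 2pr/(p+r)
over thresholds, with f ≡ 0 where p + r = 0.

Significance uses a seeded Monte-Carlo null: N uniformly random
permutations of the T ranks (untied rankings 1..T), with the add-one
estimate p = (b + 1)/(N + 1), b = number of null AUCs ≥ observed. p is
deterministic given the seed and bounded in [1/(N+1), 1]. The default is
N = 1000 draws. The overall score across benchmark networks is
OS = ½(p₁ + p₂), where p₁ and p₂ are the means of the −log₁₀-transformed
AUC-PR and AUC-ROC p-values; base 10 makes larger OS better and keeps the
conventional ordering of methods. Because the null is Monte-Carlo rather
than an analytic density fitted to a specific benchmark, OS values are
comparable within a run but not across differently-specified nulls.

Group comparisons (e.g. high- vs low-diversity pairs) use the Wilcoxon
rank-sum test: exact enumeration of all label assignments when both
groups have ≤ 10 observations (midranks handle ties, so identical groups
give p = 1 exactly), and the normal approximation with tie correction
otherwise; two-sided by default with a one-sided option.

## Diversity and similarity

Score vectors default to the rank-normalized form 1 − (rank − 1)/(T − 1)
∈ [0, 1], since raw confidences from heterogeneous algorithms are not
commensurable; raw mode is retained for experiments on a single score
scale. Two distances are defined on the M × T score matrix:

* **EUC**: Euclidean distance between two algorithms' score vectors.
* **PCA**: Euclidean distance between algorithms in the PC2/PC3 plane of
  covariance PCA (columns centered, not scaled; algorithms are the
  observations). PC1 mostly encodes overall confidence level, so
  restricting to PC2/PC3 highlights *how* algorithms differ. Component
  signs are canonicalized (largest-magnitude loading positive) for
  deterministic output; numerically zero-variance components contribute
  exactly zero, so with M = 3 the distance degenerates to |ΔPC2|. The PCA
  distance is a pseudo-metric: distinct algorithms may coincide in the
  plane.

High/low-diversity pairs are the top/bottom ⌈fraction × M(M−1)/2⌉ pairs
by distance (default fraction 0.1: 45 pairs → 5 each; ceiling is required
for that arithmetic to work), ties broken by pair order.

Dataset similarity S(da₁, da₂) is the Spearman correlation (midrank ties)
between the two datasets' pair-distance vectors computed with the same
ensemble and metric. A constant vector makes ρ undefined and is reported
as such rather than as an arbitrary number. Transfer recommendation picks
the known dataset with maximal ρ against the unknown dataset (ties by
label) and returns its top-count algorithms by AUC-PR (default 10, ties
by algorithm id). EUC- and PCA-based similarities are reported
separately, never merged.

## Synthetic benchmark

The generator emulates the study conditions the consensus framework
targets. A gold standard samples ⌈density · T⌉ true edges uniformly from
a directed regulators × genes universe. Algorithm scores follow an
additive Gaussian model: a latent signal z(e) ~ N(μ₁, 1) for true edges
and N(0, 1) for false ones, shared by all algorithms, plus per-algorithm
noise correlated within algorithm families:

    score_a(e) = q_a z(e) + sqrt(1 − q_a²) ε_a(e),
    ε_a(e) = sqrt(ρ_g) η_g(e) + sqrt(1 − ρ_g) η_a(e).

This is the simplest mechanism with independent dials for accuracy (q_a,
μ₁) and redundancy/diversity (families g, ρ_g).

Defaults (one choice, fixed): 200 genes, 30 regulators (T = 5970),
density 0.02 (~120 true links), M = 10 algorithms with uniform quality
q = 0.8 in five families of two, within-family correlation ρ_g = 0.8,
signal shift μ₁ = 2.0 (individual AUC-ROC ≈ 0.87 — a strong but imperfect
algorithm). The ensemble deliberately mimics what selecting the ten best
algorithms on a real benchmark produces: comparably accurate methods
drawn from a handful of methodological families, with same-family methods
ranking edges nearly identically. In that regime the optimistic Top1Net
consensus beats the best individual algorithm; a quality spread wide
enough that one member clearly dominates (or near-total redundancy)
instead favours the individual leader, which is exactly the distinction
the benchmark is meant to expose. Weak-algorithm experiments use
q ∈ [0.05, 0.2].

What the generator does *not* model: expression dynamics, network motif
structure, heavy-tailed score distributions, and algorithms whose errors
concentrate on specific network substructures. Passing tests therefore
show that the consensus/diversity/similarity machinery behaves as
designed under controlled signal/noise/redundancy, not that any specific
real dataset will reproduce the same margins.

A toy linear expression simulator (targets = sum of their true regulators
plus Gaussian noise) feeds the correlation baseline scorers
(|Pearson| or |Spearman| between regulator and target rows), which are
deliberately simple stand-ins for real inference algorithms.

## Numerical and design choices

* Ties everywhere are midranks; selection and truncation ties break
  lexicographically (by edge, pair order, algorithm id, or dataset
  label), making every output deterministic.
* Truncation cuts strictly at top L after the tie-break — never
  "keep all tied" — so output sizes are exact.
* Trapezoidal integration for both AUCs; the PR staircase with one point
  per distinct threshold can differ in the third decimal from
  interpolated variants.
* All randomness flows through numpy Generators seeded from explicit
  config/CLI seeds; generators are bit-reproducible.
* Readers are strict (malformed line → error with line number) because
  silent coercion of benchmark files corrupts evaluations invisibly.

## Problem sizes

The test suite runs the synthetic benchmark at its default desk scale
(T = 5970, M = 10–20, 10–20 replicates per phenomenon) and the oracle
cross-checks at T ≤ 12, chosen so stable medians emerge while the whole
suite completes in well under a minute of compute plus the seeded
Monte-Carlo nulls.

## Known limitations

* Empirical p-values are Monte-Carlo, so benchmark-specific analytic
  overall scores are not reproduced numerically.
* PCA distance depends on the ensemble it is fitted on; adding or
  removing algorithms changes all coordinates.
* The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and is therefore
  capped at group sizes of 10.
* Undirected universes canonicalize edges lexicographically; mixing
  directed predictions into an undirected universe silently merges the
  two orientations (by design, but worth knowing).
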