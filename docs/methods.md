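# Methods

This note documents the models and procedures implemented in `stniche`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## Array geometry

`synth.make_array` places spot centers on a regular lattice at exactly the
requested pitch (default 100 μm; hexagonal rows at pitch·√3/2 with
alternate rows offset by half a pitch, or a square grid). The block is
sized to the smallest lattice holding the requested count, surplus
positions are trimmed farthest-from-center first with a deterministic
(row, col) tie-break, and the block is centered in the frame.

The platform's printed figures — 5000 spots, 100 μm center spacing, 55 μm
diameter, 6.5 × 6.5 mm — are jointly infeasible: by the hexagonal packing
bound, at most 4978 points with pairwise minimum distance 100 μm fit in
that frame. The generator treats the spot count and the exact pitch as
authoritative (both are what downstream statistics depend on) and lets
boundary rows overhang the nominal frame by at most one row pitch
(86.6 μm; the default array overhangs by 82 μm in y). Requests beyond that
tolerance raise an error naming the maximum feasible count. Interior
nearest-neighbor spacing is exact to machine precision (~1e-13 μm,
from the irrational row pitch).

## Count model

Counts are Poisson with per-spot, per-gene mean

μ(s, g) = (Σ_t θ(s, t) · β(t, g)) · m(s, g) · e^(−λ_g · d(s)),

where θ are the planted cell-type proportions, β the per-type expected
counts, m a planted hotspot multiplier (> 1 inside its spot region, 1
elsewhere), λ_g a per-gene decay rate against d(s), the spot's mean
distance to a designated niche, followed by independent Bernoulli dropout
(default 0 for plain tissues, 0.1 in the demonstration tissue). Poisson +
dropout is the simplest model exhibiting the zero excess characteristic of
spot-level data; it does not model gene–gene correlation beyond
cell-type mixing, per-spot capture-efficiency variation, or spatial
autocorrelation of library size — so calibration results here say nothing
about robustness to those (real-data) effects, only that the statistics
are correct under their own null.

For a planted gradient gene, every profile's mean is set to the planted
baseline so its expected count is exactly baseline · e^(−λ·d) and the
gradient is not confounded with cell-type banding.

## Normalization

The hotspot and gradient statistics operate on log-transformed normalized
expression; which normalization to use is an open choice, since both
depend only on relative per-spot levels. We use per-spot library-size
scaling to the
median total count (a `fixed:C` target is available) followed by log1p;
spots with zero totals stay zero and are flagged. Both downstream
statistics (the mean + 1 σ threshold and Spearman ρ) depend only on
relative per-spot levels, so the choice of target affects nothing but the
scale of reported values.

## Deconvolution and model order

LDA is fitted with scikit-learn's batch variational estimator on raw
counts (spots = documents). Perplexity is computed on the training data;
held-out perplexity would need a spot split that the small fixtures cannot
spare, and the selection rule only compares models on the same data. A
*low-abundance topic* has mean proportion below 5% across spots (a
judgment call with no canonical value; 5% of a spot is below one cell's
contribution in typical spots). The dual selection criterion ("lowest
perplexity and fewest low-abundance topics") can conflict; we resolve it
lexicographically — fewest low-abundance topics first — because a starved
topic is direct evidence of overspecification, while perplexity
differences between adjacent K are often within noise. The full grid is
always reported so a user can override.

One estimator-specific caveat, found while validating: with the default
document-topic prior (1/K), mean-field variational LDA splits a
homogeneous tissue into K near-identical topics with equal shares instead
of starving the surplus ones, so an overspecified model may show zero
low-abundance topics at K barely above the truth. Perplexity still rises
past the true K, so the lexicographic rule recovers it; a sparse prior
(`doc_topic_prior` ≪ 1) restores the starvation behavior when the
low-abundance signal itself is wanted.

Topic annotation scores each marker set by the one-sided hypergeometric
tail of its overlap with the topic's candidate markers (log₂ fold > 1
versus the mean of the other topics, with a 1e-12 floor inside the log)
over the dataset's gene universe; smallest p wins, ties broken by larger
overlap, no candidates ⇒ "unassigned". This is an exact, closed-form
reading of the described marker rule rather than a ranked GSEA, and it is
what the oracle tests verify. Manual curation is supported only as an
explicit `override(topic, label)` that flags the topic as overridden.

## Niche rules

Topics sharing a label are pooled before the dominant type is taken.
Tumor and immune are positive classifications requiring the dominant
class proportion to reach the 0.5 threshold; everything else — including
spots with no majority — falls to stroma, matching the rule structure
where stroma is the residual category. Which labels count as tumor-class
or immune-class is a configuration mapping (defaults: tumor = {melanoma},
immune = {B cell, stroma immune}), since label vocabularies are
cohort-specific. Every spot records which rule fired.

## Hotspot test

The population (n-denominator) standard deviation is used in the
mean + 1 σ threshold so thresholds are bit-reproducible; scores strictly
above the threshold are high. A consequence worth knowing: if k of n
spots share a common high score, the threshold can only fall below that
score when k/n < 1/2 — the rule cannot call half the tissue a hotspot,
and the smallest toy with a 3-spot hotspot has 7 spots.

Null draws are uniform without replacement (a "selection" of spots);
subset indices are sorted before summation so identical subsets give
bit-identical sums. Aggregation means a *small* pairwise-distance sum, so
the p-value is the lower tail with the add-one estimator,
p = (1 + #{null ≤ obs})/(1 + n_perm), which is never zero. With
`exhaustive=True` all C(n, k) subsets are enumerated and p = #{≤}/C(n, k),
which equals the exact combinatorial tail (the observed subset is in the
enumeration). Sets with fewer than 5 high spots (configurable) are
reported as skipped, never significant. Raw p and BH-adjusted p are both
reported. Per-set permutation seeds are derived from the global seed and
the set *name*, so a set's result does not depend on which other sets are
tested alongside it.

## Gradient test

Distances are arithmetic means of Euclidean distances (μm) from each
non-reference spot to all reference-niche spots. Spearman ρ uses midranks;
p comes from the t approximation, with an exact pairing-permutation option
for small n. Genes constant over the used spots have undefined ρ and are
reported with p = 1 and direction "none". A `restrict_to` option limits
the correlation to spots of one niche (e.g. tumor spots against a stroma
reference — the interface use case). The binned comparison uses half-open
[0, w), [w, 2w) … intervals (default w = 2000 μm, read as micrometers),
median log-expression per bin, and a two-sided rank-sum test of the
proximal bin against each farther bin — exact U distribution when the
smaller group has ≤ 25 spots, normal approximation otherwise — BH-adjusted
across comparisons. The rank-sum is the standard nonparametric two-sample
choice for medians and is what the enumeration oracle verifies.

## Benchmark study designs

All benchmarks generate their own data and score against planted truth;
sizes are chosen to make each study conclusive at desk scale.

* **Array fidelity** — the default 5000-spot array, measured spacing via a
  KD-tree.
* **Oracle equivalence** — 12-spot random tissues; exhaustive-null p vs. an
  independently re-enumerated combinatorial tail (equal to machine
  precision).
* **Null calibration** — 1000 spots, 200 disjoint 10-gene sets, dropout
  0.2, no spatial structure; the fraction of sets at p < 0.05 must fall in
  the binomial 99% band around 0.05 (n = 200). Calibration of a
  permutation test does not depend on expression level, so the cheaper
  tissue buys 200 quasi-independent tests.
* **Power** — the full 5000-spot array, a 20-spot disc (0.4% of the
  tissue) at multiplier 5, 20 seeds. The mean + 1 σ rule isolates so small
  a lesion only when the per-spot set score is tight around its mean:
  the planted set is KEGG-sized (100 genes) over a well-expressed
  2500-gene panel (per-gene mean ≈ 8), and dropout is left at zero —
  per-gene Bernoulli dropout at rate q inflates the score standard
  deviation by ~q(1−q)·E[log1p]² per gene, which drowns a 0.4% lesion for
  any realistic set size. This is a genuine property of the threshold
  rule, not of the implementation: detecting small hotspots in sparse data
  requires large, well-expressed gene sets.
* **Gradient recovery** — 800 spots, 200 genes, five planted decay genes
  at the weakest rate the pipeline should flag (5 × 10⁻⁴/μm, baseline 5,
  dropout 0.1), stroma = left 30% of spots; recovery means all planted
  genes negative and in the top decile by |ρ|, over 10 seeds. The exact
  ρ = −1 check uses generic-position (continuous random) coordinates: a
  symmetric lattice produces floating-point near-ties in mean distances
  that collapse to exact expression ties under the exponential, breaking
  the rank bijection for reasons unrelated to the statistic.
* **K selection** — 450 spots, 80 genes, three banded types at 0.9 purity,
  dropout 0.1, grid K = 2..7 (the pipeline default grid stays 3–15; the
  fixture's truth is K = 3, so the study grid brackets it from both
  sides), 10 seeds. Niche accuracy is
  scored on the *selected* model, as the pipeline runs it: when a seed's
  K = 3 fit lands in a degenerate optimum, the selection rule moves to
  K = 4 and the pooled labels still classify every high-purity spot
  correctly — which is the behavior the selection rule exists to provide.

## Known limitations

* The generator does not simulate H&E images, sequencing error, spatial
  library-size trends, or gene–gene correlation beyond mixing; results on
  it validate statistical correctness, not robustness to platform
  artifacts.
* Training-data perplexity is used for model order; for large cohorts a
  held-out split may select differently.
* The exhaustive hotspot null is capped at 2 × 10⁶ subsets.
* Topic annotation assumes marker sets overlap the measured gene universe;
  labels are only as good as the supplied markers, and the manual override
  exists precisely because cohort-specific curation cannot be automated.
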