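# stniche

Spatial statistics for Visium-style spot transcriptomics of tumor tissue:
who is where, and what changes at the boundaries.

Spot-based spatial transcriptomics measures RNA counts on a hexagonal grid
of 55 μm capture spots (≈100 μm apart, ~5000 spots per 6.5 × 6.5 mm
section). Each spot covers several cells, so the analysis questions that
matter in a tumor section — where the malignant cells, stroma, and immune
infiltrate sit, which pathways switch on in spatially confined regions, and
which genes respond to proximity between compartments — all have to be
answered through spot-level statistics. `stniche` implements that workflow
as a tested, reusable library:

1. **Deconvolution** (`stniche.deconvolve`) — latent Dirichlet allocation
   over spots-as-documents / genes-as-words infers per-spot cell-type
   proportions θ (spots × K) and topic-gene profiles β (K × genes). The
   number of topics K is chosen over a grid (default 3–15) by a
   lexicographic rule: fewest *low-abundance topics* (mean proportion
   < 5%), then lowest perplexity. Topics are labeled by hypergeometric
   over-representation of their log₂-fold > 1 genes in cell-type marker
   sets, with a top/bottom-15 report and a manual-override hook.
2. **Niche classification** (`stniche.niches`) — each spot's pooled
   dominant cell type maps to **tumor** (tumor-class label at proportion
   ≥ 0.5), **immune** (B-cell / stroma-immune class at ≥ 0.5), else
   **stroma**; every spot carries a rule trace.
3. **Hotspot detection** (`stniche.stenrich`) — for a gene set, spots
   scoring above mean + 1 σ of the per-spot mean log-normalized set
   expression are "high"; the observed sum of pairwise Euclidean distances
   among high spots is compared to sums from random same-size spot draws
   (default 1000). Aggregation ⇒ small sums, so
   p = (1 + #{null ≤ obs}) / (1 + n_perm); exact subset enumeration is
   available for small tissues, Benjamini–Hochberg across sets.
4. **Expression gradients** (`stniche.stgradient`) — for every spot outside
   a reference niche, its mean Euclidean distance to the reference spots;
   per gene, Spearman ρ between distance and log-normalized expression
   (midranks for ties), plus a binned-distance comparison (half-open
   2000 μm bins, rank-sum proximal vs. farther) and nonzero-expression
   prevalence.
5. **Synthetic tissues** (`stniche.synth`) — a Visium-like generator with
   exact array geometry, cell-type mixing (Poisson counts over mixed
   profiles), planted hotspots, planted distance-decay genes
   (μ ∝ e^(−λ·d)), and Bernoulli dropout — with the ground truth serialized
   next to the spaceranger-style export so every stage above is scored
   against known truth.

`stniche.io` reads/writes the standard formats (Matrix Market counts +
barcode/feature lists + tissue-positions CSV, GMT gene sets) and does
per-spot library-size normalization (median total or fixed target, then
log1p). `stniche.pipeline.run_pipeline(PipelineConfig())` orchestrates all
stages with a checksummed manifest and per-stage error isolation.

## Worked example

The numbered drivers under `analysis/` run the whole story on the bundled
synthetic tissue (80 genes × 450 spots; three banded cell types at 0.9
purity; one planted 25-spot hotspot at multiplier 5; three stroma-referenced
decay genes; 10% dropout):

```sh
python analysis/01_simulate_tissue.py     # writes scratch/data/
python analysis/02_deconvolve_niches.py   # K selection, topic labels, niches
python analysis/03_hotspot_enrichment.py  # hotspot permutation tests
python analysis/04_niche_gradients.py     # distance gradients + binned test
```

`02` prints the selection grid and niche composition:

```
 K  n_low_abundance_topics  perplexity  selected
 2                       0   60.637473     False
 3                       0   54.596252     False
 4                       0   54.324453      True
 ...
selected K = 4
topic labels: {0: 'melanoma', 1: 'B cell', 2: 'unassigned', 3: 'fibroblast'}
niche composition: {'tumor': 144, 'immune': 157, 'stroma': 149}
```

K = 4 rather than the 3 planted cell types is informative: the planted
hotspot adds a fourth transcriptional program, which surfaces as the
unassigned topic; the three niches still match the planted ~150-spot bands.
`03` recovers the planted hotspot and — correctly — the spatially banded
fibroblast markers, while the null sets stay flat:

```
               set  n_high  observed_sum        p  adjusted_p status
fibroblast_markers     128  6.285715e+06 0.000999    0.001998 tested
        null_set_A      69  2.669292e+06 0.999001    0.999001 tested
        null_set_B      74  2.971825e+06 0.989011    0.999001 tested
   planted_hotspot      32  2.567276e+05 0.000999    0.001998 tested
```

`04` finds the planted decay genes at the top of the gradient table
(G0062: ρ = −0.244, BH-adjusted p ≈ 0.001, decreasing with distance from
stroma) and shows the binned view: median log-expression 1.09 within
1000 μm of stroma vs. 0.71 beyond (rank-sum p ≈ 1.3 × 10⁻⁴).

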