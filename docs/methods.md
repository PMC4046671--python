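# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `filamix`, together with what the test
suite does and does not establish about real data.

## The mixing model

A whole-filament RNA preparation is a physical mixture of vegetative-cell
and heterocyst RNA. With F_i, V_i and Ht_i the replicate-mean signals of
gene *i* in the three preparation types, the model is the no-intercept
plane

    F_i = a·V_i + b·Ht_i

with *a* and *b* global constants reflecting cell-type abundance and RNA
yield. For typical heterocyst frequencies (5–10% of cells) and equal
per-cell RNA, a ≈ 0.92 and b ≈ 0.08. The coefficients are deliberately
**unconstrained**: neither positivity nor a+b=1 is imposed, because real
data can produce â > 1 or b̂ < 0, and such estimates are diagnostic
(e.g. of unequal cDNA loading or unreliable heterocyst fractions) rather
than errors to be clipped away.

Two fitting routes are provided and kept deliberately distinct:

* `ols` — closed-form least squares through the origin on (V, Ht) → F.
  The 2×2 normal equations are solved directly; a rank check rejects
  collinear V/Ht input.
* `grid` — exhaustive lattice search minimizing the sum of squared
  *weighted* residuals (below). Default lattice a ∈ [0, 1.5],
  b ∈ [−0.3, 0.5], step 0.001. The weighted objective is quadratic in
  (a, b), so it collapses to six precomputed scalar moments and the
  ~1.2M lattice evaluations are a single broadcast — the brute-force
  search stays honest while costing milliseconds. Using the
  weighted-residual objective keeps the search coherent with the outlier
  statistic; the a/b ranges comfortably bracket every plausible estimate,
  including the anomalous-sign cases above.

Uncertainty comes from a gene-level bootstrap: genes are resampled with
replacement n_boot times (default 1000), the model is refitted, and 95%
percentile intervals are reported. The resampling generator is explicitly
seeded; identical seeds give identical intervals. Coverage was checked by
simulation (scaled down to 60 datasets × 200 resamples in the test
suite): intervals cover the generating b in the 90–99% band.

The fit operates on replicate **means**, matching the model's definition
of F_i, V_i, Ht_i; replicate-level fitting is not the default anywhere.

### Data reduction before fitting

Two filters precede the fit, per growth condition:

1. genes whose mean across the condition's nine samples is below
   128 signal-intensity units (SIU) — too close to background for the
   ratio structure of the model to be meaningful;
2. genes whose replicate coefficient of variation exceeds a threshold
   (default 0.5) within any sample-type group — irreproducible
   measurements. The CV-within-any-group rule is this package's concrete
   definition of "high variability between biological replicates"; the
   threshold is configurable and the filter can be disabled
   (`cv_threshold=inf`).

The low-signal filter runs first, and a gene is counted in exactly one
removal bucket, so the reduction report always reconciles.

## The weighted-residual degradation statistic

    R_i = (F_i − a·V_i − b·Ht_i) / sqrt(V_i² + Ht_i² + F_i²)

The denominator — the length of the (V, Ht, F) vector — expresses the
residual as a proportion of the gene's overall transcript level, making
R comparable between weakly and strongly expressed genes. Genes with
V = Ht = F = 0 have no defined direction and are excluded with a warning.

Interpretation of the sign: R_i ≫ 0 (direction `f_high`) means the
filament carries more of transcript *i* than the isolated fractions can
explain — the transcript was lost during cell separation, classically by
rapid degradation in isolated heterocysts (nitrogenase transcripts).
R_i ≪ 0 (`f_low`) is the converse. Ranking uses |R| by default; both
one-sided directions are exposed because the biological question usually
concerns `f_high`. Rank ties break lexicographically by gene id so output
is deterministic.

## Differential expression

Per gene and condition, vegetative vs heterocyst expression is compared
with a two-tailed Welch t-test (unequal variances, Welch–Satterthwaite
degrees of freedom). Tests run on log2-transformed signals by default
(variance stabilization of multiplicative noise); a raw-scale flag
exists. Fold change is the ratio of replicate means (not the mean of
ratios), oriented Ht/V; means below 1 SIU are clamped to 1 before the
ratio and flagged, since values below background resolution cannot
support a ratio. A gene is "up" in a cell type when its fold exceeds the
threshold (strict inequality, default 2) at p below alpha (strict,
default 0.01). No multiple-testing correction drives the classification;
a Benjamini–Hochberg column is available for modern workflows but is
purely informational.

Degenerate inputs follow explicit conventions, with warnings: both
groups constant and equal → p = 1; zero variance with unequal means →
p = 0.

A calibration caveat the tests quantify: with three replicates per
group, the Welch approximation is conservative in the far tail — on null
data the true rate of p < 0.01 is ~0.5–0.6%, not 1%. The null-calibration
checks therefore simulate with the background floor disabled (floor
clamping censors low-signal genes and deflates the rate further, which
would test censoring rather than the t approximation).

## Profiling

* **PCA** treats the samples (arrays) as observations and genes as
  features, centered per gene (optionally scaled). Component signs are
  fixed so each loading vector's largest-magnitude entry is positive,
  making scores reproducible. Variance-explained fractions are reported
  per component.
* **Category profiles**: each of the sixteen functional categories is
  credited with 100 × (sum of its genes' group-mean signals)/(total);
  shares sum to 100 by construction. Group means default to
  condition × sample-type replicate means.
* **Expression bins**: the ordinal seven-level scale background (≤150),
  just-above-background (151–200), very-low (201–600), low (601–2,000),
  moderate (2,001–6,000), high (6,001–20,000), very-high (20,001–60,000)
  SIU; boundaries are inclusive of their upper endpoint and values above
  60,000 clamp into very-high. The background vs just-above-background
  distinction is admittedly soft; both labels are emitted and merging is
  left to presentation.
* **Percent-of-maximum**: a gene's group-mean signal as a percentage of
  the strongest gene in that group — the natural scale for statements
  like "nifH reached 44% of the strongest heterocyst signal".

## Quantile normalization

Standard per-rank-mean quantile normalization across sample columns: the
reference distribution is the mean of the sorted columns; each column's
order statistics are replaced by the reference, preserving within-column
rank order. Ties within a column all receive the mean of the reference
values their ranks span — deterministic and symmetric. Consequences
worth knowing: on tie-free data all output columns share exactly one
multiset and the transform is idempotent to numerical precision; columns
containing ties (e.g. saturated or floor-clamped values) deviate from the
common multiset at the tied ranks, by construction. Vendor-normalized
input can be passed through unchanged (`--skip-quantile`).

## RT-qPCR quantification and cell specificity

Quantities are interpolated from a dilution-series standard curve — Ct
regressed on log10(cDNA amount) — rather than ΔΔCt. A valid assay has
negative slope; amplification efficiency is 10^(−1/slope) − 1, with
−3.32 Ct/decade ⇔ 100% (perfect doubling). Levels are normalized to the
constitutively expressed reference gene (rnpB) quantified from the same
sample; the constancy assumption is checked (warn at >5% Ct spread), not
enforced.

Cell specificity of an RNA preparation uses a marker gene expressed in
only one cell type (rbcL → vegetative cells, nifK → heterocysts): the
marker's reference-normalized signal in the opposite preparation, as a
percent of its home-preparation signal, is the cross-signal, and
specificity = 100 − cross-signal%. A cross-signal above 100% contradicts
marker specificity and is rejected as an assay failure. On synthetic
mixed preparations, contaminating fraction f of foreign RNA yields
cross-signal ≈ 100·f, so the estimator inverts the contamination
correctly.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes,
with known ground truth:

| parameter | default | rationale |
|---|---|---|
| n_genes | 5,657 | genome-scale array of the motivating study design |
| n_replicates | 3 | triplicate biological replicates per sample type |
| mix_a / mix_b | 0.92 / 0.08 | vegetative/heterocyst filament shares |
| lognormal meanlog/sdlog | 6.0 / 1.3 | right-skewed signals, median ~400 SIU, spanning the ~50–60,000 SIU range |
| noise_cv | 0.10 | multiplicative replicate noise; gives replicate R² in the observed 0.86–0.998 band |
| background_floor / ceiling | 50 / 60,000 SIU | detection floor; saturation at the top of the very-high bin |
| de_fraction, de_log2fc_range | 0.30, (2, 5) | ~30% of genes ≥4-fold different between cell types, consistent with ~21% of retained genes exceeding 2-fold at p<0.01 in the motivating data |
| degraded_gene_count, degradation_factor | 10, 0.1 | ten transcripts reduced to 10% in isolated-heterocyst samples |
| degraded_log2fc_range | (4.5, 6.5) | degraded transcripts are heterocyst-specific; heterocyst signals ~10× the filament signal imply true Ht/V ratios near 2^5.5 |

Mechanics, in order: a lognormal baseline gives each gene's expression in
both cell types; degraded genes get a strong heterocyst-specific effect;
planted DE genes get effects split evenly between cell types (keeping
global normalization plausible); filament expectations are formed as
a·V + b·Ht **before** degradation, and the heterocyst sample expectation
is scaled by δ **after** mixing — so filaments keep the true heterocyst
contribution, which is precisely the discrepancy the weighted residual
detects; replicates then apply unit-mean lognormal noise
(σ² = ln(1+cv²)) and clamp to [floor, ceiling]. All draws come from one
seeded generator; identical parameters and seed give byte-identical
output.

Degraded genes being heterocyst-upregulated is a modeling commitment, not
a convenience: a transcript expressed equally in both cell types loses
almost nothing detectable when its heterocyst copy degrades (the
heterocyst term contributes only b ≈ 0.08 of the filament signal), so the
degradation phenomenon is intrinsically a heterocyst-specific-transcript
phenomenon.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data:

* probe-level structure (17 probes × 4 spots per gene), scanner physics,
  spatial artifacts, batch effects;
* between-condition biological differences: conditions in a multi-
  condition simulation share the same latent cell-type profiles and
  differ only in noise realization;
* shared biological variation between same-culture samples (each sample's
  noise is independent);
* the raw-scale Pearson correlation between V and Ht samples runs lower
  in synthetic data than the 0.40–0.87 observed in real data, because
  planted DE effects reach the high-abundance tail that dominates
  raw-scale correlation; replicate-level correlations do match the
  observed band.

## Numerical and degenerate-input choices

* Mixing fit: collinear V/Ht → explicit singular-fit error; fewer than
  3 genes → error. Grid SSE is clamped at 0 against roundoff.
* Weighted residuals: zero-norm genes excluded with a warning; the
  identity r·‖·‖ + f_calc = f_mean holds to machine precision.
* Quantile normalization: requires ≥2 columns; tie blocks found on the
  stably-sorted column so equal values always share one output value.
* classify_bin: negative input rejected; the scale is a total monotone
  step function on [0, ∞).
* TSV I/O uses round-trip float parsing so write→read→write is
  byte-identical.
* Estimated coefficients, CIs and ranks are deterministic given seeds;
  PCA sign is fixed by convention.

## Scale of the validation runs

Simulation-backed checks use deliberately chosen problem sizes: recovery
and degradation-detection replications run 100 seeds at 4,000 genes;
noiseless recovery runs once at the full 5,657; null calibration uses 20
seeds × 5,000 genes; bootstrap coverage is scaled down to 60 datasets ×
200 resamples. These sizes give the replication rates quoted in the tests
stable denominators while keeping the whole suite and the acceptance
script in the tens of seconds.

## Known limitations

* The Welch test's far-tail conservatism at n=3 (above) means "p < 0.01"
  on triplicate data is in truth closer to a 0.5% test.
* The mixing-coefficient estimator inherits variance from replicate noise
  on the most abundant genes; at noise_cv = 0.15 the ±0.02 recovery band
  is met in ~95% of seeds, with â also carrying a small (+0.004) upward
  bias from the noise/abundance interaction.
* The CV-based variability filter is a surrogate definition; with real
  data whose original filter rules are unknown, retained-gene counts will
  reproduce only approximately.
* estimate_specificity presumes the marker is fully specific to its home
  cell type; genuine low-level cross-expression is indistinguishable from
  contamination by design.
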