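# Methods

This note documents the models behind `stemsig`, the design of the synthetic
experiments used to validate them, and the numerical choices that a user may
want to revisit.

## The processing model

### Background correction (normexp)

An observed single-channel spot intensity is modeled as X = S + B with true
signal S ~ Exponential(α) and additive scanner background B ~ Normal(μ, σ²).
Parameters are estimated per array by maximum likelihood on the convolution
density

    f(x) = (1/α) · exp((μ − x)/α + σ²/(2α²)) · Φ((x − μ)/σ − σ/α),

initialized by moments (the third central moment of the convolution is 2α³;
the normal part contributes none). The Nelder–Mead fit falls back to the
moment estimates with a warning if it fails to converge. The corrected value
is the posterior mean

    E[S | X = x] = μₛ + σ·φ(μₛ/σ)/Φ(μₛ/σ),   μₛ = x − μ − σ²/α,

evaluated through `log Φ` for numerical stability; it is strictly positive
and strictly increasing in x, so correction never re-orders spots within an
array.

A constant **offset of 16 intensity units is added before the log2
transform** (`log_offset`). Probes whose intensity sits inside the
background-noise band have exploding variance on the raw log scale; the
offset bounds that variance so the scalar variance prior of the moderated t
remains adequate across the intensity range. During development the
realized false discovery proportion of the full pipeline ran ≈0.061 at a
nominal 0.05 without the offset and ≈0.050 with it; the offset is the
standard remedy for exactly this effect in single-channel array practice.
Set `log_offset: 0` in the config to disable.

### Normalization

* **Within array**: each array's deviation from a per-probe mean
  pseudo-reference is smoothed by lowess (span 0.3, 3 robustifying
  iterations) against the pseudo-reference and subtracted. With two arrays
  this reduces to classic MA-plot lowess up to a factor ½ (each array owns
  half of the M deviation).
* **Between arrays**: average-quantile normalization — rank k in every array
  maps to the mean of the rank-k values across arrays. Ties receive the mean
  of the reference values their ranks span. The operation is idempotent and
  leaves identical columns untouched.
* **Duplicate spots** sharing a probe identifier are averaged last, in
  first-occurrence order.

The order background-correction → log2 → within-array → between-array →
duplicate averaging follows the standard single-channel convention.

A caveat worth knowing: quantile normalization is only
distribution-preserving when each array carries a comparable share of
elevated probes. If regulation is strongly one-sided in a single group, the
forced equality of distributions compresses the true fold changes of the
affected tail. The simulator's default planting is approximately balanced
per array, as real multi-cell-type designs tend to be.

## Differential expression

Per probe, a one-way group-means fit pools the within-group variance s²_g
with d_g = N − k degrees of freedom (every group needs ≥ 2 replicates). The
variance prior (d₀, s₀²) is estimated by moment-matching on z = log s²:
Var(z) in excess of trigamma(d_g/2) identifies trigamma(d₀/2), inverted by
Newton iteration; the mean of z identifies s₀². Zero excess dispersion (or a
fit above 10⁶ df) returns an infinite-d₀ sentinel, under which the moderated
t uses s₀² everywhere and a normal reference distribution. d₀ = 0 is the
no-shrinkage limit and reproduces the ordinary pooled two-sample t exactly.

Benjamini–Hochberg adjustment is applied per contrast by default
(`pool_bh: true` pools all ten contrasts first — the choice is not
empirically distinguishable at these scales but is exposed because both
conventions exist). Calls are U/D/n by the dual cutoff p_adj < 0.05 and
|log₂FC| > 2; `strict_cutoffs: false` switches to ≤ / ≥.

## Signatures

For reference cell type r, the profile keeps every probe with at least one
non-n call against the other groups, with log₂FC oriented r − other. The FC
score sums the log₂FC of the significant comparisons only (n contributes 0);
with five groups it has at most four terms, so ±8 corresponds to a 2-log₂
change against every other cell type.

* **Specific**: call U against every other group (probe level, plus an
  annotated-only gene view).
* **Shared stem**: annotated genes with FC score ≤ −8 in the profile of
  *each* somatic reference (fibroblast and monocytic analogs) — i.e. genes
  strongly depleted in every somatic type relative to the stem-like types.
  The selection is monotone in the threshold and is taken as an
  intersection, not a union.
* **Germ**: annotated genes with FC score ≥ +8 in the germ-cell profile,
  ranked by descending score (ties broken by probe id).

Unannotated probes are retained in all probe-level outputs but excluded from
gene-level signatures.

### A calibration limit of the score threshold

The FC score of a shared-stem gene in a somatic profile is a sum of three
fold changes sharing the somatic reference mean, so its variance is
(9 + 3)·σ²/n rather than the naive 3·2σ²/n. At effect 3 log₂ per contrast
and replicate noise σ = 0.3 (n = 3), the score is ≈ N(−9, 0.6²): about 5% of
genes per somatic profile fall short of the −8 cut, and the intersection
over two somatic profiles recovers ≈ 91–93% of planted genes (measured
0.925, pooled over four simulations) while keeping precision at 1.0. At
σ = 0.2 the same selection recovers ≥ 99%. Users planting weaker effects or
noisier replicates should either lower the score threshold or treat the
shared list as high-precision rather than high-recall.

## Integration ("virtual array")

Gene-level matrices are joined on the intersection of (upper-cased) symbols;
all samples are quantile-normalized to one common reference distribution and
every gene is centered by its per-dataset median, which removes additive
platform/batch offsets exactly while leaving within-dataset group structure
intact. This is deliberately the minimal batch treatment sufficient for
cross-platform clustering of cell types; the function is pluggable if an
empirical-Bayes batch model is preferred. Genes are then ranked by one-way
ANOVA across biological groups (ascending p, ties by descending F, then
symbol — deterministic); the top 1000 (configurable) feed average-linkage
clustering on 1 − Pearson correlation with columns pre-sorted by sample id
for deterministic tie-breaking, exported as newick. PCA is computed by SVD
of the gene-centered matrix; all components are returned and replicate
barycenters are per-group mean scores.

## qPCR quantification

Comparative ΔCt with amplification efficiency fixed at 2: ΔCt subtracts the
reference (housekeeping) gene within each sample, ΔΔCt subtracts the
calibrator group's mean ΔCt, RQ = 2^(−ΔΔCt). The calibrator group's
geometric-mean RQ is exactly 1 per gene regardless of noise, and RQ is
invariant to adding a constant to all Ct values of a sample (the reference
cancels it). Technical replicates are averaged on the Ct scale before ΔCt.
The concordance helper reports the fraction of genes whose qPCR log-fold
sign (group vs calibrator) matches the microarray's.

## The simulator

`generate_experiment` emulates a five-cell-type, three-replicate,
~44k-probe single-channel study: two somatic analogs (CEF, BM2), three
stem-like analogs (cES, PGC, cBC), 57.8% of probes annotated with a symbol,
5% duplicate spots, exponential-signal-plus-normal-background intensities
(α = 800, μ = 100, σ = 15 a.u.) and a smooth per-array quadratic
log-intensity bias of amplitude 0.3 log₂ that within-array lowess can
remove. Planted classes: `specific:<group>` (elevated in one group),
`shared_stem` (equally elevated in all stem analogs), `germ` (elevated in
the germ analog against all four other groups — mirroring the fact that a
germ signature coincides with the germ group's top specific genes), `null`.
Default planted counts (500/650/40/110 specific, 88 shared, 180 germ) echo
the list sizes such a study reports. Default effect size is 3 log₂ and
replicate noise 0.3 log₂ per sample.

Generative choices that matter:

* The per-probe baseline signal is a **single** Exponential(α) draw, so the
  across-probe intensity marginal matches the normexp model and its
  parameter recovery can be tested fairly; replicate noise is lognormal
  (N(0, 0.3) on log₂). Spot-level exponential noise would impose a CV of 1
  per spot, which no 3-replicate design could overcome.
* Planted signature probes draw their baseline from the exponential
  conditioned to exceed α/2 (a memoryless shift): genes living inside the
  background band are unrecoverable by construction, and a study's
  signature genes are by definition robustly expressed.
* A `germ_secondary_level` knob can leak a fraction of the germ effect into
  the blastoderm analog (germ cells are present in early blastoderms); it
  defaults to 0 so planted classes are disjoint in profile space.

`generate_companion_dataset` builds a gene-level "foreign platform" dataset
(mouse-analog) sharing an exact number of symbols with the truth
(planted-class symbols first), with its own groups mapped onto the planted
profiles (default: an ES-analog carrying the shared-stem profile and a
fibroblast-analog at baseline), a +2 log₂ batch offset and independent
noise. `generate_ct_table` converts planted expression into Ct values
(Ct = 30 − log₂ expression + noise) with a reference gene required to be
planted flat across groups.

What the simulator does **not** model: spatial artifacts, dye/labeling
effects, probe cross-hybridization, intensity-dependent replicate variance
beyond the background band, correlated probes within a gene, or annotation
errors. Passing recovery tests therefore demonstrates the pipeline's
statistical correctness under its own assumptions, not robustness to every
failure mode of real arrays.

## Problem sizes used in validation

The test suite validates calibration with 200 replicate two-group
simulations of 2000 probes (10% planted effects, balanced across groups),
signature recovery on four simulations of 6000 probes at the study's
planted-gene density, and the cross-platform clustering property on 50
seeds of a 1200-probe experiment plus companion dataset — sizes chosen so
the full suite runs in minutes while keeping Monte-Carlo error well below
the margins being tested. `scripts/acceptance.py` reruns the calibration
quantities from scratch at the same sizes.
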