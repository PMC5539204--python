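# Methods

This note documents the models and procedures implemented in `mirmint`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter in edge cases.

## Study design assumed

The package targets a two-group, unpaired design: a control group and a
treated/diseased group of equal size (defaults emulate n = 6 animals per
group), with gene expression measured as log2-scale intensities
(array-style, gene-level summaries) and miRNA abundance measured on the Ct
scale (qPCR cards). Group comparisons are between-group throughout; no
paired or blocked modes are provided.

## qPCR quantification

**Efficiency estimation.** Per-well amplification efficiency is estimated
from the exponential phase of the raw fluorescence trace. "Above baseline"
means fluorescence exceeding `baseline_factor` (default 3) times the median
of the first `baseline_cycles` (default 5) cycles — a robust threshold that
ignores early-cycle noise. Among all windows of `window_width` (default 5)
consecutive above-baseline cycles, the linear regression of
log10(fluorescence) on cycle with positive slope and maximal R² is chosen
and E = 10^slope. An estimate whose best window misses `min_r2` (default
0.99) is returned flagged as failed but with full diagnostics; a curve with
no positive-slope window (e.g. entirely at plateau) raises a "no
exponential phase" error. Estimates above the physical maximum E = 2 are
reported as computed and flagged, never clamped: silent clamping would hide
evaporation/pipetting artifacts from QC.

**geNorm stability.** Ct values are converted to relative quantities
q = E^(Ct_min − Ct) per target (E defaults to 2). For candidates j, k the
pairwise variation V_jk is the standard deviation (ddof = 1) across samples
of log2(q_j/q_k); M_j is the mean of V_jk over k ≠ j. The least stable
candidate (highest M, ties broken by lexicographic id so rankings are
deterministic) is removed and M recomputed until two remain; the final pair
is ordered by its last-round M. V(n/n+1) is the standard deviation across
samples of the difference between log2 normalization factors (geometric
means of quantities) built from the n versus n+1 most stable candidates.
Because M is built entirely from within-sample ratios, adding a constant to
all Cts of one sample (loading variation) leaves it invariant — this is the
property that makes geNorm suitable for reference selection and it is
tested directly.

**Relative expression.** The efficiency-corrected comparative-quantification
ratio uses group-mean ΔCt (mean control Ct minus mean treated Ct), matching
the unpaired design: ratio = E_t^ΔCt_t / NF with NF the geometric mean of
E_r^ΔCt_r over the reference set. With all E = 2 this reduces to the
classic 2^−ΔΔCt value. An empty reference set is an error — unnormalized
ratios are not meaningful for this data type. Efficiencies default to 2
when curves are not supplied; when they are, per-target estimates can be
passed in (both modes exist because protocols differ on this point).

**Randomization test.** Significance of a ratio is assessed by fixed
reallocation: group labels are randomly reshuffled with group sizes held
fixed and the log2 ratio recomputed; the two-sided p-value is
(#{|log2 r_perm| ≥ |log2 r_obs|} + 1)/(N + 1) with N = 10,000 permutations
by default. The +1 correction keeps p strictly positive (the observed
allocation is always a valid reallocation). A structural consequence worth
knowing: at n = 6 + 6 the identity and complement reallocations always tie
the observed |statistic|, so the two-sided p can never fall below
2/C(12,6) ≈ 0.0022 in expectation — strong effects saturate near that
floor rather than reaching arbitrarily small values. Under the null the
test is calibrated (type-I error ≈ 0.05 at α = 0.05, checked by
simulation) and slightly conservative, as permutation tests with the +1
convention are.

**Mann–Whitney.** For min(n_a, n_b) ≤ 8 the two-sided p-value is exact:
all C(n_a+n_b, n_a) label assignments of the observed pooled values are
enumerated, U computed from mid-ranks, and p is the fraction of assignments
with |U − n_a n_b/2| at least the observed deviation. Ties therefore need
no continuity correction — the enumeration is over the observed data as it
stands. Larger groups use the tie-corrected normal approximation (scipy,
no continuity correction).

## Differential expression

**Quantile normalization** maps every column onto the across-column mean of
sorted values; ties receive the average of the reference values at the tied
rank positions (implemented by interpolating average ranks into the sorted
reference), which makes the operation idempotent. Probe-level background
correction is out of scope: the package consumes gene-level signal, so
quantile normalization is the matrix-level stand-in for array preprocessing.

**Moderated t.** Per-feature pooled variances s²_g on d = n₁ + n₂ − 2 df
are shrunk toward a prior fitted by moment matching: with
e_g = log s²_g − ψ(d/2) + log(d/2), the prior df solves
ψ′(d₀/2) = var(e) − ψ′(d/2) via a Newton inverse of the trigamma function,
and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the observed spread of
log-variances does not exceed what sampling alone implies, d₀ = ∞ and the
scale is the arithmetic mean of the s²_g (all features share one variance).
The moderated t uses the posterior variance on d₀ + d df. The
implementation is cross-checked in the test suite against the reference
empirical-Bayes implementation in Bioconductor (agreement to ~1e-8 on both
branches) and reduces exactly to the ordinary two-sample t at d₀ = 0.
Zero-variance features are handled through the prior; in the fully
degenerate zero-noise limit (all variances 0) a feature gets p = 0 when its
fold change is nonzero and p = 1 otherwise, so planted effects are still
recovered without division errors.

**DE calling.** Fold change is linear-scale with sign from
(treated − control) means; defaults fold ≥ 1.5 and raw p ≤ 0.05. Raw-p
filtering is the default because printed array-study cutoffs are usually
raw; BH-adjusted filtering is one flag away, and both cutoffs are config
presets (0.05 and the stricter 0.01 variant both appear in practice for
this kind of study; the package asserts neither as "correct"). Note that
raw-p calling at these settings admits false positives by construction —
the worked example in the README shows 230 calls against 150 planted — and
downstream stages are designed to tolerate that (see integration).

## Target integration

The candidate universe is the union of all evidence rows; a pair is
retained when ≥ `min_algorithms` (default 4) *distinct prediction
algorithms* report it, or when any curated validated-target row exists
(`accept_validated`, default on — validated evidence is treated as
sufficient on its own; the contribution of validated-only pairs is
reported separately in the stats so the choice is auditable). Duplicate
rows collapse to the distinct-algorithm count and the validated flag is
sticky.

Edges are then restricted by the anti-correlation rule: miRNA → gene is
kept only when both features are differentially expressed with opposite
direction labels. Direction labels (not per-sample correlation
coefficients) implement the rule because the pipeline pairs DE lists, not
sample-matched profiles. A feature appearing in both the up and down list
is a hard error — silent resolution would corrupt every downstream count.
Candidates referencing features that are not DE at all are skipped with a
logged count.

This two-stage filter is why the pipeline is robust to liberal DE calling:
a false edge requires a false pair to reach 4-algorithm support
(probability ≈ C(5,4)·fpr⁴ per pair at the default per-algorithm false
positive rate 0.005 — about 3e-9) *and* both endpoints to be falsely
called DE in opposite directions. In the 20-seed recovery study the
recovered-edge precision is consistently ≈ 1.0.

miRNA–miRNA overlap is the Jaccard coefficient of target sets; JC = 0
pairs are omitted. Topology statistics report interaction counts, degree
distributions, the fraction of miRNAs with ≥ k targets (default k = 2) and
genes co-regulated by ≥ m miRNAs (default m = 3). An optional user-supplied
PPI table adds gene–gene annotation edges as a distinct edge class without
touching regulatory semantics.

## Enrichment

Over-representation uses the upper-tail hypergeometric p = P(X ≥ k) with
the universe defaulting to all measured features (array studies should test
against what was measurable, not the genome), BH adjustment across tested
terms, and a minimum-overlap filter (default 1) for which terms are tested
at all. Enriched terms (default p ≤ 0.001) are related by Cohen's kappa on
membership indicator vectors over the universe; pe = 1 degeneracies are
reported as kappa 0. Clusters are connected components of the
kappa ≥ threshold (default 0.3) graph — the simplest procedure consistent
with kappa-threshold functional grouping; hierarchical refinements were
considered and deferred since component membership is what downstream
reporting uses. Each cluster is represented by its lowest-p term.

## Synthetic data: what it emulates and what it does not

The generator plants a complete, internally consistent ground truth:
Gaussian log2 intensities with homoscedastic noise (baseline Uniform(6,12)
for genes, Uniform(4,10) for miRNAs), a planted ±`effect_log2fc` group
effect on a fraction of features, true edges joining DE miRNAs to
oppositely-directed DE genes (`targets_per_mirna` each), per-algorithm
Bernoulli prediction tables (sensitivity for true pairs, a small false
positive rate for all others), two validated databases modeled as noiseless
subsets of the true edges (curated databases are treated as ground truth),
gene sets with a controllable fraction of members drawn from DE genes,
noiseless-or-lognormal amplification curves with known efficiency, and a
16-candidate reference panel with 3 planted stable members (stable Ct SD
0.2 cycles, unstable 1.0, on top of a shared per-sample shift of SD 0.5 —
values chosen once as representative of real reference-panel behavior).

Default design: 2,000 genes and 120 miRNAs (the measured panels of this
kind of study scaled down roughly 8× and 3× to keep runs fast), 7.5% DE
genes and 5% DE miRNAs, |log2FC| 1.5, noise SD 0.5, n = 6 per group,
7 evidence sources (5 prediction algorithms + 2 validated databases),
sensitivity 0.9 and false positive rate 0.005 per algorithm.

Deliberately not emulated: probe-level artifacts, spatial/batch effects,
heteroscedastic (intensity-dependent) noise, Ct machine quirks,
miRNA-induced changes in target mRNA levels (planted gene effects are
assigned, not propagated through edges). Passing tests on this data
therefore demonstrate correctness of the statistical machinery and the
integration logic under the stated model — not robustness to array
artifacts or to correlation structure the generator does not produce.

All randomness descends from one seed: `SeedSequence(seed, spawn_key=(k,))`
with k = 0 expression, 1 predictions, 2 gene sets, 3 curves, 4 reference
panel, so each generator is reproducible in isolation. `noise_sd = 0` is
explicitly allowed as the exact zero-noise limit used in recovery tests.

## Pipeline conventions

Tabular I/O is strict TSV (UTF-8, header row, '.' decimal, no CSV
sniffing); malformed rows fail with file and line number. miRNA abundance
travels to the quantification stage on the Ct scale via Ct = 30 − log2
signal (one cycle per doubling); candidate reference small RNAs are
generated as stable features, geNorm-ranked inside the pipeline, and the
top `n_references` (default 4) form the normalization set. The run report
echoes every threshold exactly as configured and records counts in and out
of every filter, so a run is auditable without re-reading logs. With a
fixed seed the pipeline is a pure function of (config, inputs) — two runs
produce byte-identical stage outputs.

## Problem sizes used in validation

The recovery studies run the full pipeline at the default design (2,000
genes × 12 samples, 120 miRNAs) with 2,000 randomization permutations per
miRNA; the null-calibration study uses 1,000 simulated datasets × 2,000
permutations; geNorm recovery uses 100 panels; the DE recovery study uses
1,000 features at n = 3 + 3 over 20 seeds. These sizes give stable Monte
Carlo estimates (binomial SE ≲ 0.007 on the calibration rate) while keeping
the whole suite around a minute.

## Known limitations

- Unpaired two-group designs only; no covariates, batches or paired modes.
- The moderated t assumes homoscedastic Gaussian log-intensities per
  feature; no intensity trend (limma-trend style) is fitted.
- The randomization test's two-sided p has the 2/C(n₁+n₂, n₁) floor noted
  above; with 6 + 6 samples it cannot certify significance below ~0.002.
- Direction-label anti-correlation cannot distinguish direct regulation
  from co-membership in a regulated program; it is a filter, not causal
  inference.
- Component clustering of enriched terms merges chains transitively; two
  dissimilar terms can share a cluster through intermediates.
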