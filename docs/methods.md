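# Methods

## Scope and model of the data

`refstab` operates on three data objects: a gene × sample TPM matrix whose
samples are biological replicates nested in conditions (developmental
stages, tissues or stress timepoints), a gene × sample Ct matrix from a
small RT-qPCR panel (optionally with sample groups), and paired
(log2 TPM, Ct) observations. All expression analysis happens on the
log2(TPM) scale; all qPCR analysis on the Ct scale or on relative
quantities Q = E^(minCt − Ct) derived from it.

## CV screening

Replicates are averaged on the TPM scale (arithmetic mean per condition,
before the log), so the unit of variation for screening is the condition.
Per gene, across conditions: μ = mean log2(TPM), SD = sample standard
deviation (n−1 denominator, the spreadsheet convention), CV = SD/μ. A gene
is a candidate iff

- μ > `min_mean_log2tpm` (default 5 — at or below the cut-off is excluded,
  since genes that weak amplify poorly in qPCR),
- SD < `max_sd_log2tpm` (default 1),
- CV < `max_cv` (default 0.2),

all strict. The first failing filter, in the order low_expression → high_sd
→ high_cv, is recorded per gene. Genes with any non-positive TPM after
replicate averaging are excluded as `nonpositive_tpm` before statistics are
computed: a reference gene must be detectably expressed everywhere, and a
pseudocount would distort CV exactly in the region the cut-offs probe.
Candidates are ordered by ascending CV with lexicographic gene-id
tie-break. Percentages in text output are printed to two decimals.
Candidate sets from 2–3 datasets can be intersected; both exclusive Venn
regions and plain overlap counts are reported, defined by exact gene-id
membership.

## Stability statistics

**Quantity conversion.** Q[g,s] = E^(minCt_g − Ct[g,s]) with amplification
efficiency E defaulting to 2.0 (perfect doubling; no per-primer
efficiencies are modelled, a flag overrides). Each gene is calibrated to
its own minimum Ct, so max Q = 1 per gene; every statistic downstream is
invariant to that per-gene calibration.

**geNorm.** M_j is the mean over partners k ≠ j of SD_samples(log2 Q_j/Q_k).
The highest-M gene is removed and M recomputed until two genes remain; ties
during exclusion remove the lexicographically larger id. The final two
genes are reported with tied ranks 1.5/1.5 (the method cannot order them;
average ranks keep the geometric-mean aggregation well defined), earlier
exclusions get ranks 3, 4, …, G. Pairwise variation
V(n→n+1) = SD_samples(log2 NF_n/NF_{n+1}), where NF_n is the per-sample
geometric mean of the n most stable genes, is reported for n = 2…G−1 but no
"enough genes" decision is made from it.

**NormFinder.** Data are mapped to the log2-quantity scale as −Ct·log2(E).
Ungrouped mode is the simple measure: per gene, the SD of sample-centered
values, with a gene-count bias correction — centering leaks 2/n of a gene's
own variance plus 1/n² of the panel total into its residuals, so the moment
equations are solved for unbiased σ̂² (clipped at 0). Grouped mode (≥2
groups, each ≥2 samples) fits the variance decomposition per group: doubly
centered residuals give σ̂²_ig with the same gene-count correction;
intergroup deviations d_ig (the gene × group interaction of group means,
summing to zero over genes and over groups) are shrunk by
γ̂²/(γ̂² + σ̂²_ig/n_g), where γ̂² is the method-of-moments estimate of the
intergroup variance over the (n−1)(G−1) interaction degrees of freedom. The
stability value is

ρ_i = mean over groups of ( |d̃_ig| + √(σ̂²_ig/n_g) ),

i.e. shrunken intergroup deviation plus the intragroup variation's
contribution to the group-mean uncertainty. Circulating implementations of
the grouped model differ in that second term; the posterior-SD variant
collapses to ρ ≡ 0 whenever γ̂² = 0 (e.g. balanced designs with no real
group differences), losing all ranking information, so this package uses
the group-mean SE, which degrades gracefully to a pure intragroup measure.

**BestKeeper.** Per gene: arithmetic and geometric mean, min, max, SD and
CV% = 100·SD/mean of raw Ct; the BestKeeper index is the per-sample
geometric mean of Ct over the panel; each gene's Pearson r against the
index comes with the two-sided p from the t-distribution (n−2 df). Ranking
uses ascending SD(Ct) — the dispersion statistic — with SD > 1 cycle
flagged "inconsistent"; r is reported but not ranked on. A zero-variance
gene has undefined r (reported missing) and ranks first by SD.

**ΔCt method.** For gene j, the score is the mean over partners k of
SD_samples(Ct_j − Ct_k); the full symmetric pairwise-SD table is retained.

**Missing Ct.** geNorm/NormFinder/BestKeeper drop genes with missing wells
(complete-case, warned); ΔCt uses pairwise complete-case per gene pair. No
imputation — panels are too small to verify one.

## Comprehensive ranking

Each method contributes a rank vector (1 = most stable; average ranks for
within-method ties). Per gene, GM = (r₁r₂r₃r₄)^{1/4}; genes are ordered by
ascending GM, ties broken by the ΔCt rank then gene id for determinism.
Rank positions are aggregated, not raw scores: the four statistics live on
incommensurable scales, and rank aggregation (the RefFinder convention) is
the established way to combine them. All four methods must cover the same
gene set; a mismatch is an error naming the symmetric difference.

## TPM → Ct calibration

Ordinary least squares of Ct on log2(TPM): slope β₁, intercept β₀,
R² = 1 − SS_res/SS_tot, and the slope's F(1, n−2) p-value (identical to the
two-sided t-test in simple regression — the "ANOVA of regression"). At
least 3 points and non-constant x are required. Prediction is
β₀ + β₁·log2(TPM), defined for TPM > 0 only. One global fit is made across
genes and samples; no gene-wise calibration curves.

## Synthetic data

The generator emulates the multi-condition bulk RNA-seq designs the
screening stage consumes. Defaults: 2000 genes, 9 conditions × 3 replicates
(a developmental series of nine stages with triplicate sampling — also the
problem sizes used throughout the test suite), 10% stable genes, baseline
μ ~ U(6, 18) log2 units, stable per-condition SD ∈ (0.01, 0.15), unstable
SD ∈ (1.2, 3.0), replicate noise SD 0.1 log2 units.

Per-condition values are Gaussian draws recentered and rescaled so the
realized condition-level mean and SD equal the drawn parameters exactly
(variance targeting). This is deliberate: the truth label then describes
what the gene's log2 profile actually does, and the screening outcome is
guaranteed by construction — with raw Normal draws, about 5% of genes with
generating SD in (1.2, 3) would realize a sample SD below 1 across nine
conditions and legitimately pass the filters, making "unstable" labels
partly false. Replicate noise is added after targeting, so realized SDs
wobble by ~√(0.1²/3) — negligible against both cut-offs.

Ct panels are generated from the single global line
Ct = −0.5405·log2(TPM) + 34.51 (the only TPM–Ct link quantified for these
data) plus independent cycle noise. The default noise SD of 2.5 cycles
represents cross-gene, cross-sample scatter and puts the refitted R² in the
weak-correlation regime (≈0.36 with x ~ U(6,18); a tuning choice, not a
measured value); within-panel simulations for stability testing instead use
0.2 cycles, a typical qPCR technical SD, passed explicitly. Optional
per-gene, per-group Ct shifts create intergroup structure for grouped
NormFinder. All randomness flows from one integer seed through a single
`numpy.random.Generator`.

What the generator does **not** emulate: count noise and sequencing depth
(TPM is drawn directly), correlated gene programs, batch effects,
condition-autocorrelated trajectories, or gene-specific amplification
efficiencies. Passing the end-to-end tests therefore shows the statistics
and their wiring are correct under log-normal dispersion with a known
stable fraction — not that the default cut-offs are optimal for any real
organism.

## Numerical choices and degenerate inputs

- Sample SD (ddof = 1) everywhere a dispersion across samples/conditions is
  taken.
- CV for a gene with μ = 0 is undefined (NaN); such genes always fail the
  expression filter first.
- geNorm requires ≥3 genes and ≥2 samples; NormFinder ≥3 genes (≥3 samples
  ungrouped, ≥2 per group grouped); BestKeeper ≥2 genes, ≥3 samples and
  Ct > 0; ΔCt ≥2 genes. Violations are errors, not warnings.
- σ̂² estimates clipped at 0; γ̂² floored at 0; shrinkage factor set to 0
  when both signal and noise are zero.
- Ct outside (0, 45) warns but is kept; unparseable cells are errors with
  row/column coordinates.
- Table writers emit 6 significant digits for result tables and full
  precision (17 significant digits) for data matrices, so data round-trips
  are bit-exact.
- Tie-breaks are lexicographic on gene id wherever a method is silent, for
  reproducibility.

## Known limitations

- The CV screen's exact candidate counts on real datasets depend on how
  zero-TPM genes are treated upstream; the no-pseudocount exclusion policy
  here is one defensible choice among several.
- BestKeeper's original tool ranks by mean absolute deviation of Ct; this
  package uses SD(Ct). Orderings can differ on skewed panels.
- geNorm cannot order its final pair; downstream aggregation sees both at
  rank 1.5.
- The calibration model is a single global line; it intentionally ignores
  gene-specific amplification behaviour, so per-gene Ct predictions carry
  the full scatter seen in the fit's R².
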