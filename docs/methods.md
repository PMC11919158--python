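# Methods

## Problem and scope

`varcalib` evaluates how well in-silico missense pathogenicity predictors —
an ensemble score bounded on [0, 1] (REVEL-like) and a Phred-scaled
deleteriousness rank score (CADD-like) — identify disease-causing variants
within a fixed panel of disease-associated genes, using case–control
sequencing cohorts annotated against a clinical variant archive (ClinVar-style
classifications).  The package implements the full evaluation chain:

1. **Classification and filtering.**  Raw consequence terms are reclassified
   into protein-truncating (PTV: splice donor/acceptor, frameshift,
   stop-gained, start-loss, stop-loss), missense, and synonymous; any other
   coding term raises rather than being coerced, so annotation problems stay
   visible.  Archive classifications are binned six ways (B/LB, conflicting,
   VUS, P/LP, absent, other).  Analyses keep PTV and missense variants that
   are rare in the reference population (allele frequency < 0.01, strict; a
   missing frequency counts as rare, since absence from a large reference
   cohort is itself strong rarity evidence and novel variants must survive
   the filter).
2. **Threshold calibration** on the binary truth set of missense variants
   classified B/LB (negative) vs P/LP (positive).
3. **Enrichment** of uncertain ("VUS-like" = VUS + conflicting + absent)
   variants above the predetermined thresholds in cases vs controls.
4. **Per-variant effect measures** and their correlation with scores.
5. **Supporting-pathogenic yield** under ordered decision rules.

Two counting conventions run through the analyses: **unique** variants
(each distinct variant counted once per cohort where observed) and
**observed** variants (each variant weighted by its cohort allele count).
Enrichment and yield default to observed counts — the convention that gives
per-cohort multiplicity — while calibration uses unique variants (a
frequency-weight option exists but defaults off).  Whether the emulated
study weighted by alleles or carriers is not derivable from its text; the
allele-count convention is documented here as this package's choice.

## Calibration statistics

All calibration statistics are computed from first principles and share one
classification rule: *predict pathogenic iff score ≥ threshold*.

**Logistic model.**  log-odds(P/LP) = β₀ + β₁·score, fitted by
iteratively reweighted least squares; convergence when the log-likelihood
changes by < 1e-10, cap 100 iterations.  Complete separation (disjoint
class score ranges — a monotone likelihood) is detected up front and
returned as a flagged fit whose linear predictor spans ±30 across the
observed score range, centred on the class boundary midpoint, instead of
divergent coefficients.

**ROC / AUC.**  The empirical curve has one operating point per distinct
score (ties share a point; no interpolation within ties) plus the (0, 0)
corner.  Reported cut-points are midpoints of the half-open score interval
realising each operating point (±∞ at the corners): any threshold in
(s₂, s₁] produces the same confusion counts, and the midpoint is a
representative interior value.  AUC is the trapezoidal area, which equals
the concordant-pair fraction with half-credit for ties.

**Youden index.**  J = max over thresholds of (TPR − FPR); ties break
toward the larger (more specific) threshold.

**Kolmogorov–Smirnov.**  Class-conditional empirical CDFs use the ≤
convention; the statistic is the *signed* maximum of ECDF_neg − ECDF_pos
(benign-class CDF minus pathogenic-class CDF).  Under the shared
conventions this equals the maximum Youden index of the same data — and the
package guarantees the identity *bit-for-bit* by computing both from the
same integer cumulative counts, as (cn·n_pos − cp·n_neg)/(n_neg·n_pos).
The p-value is the classical asymptotic Kolmogorov series
Q(λ) = 2·Σ (−1)^{k−1} e^{−2k²λ²} at λ = √(mn/(m+n))·D, evaluated
in-package.  (Modern SciPy's two-sample test instead evaluates the
one-sample Kolmogorov distribution at an effective sample size; the two
conventions differ by a few tens of percent at moderate n, which is
immaterial for the saturated p-values this analysis produces.)

**Confusion metrics.**  Accuracy, sensitivity, specificity, PPV and NPV are
derived from the 2×2 counts at a threshold; any rate with a zero
denominator is returned as an explicit `None`, never 0 or silent NaN.

## Association statistics

**Rank-sum and correlation.**  Score distributions per ClinVar class are
compared with the Wilcoxon rank-sum (Mann–Whitney) test — exact by
enumeration when the combined n ≤ 12 and tie-free, otherwise the normal
approximation with tie and continuity corrections — and score agreement
with Pearson's product-moment correlation (p from the t transform with
n − 2 df).  Both delegate to SciPy.  The rank test is reported alongside,
not conflated with, group means.

**Fisher's exact test.**  Two-sided, conditioning on both margins: the p
sums hypergeometric probabilities of all tables whose point probability is
≤ that of the observed table, within a relative tolerance of 1e-7
(minimum-likelihood convention).  Tables with total ≤ 500 use exact integer
binomial weights with the tolerance applied in integer arithmetic; larger
tables use log-space hypergeometric probabilities with log-sum-exp.

**Cochran–Mantel–Haenszel.**  Common OR by the Mantel–Haenszel estimator
Σ(aᵢdᵢ/Nᵢ)/Σ(bᵢcᵢ/Nᵢ); chi-square without continuity correction; 95% CI
from the Robins–Breslow–Greenland variance of the log common OR.  Strata
with a zero row or column margin contribute no information and are skipped
with a log entry.  Enrichment p-values are Bonferroni-adjusted with m =
the number of raw tests computed in the enrichment stage.

**Score-bin boundary.**  The decision rule is score ≥ 0.644 (REVEL) /
≥ 20.0 (CADD); printed bin labels like "0.000–0.643" are treated as the
rule, not as a gap, so values in (0.643, 0.644) fall below.  The
descriptive three-way bins split additionally at 0.183 (REVEL) and 10.0
(CADD), lower-inclusive.

**Two-bin caveat.**  With exactly two complementary score bins, the
below-threshold 2×2 table is the column-swapped above-threshold table, so
its odds ratio is exactly the reciprocal of the above-bin OR.  Published
analyses of this design sometimes print a below-bin OR that is *not* the
reciprocal, implying a different implicit denominator; this package
implements the explicit complementary-table definition.

**Per-variant measures.**  The allele odds ratio follows its source
formulation literally, with persons-minus-allele-count denominators:
OR = (caseAC/(n_cases − caseAC)) / (controlAC/(n_controls − controlAC)).
The unit mixture (alleles in numerators, persons in denominators) is noted
rather than silently corrected; counts reaching the person count raise.  A
zero control count makes the OR undefined (`None`); an optional Haldane
0.5 correction exists but defaults off, and undefined ORs are excluded from
correlations.  The carrier ratio is affected/(affected + reference)
carriers, defined only for variants seen in ≥ 1 affected individual.
Before correlating scores with odds ratios, values beyond k = 3 sample
standard deviations (n − 1 denominator) of the mean are trimmed in a single
pass.

## Supporting-pathogenic yield

Ordered, mutually exclusive rules over filtered records: P/LP → supporting;
uncertain-class PTV → supporting; uncertain-class missense with score ≥
threshold → supporting; archive-absent PTV → supporting; archive-absent
missense with score ≥ threshold → supporting; anything else (including all
B/LB and "other" records) → not supporting.  "Uncertain class" includes
conflicting interpretations, harmonising the yield rules with the
enrichment analysis's VUS definition; the run manifest records the rule
version.  Missense records missing the tool's score map to a distinct
unknown-score outcome so annotation gaps are counted, not hidden.  Yield
counts are allele-weighted per gene and cohort.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume — it
is the package's test bed, not a population-genetics simulator.

* **Defaults are the study conditions.**  Two strata: a whole-exome-like
  cohort (3,864 cases / 7,839 controls, 1,395 variants) and a
  whole-genome-like cohort (4,366 / 1,832, 1,149 variants) over a 20-gene
  panel with size-weighted variant allocation.  Class mixture over unique
  variants: 22% B/LB, 5% conflicting, 20% VUS, 3% P/LP, 48% absent, 2%
  other.  Consequences: 10% PTV, 15% synonymous, 75% missense.
* **Scores.**  Bounded scores are Beta-distributed per class with total
  concentration 4 and means 0.237 (B/LB), 0.304 (conflicting), 0.319 (VUS
  and absent), 0.713 (P/LP); Phred-like scores are Gamma with shape 8 and
  means 18.65 / 19.03 / 20.97 / 24.46 respectively.  The means mirror the
  emulated study's per-class means; concentrations are chosen once as
  realistic spread.  A truncated-normal family is available when an
  analytic class-pair AUC (Φ(Δμ/√(σ₁²+σ₂²))) is wanted for validation.
* **Frequencies and counts.**  Population AF = max_af·Beta(0.5, 4) with
  max_af = 0.0099 (everything survives the 0.01 rarity filter) and a 25%
  archive-absent missing mass; reference allele counts derive from a
  51,592-person reference.  Per-variant total allele counts are
  1 + Poisson(2.9), matching an observed/unique ratio of roughly four.
* **Enrichment.**  Each allele is assigned to the case cohort independently
  with probability p = OR·p₀/(1 − p₀ + OR·p₀), p₀ = n_cases/(n_cases +
  n_controls), where OR is the designed odds ratio (default 1.378) for
  uncertain-class missense variants at/above the designed threshold
  (REVEL 0.644) and 1 otherwise.  This makes the designed OR directly
  interpretable as the allele odds ratio the analyses estimate.
* **Not emulated:** linkage, site-frequency spectra, genotype matrices,
  carrier vs allele distinction (homozygotes), per-gene score structure,
  reference-population substructure, or correlated scores between tools
  beyond shared class labels.  Passing tests therefore demonstrate the
  *statistical machinery* is correct under the designed model, not that the
  predictors behave this way on real cohorts.

Generation is deterministic given the seed (a separate stream per
stratum), and infeasible configurations (allele counts exceeding twice a
cohort size) raise at generation time.

## Validation summary

The test suite verifies, among others: the KS–Youden identity bit-for-bit
on 1,000 random score sets; trapezoidal AUC against a concordant-pair
oracle; Fisher's two-sided p against an exhaustive independent enumeration
for **every** 2×2 table with N ≤ 40 (< 1e-12 agreement) and against an
exact-rational oracle on random tables; the CMH estimator, statistic and
RBG interval against `statsmodels.StratifiedTable`; IRLS against a
reference GLM fit; and, on synthetic cohorts (2,000 variants per stratum),
null type-I error of the CMH test in [0.03, 0.07] over 400 seeds, mean
common-OR recovery within 10% with ≥ 90% CI coverage over 200 seeds for
designed ORs 1.0/1.5/2.0, and recovery of logistic coefficients
(−7.474, 11.192) within 5% at n = 50,000.  These problem sizes are the
package's validation conditions; larger runs scale linearly.

## Pipeline determinism

`run_pipeline` is a pure function of (inputs, configuration): reports are
byte-identical across reruns, floats are rounded to 6 significant digits at
serialisation only, and every stage logs rows_in = rows_out + rows_dropped
so conservation is machine-checkable from the manifest.

## Known limitations

* The enrichment below-threshold result is the exact reciprocal of the
  above-threshold result by construction (two complementary bins).
* Exact (network-algorithm) CMH p-values, ROC confidence bands,
  cross-validated threshold selection, covariate adjustment and full ACMG
  classification are out of scope.
* The carrier ratio uses allele counts as a carrier proxy (no homozygote
  accounting), consistent with the generator's allele-level model.
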