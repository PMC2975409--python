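# Methods

## Problem and overall procedure

The package implements a panel-biomarker discovery analysis for case/control
plasma proteomics. Starting from a wide peptide-level intensity table with a
two-group sample annotation, the analysis proceeds:

1. **Quantification** — log2 transform, quantile normalization across
   samples, and rollup of peptides to one protein intensity per sample
   (weighted average of the protein's peptides).
2. **Differential testing** — a per-protein two-sample statistic with a
   permutation p-value: the proportion of group relabelings whose statistic
   is at least as extreme in absolute value as the observed one.
3. **Selection and multiplicity** — significance at a fixed per-test level
   α, summarized by the per-family Type 1 error rate `PFER = n_tested × α`
   and the nominal `FDR = PFER / n_declared`.
4. **Panel derivation** — intersection of the significant set with
   user-supplied reference biomarker sets; Venn counts across studies.
5. **Pathway matrices** — binary pathway×protein association matrix; the
   pathway-protein frequency count matrix (PPFCM) whose cell
   (pathway, study) counts the study's panel members in that pathway;
   per-pathway one-sided Fisher's exact over-representation tests.
6. **Cross-study similarity** — the *protein method*
   (Jaccard: |∩|/|∪|) and the *pathway-matrix method* (Pearson correlation
   of two studies' PPFCM columns).

Permutation testing is motivated by the distributional diagnostic in step 1:
pooled log2 peptide intensities fail a one-sample Kolmogorov–Smirnov
normality test, so a parametric t-test's normality assumption is not
supportable and inference is taken from the permutation distribution
instead.

## The permutation test

The default statistic is the pooled-variance two-sample t (case minus
control, so positive = over-expressed in cases); Welch t and the plain mean
difference are selectable. Relabelings are either

* **exhaustive** — all `C(n, n_case)` distinct assignments of samples to the
  case group, or
* **Monte-Carlo** — `n_perm` independent uniformly random assignments
  (assignments may repeat), seeded;

`auto` picks exhaustive whenever the full enumeration is no larger than the
requested Monte-Carlo count. The p-value is the plain proportion of
relabelings with `|T_perm| ≥ |T_obs|`.

Numerical and edge-case choices:

* **Exceedance rule.** The ≥ ("at least as extreme") comparison is the
  default: under a strict `>` a constant protein would get p = 0, which is
  not a valid permutation p-value. A `strict=True` flag implements the
  strict comparison, and `add_one=True` gives the (b+1)/(B+1) smoothed
  estimator; the plain proportion is the default. In exhaustive mode the
  identity assignment guarantees p ≥ 1/C(n, n_case); in Monte-Carlo mode the
  plain proportion can in principle be 0 when no draw reaches the observed
  statistic.
* **Ties at the observed value.** Relabelings whose statistic is
  mathematically equal to the observed one (the identity assignment, and its
  mirror when group sizes are equal) may be computed a last-ulp away from
  the observed value depending on the evaluation path. Comparisons therefore
  treat values within a relative tolerance of 1e-9 as ties, and exhaustive
  mode counts the identity/mirror assignments analytically. On continuous
  data all other relabelings sit far outside this tolerance, making
  exhaustive p-values exactly equal to an exact-arithmetic enumeration.
* **Degenerate proteins.** A constant protein (zero variance) is tested with
  the mean-difference statistic (warning logged); its p-value is 1 under the
  ≥ rule. A permuted split with zero pooled variance but non-zero mean
  difference evaluates to ±inf, the correct limit for the exceedance
  comparison.
* **Enumeration.** Exhaustive mode enumerates all `C(n, n_case)`
  assignments rather than deduplicating complementary labelings; the
  p-value is identical and the reported evaluation count is the full
  enumeration size.

`PFER` is linear in both α and the number of tests; `fdr_nominal` returns
NaN when nothing is declared (a value-state, not an error).

## Quantification choices

* **Zeros** in raw intensities are replaced by half the smallest positive
  value in the matrix before log2 (logged); negatives are an error.
* **Quantile normalization** maps each column's ranks to the across-column
  means of the rank-ordered values; ties within a column receive the mean of
  the rank-means they span. A single-column input is returned unchanged with
  a warning.
* **Rollup** defaults to equal weights. Inverse-variance weights (peptides
  weighted by the reciprocal of their across-sample variance, normalized per
  protein) are available for down-weighting noisy peptides; zero-variance
  peptides are clamped to the smallest positive variance. The full
  three-effect mixed model (group/sample/replicate) used for label-free
  quantification in the originating workflow is simplified to this weighted
  rollup: replicate structure is absent from the data layout this package
  targets, and the group/sample effects are handled by the downstream
  permutation test and the normalization respectively.
* **KS test** reference parameters default to the sample mean and sd
  (ddof=1); a fixed-parameter mode supports testing against a prescribed
  normal. The p-value uses the asymptotic Kolmogorov distribution. The Q-Q
  export uses plotting positions (i − 0.5)/n.

## Pathway and similarity choices

* The set-similarity score is the Jaccard index; two empty sets score 1
  (equal sets). Percent reporting truncates toward zero at integer
  precision (13/32 = 40.625% → "40%"); the raw fraction is always emitted
  alongside.
* Fisher enrichment is one-sided over-representation by default (equal to
  the hypergeometric upper tail); two-sided is selectable. Pathways with no
  members in the universe are dropped with a warning, as are query/panel
  members outside the universe.
* PPFCM pathway rankings break count ties lexicographically by pathway name.
* The pathway-matrix similarity is undefined (NaN, warning) when a study's
  pathway-count column is constant.
* Identifier matching is case-sensitive exact string equality; an optional
  two-column mapping table supports joins across identifier namespaces.

## The synthetic-data generator

The generator emulates label-free LC-MS/MS plasma profiling studies. Its
defaults are the study conditions the analysis is exercised under: 40 cases
vs 40 controls (a 20 vs 20 variant for the smaller study), 1422 proteins
carrying 1–6 peptides each (≈ 4970 peptides), 254 planted differential
proteins split 208 over- / 46 under-expressed, at 2 log2 units.

Log2 intensity is additive: a protein baseline (right-skewed gamma,
shape 3, scale 1.5 log2 units above a 14.0 floor), a peptide offset
(normal, sd 1.0), a sample offset (normal, sd 0.25), a residual, and the
signed planted effect applied to all peptides of a differential protein in
the case columns only (peptide effects are protein-consistent because
testing happens after rollup). The default residual is a centered
log-normal (log-sd 0.5, sd ≈ 0.6 log2 units at unit scale) — heavy
right tail; `normal` and two-component `mixture` residuals are selectable.
The gamma baselines and skewed residuals make the pooled log2 distribution
KS-rejectable as normal at realistic sizes, matching the diagnostic the
analysis reacts to. The direction split is
`n_over = round(n_differential × frac_overexpressed)`, remainder under.
Missing values are not generated by default; an optional missing-at-random
fraction plants NaNs in the raw matrix.

What the generator does **not** emulate: peptide sequences, retention
times, charge states, spectra, batch effects, peptide-protein degeneracy
(shared peptides), or intensity-dependent missingness. Passing tests on this
generator show the statistical machinery behaves as specified under
realistic distributional shapes — not that the pipeline overcomes
acquisition artifacts absent from the simulation.

### A known limitation found with the generator

With ~18% of the proteome planted at 2 log2 units, mostly in one direction,
quantile normalization's assumption (all samples share one intensity
distribution) is violated: forcing case columns onto the common
distribution shifts the unchanged majority of proteins slightly in the
opposite direction, and with 40 vs 40 samples these compensatory shifts
become significant, inflating "under" calls far beyond the nominal FDR.
Planted-effect recovery and the null-data Type-I calibration are unaffected
(the null study satisfies the QN assumption), but the nominal FDR should
not be read as the realized false-discovery proportion under strong
asymmetric signal. This is a property of the quantile-normalization step,
faithfully implemented, not of the permutation test.

## Problem sizes used by the shipped analyses and tests

The numbered analysis scripts run three full-size studies (1422 proteins,
40+40 / 20+20 samples) with 20,000 Monte-Carlo relabelings per protein —
p-value granularity 5e-5, an order of magnitude below the α = 0.001
selection level. The test suite's calibration check uses a 1000-protein null
study and the recovery check the full 1422-protein design, both at 10,000
relabelings, for the same reason. Exhaustive-oracle equivalence is verified
on all two-group layouts with up to 12 samples against an exact
rational-arithmetic enumeration.

## Reference sets and annotations

Reference biomarker sets and pathway annotations are user-supplied files
(one-ID-per-line lists; GMT). The generator can draw reference sets with an
exact prescribed overlap to a given set, and random pathway annotations
within a size range, for controlled cross-study experiments. No live
database queries are performed, keeping results independent of database
versions.
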