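# plasmapanel

Panel-biomarker discovery for case/control plasma proteomics.

Single-marker discovery in plasma is fragile: label-free LC-MS/MS intensity
data are noisy, non-normally distributed, and candidate lists barely overlap
between studies. `plasmapanel` implements a systems-style alternative for
two-group (case vs control) designs: distribution-free per-protein testing,
panel derivation against published reference sets, and cross-study
comparison at the pathway level, where agreement is typically much higher
than at the protein level. It is aimed at computational proteomics
researchers who have peptide- or protein-level intensity tables and want a
tested, reproducible implementation of this workflow — plus a synthetic
study generator with known ground truth for validating it.

## Method

For protein *g* with case values *x* and control values *y*, the default
statistic is the pooled-variance two-sample t,

    T_g = (x̄ − ȳ) / sqrt(s_p² (1/n₁ + 1/n₂)),

and its p-value is taken from the permutation distribution: the proportion
of case/control relabelings with |T_perm| ≥ |T_obs| (all C(n, n₁)
assignments when feasible, otherwise seeded Monte-Carlo relabelings).
Selection at a per-test level α is summarized by the per-family Type 1
error rate and the nominal false discovery rate,

    PFER = n_tested × α,        FDR = PFER / n_declared.

Upstream, peptide intensities are log2-transformed, quantile-normalized
across samples, and rolled up to proteins as a weighted average of each
protein's peptides; a one-sample Kolmogorov–Smirnov test (and Q-Q export)
documents the non-normality that motivates permutation inference.
Downstream, a candidate panel is the intersection of the significant
proteins with reference biomarker sets, and two similarity scores compare
panels across studies:

* **protein method** — Jaccard index |P_i ∩ P_j| / |P_i ∪ P_j|,
  reported as an integer percent truncated toward zero;
* **pathway-matrix method** — Pearson correlation of the two studies'
  columns of the pathway-protein frequency count matrix (PPFCM), whose
  cell (pathway, study) counts the study's panel members in that pathway.

Per-pathway Fisher's exact tests (one-sided over-representation) score
enrichment of a panel against a GMT annotation.

See `docs/methods.md` for assumptions, edge-case handling and limitations.

## Worked example

```python
import plasmapanel as pp

# simulate a 40 vs 40 study: 1422 proteins, 254 differential
# (208 over / 46 under) at 2 log2 units
design = pp.StudyDesign(seed=21)
matrix, pep_map, truth = pp.generate_study(design)

# quantify: log2 -> quantile normalize -> roll peptides up to proteins
proteins = pp.rollup_proteins(
    pp.quantile_normalize(pp.log2_transform(matrix)), pep_map)

# permutation test, selection at alpha = 0.001
results = pp.permutation_pvalues(proteins, kind="pooled_t",
                                 n_perm=10_000, seed=22)
summary, flagged = pp.select_significant(results, alpha=0.001)
print(f"{summary.n_significant}/{summary.n_tested} significant "
      f"(PFER={summary.pfer:.3f}, FDR={summary.fdr_nominal:.4f})")

recovered = set(flagged.index[flagged.significant]) & truth.differential_ids
print(f"recovered {len(recovered)}/{len(truth.differential_ids)} planted")
```

Output:

```
729/1422 significant (PFER=1.422, FDR=0.0020)
recovered 254/254 planted
```

PFER = 1422 × 0.001 = 1.422 expected false positives across the family; all
254 planted proteins are recovered. (The surplus calls are compensatory
shifts introduced by quantile normalization under this deliberately strong,
one-sided planted signal — see `docs/methods.md`.) Comparing two panels of
sizes 25 and 20 sharing 13 members:

```python
panel_a = pp.BiomarkerSet("A", frozenset(f"p{i}" for i in range(25)))
panel_b = pp.BiomarkerSet("B", frozenset(
    [f"p{i}" for i in range(13)] + [f"q{i}" for i in range(7)]))
s = pp.set_similarity(panel_a, panel_b)   # 13/32 = 0.40625
pp.percent_truncated(s)                   # 40
```

## Analysis scripts and CLI

`analysis/01_simulate_studies.py` … `06_similarity_scores.py` run the full
narrative on three simulated studies (A/B: 40 vs 40, C: 20 vs 20), writing
tables under `results/analysis/`. The same stages are available as a CLI —
`plasmapanel simulate | quantify | test | panel | pathways | similarity`,
plus `plasmapanel run --config cfg.yaml` for an end-to-end run with a JSON
manifest (config snapshot, per-stage seeds, output checksums). Exit codes:
0 success, 1 validation error, 2 stage failure.

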