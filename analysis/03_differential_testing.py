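"""Permutation differential testing with PFER / nominal-FDR summaries.

Each protein is tested with a pooled-variance t-statistic whose p-value is
the proportion of random group relabelings at least as extreme in absolute
value.  Significance is called at alpha = 0.001 and summarized by the
per-family Type 1 error rate (PFER = n_tested x alpha) and the nominal FDR
(PFER / n_declared).  Recovery against the planted truth is reported.
"""

import pandas as pd

from common import ALPHA, DESIGNS, MASTER_SEED, N_PERM, STATISTIC, study_dir
from plasmapanel import permutation_pvalues, select_significant
from plasmapanel.matrix import IntensityMatrix
from plasmapanel.panel import BiomarkerSet
from plasmapanel.permtest import write_results
from plasmapanel.pipeline import stage_seed

for label in DESIGNS:
    d = study_dir(label)
    proteins = IntensityMatrix.from_tsv(d / "proteins_log2.tsv",
                                        d / "groups.tsv", scale="log2")
    results = permutation_pvalues(proteins, kind=STATISTIC, n_perm=N_PERM,
                                  seed=stage_seed(MASTER_SEED, "test", label),
                                  mode="auto")
    summary, flagged = select_significant(results, ALPHA)
    write_results(flagged, d / "test_results.tsv")
    summary.to_tsv(d / "significance_summary.tsv")
    called = frozenset(flagged.index[flagged["significant"]])
    BiomarkerSet(label, called).to_tsv(d / "significant.tsv")

    truth = set(pd.read_csv(d / "truth.tsv", sep="\t")["protein_id"])
    recovered = len(called & truth)
    false_pos = len(called - truth)
    print(f"study {label}: {summary.n_significant}/{summary.n_tested} "
          f"significant at alpha={ALPHA} (PFER={summary.pfer:.4g}, nominal "
          f"FDR={summary.fdr_nominal:.4g}; {summary.n_over} over / "
          f"{summary.n_under} under); recovered {recovered}/{len(truth)} "
          f"planted proteins, {false_pos} false calls")

print("note: with ~18% of proteins planted at 2 log2 units (mostly "
      "over-expressed), quantile normalization compensates by shifting the "
      "unchanged majority, producing spurious 'under' calls — recovery of "
      "planted effects is complete, but the nominal FDR understates the "
      "realized false-discovery proportion under such strong asymmetric "
      "signal")
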