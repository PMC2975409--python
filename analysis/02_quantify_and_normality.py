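"""Quantify proteins and check the normality assumption.

For each study: log2-transform, test the pooled log2 peptide intensities for
normality (one-sample Kolmogorov-Smirnov against a fitted normal, with a Q-Q
table export), quantile-normalize across samples and roll peptides up to
protein-level intensities.  The KS rejection motivates the permutation test
used downstream in place of a parametric t-test.
"""

from common import DESIGNS, study_dir
from plasmapanel import (ks_normality_test, log2_transform, qq_export,
                         quantile_normalize, rollup_proteins)
from plasmapanel.matrix import IntensityMatrix
from plasmapanel.synthetic import read_peptide_map

for label in DESIGNS:
    d = study_dir(label)
    m = IntensityMatrix.from_tsv(d / "peptides_raw.tsv", d / "groups.tsv",
                                 scale="raw")
    log2 = log2_transform(m)
    pooled = log2.values.to_numpy().ravel()
    report = ks_normality_test(pooled)
    report.to_tsv(d / "normality.tsv")
    qq_export(pooled).to_csv(d / "qq.tsv", sep="\t", index=False)
    proteins = rollup_proteins(quantile_normalize(log2),
                               read_peptide_map(d / "peptide_map.tsv"))
    proteins.to_tsv(d / "proteins_log2.tsv", d / "groups.tsv",
                    id_label="protein_id")
    verdict = "rejected" if report.p_value < 0.01 else "not rejected"
    print(f"study {label}: pooled log2 intensities n={report.n}, "
          f"KS D={report.D:.4f}, p={report.p_value:.3g} -> normality "
          f"{verdict}; rolled up to {proteins.n_features} proteins")
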