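"""Cross-study biomarker-set similarity by the two scoring methods.

The protein method is the Jaccard index of two panels (reported also as an
integer percent truncated toward zero); the pathway-protein matrix method is
the Pearson correlation between the studies' PPFCM columns, which credits
agreement at the pathway level even when the specific proteins differ.
"""

import pandas as pd

from common import DESIGNS, RESULTS, study_dir
from plasmapanel import matrix_similarity, percent_truncated, set_similarity
from plasmapanel.panel import BiomarkerSet

panels = {label: BiomarkerSet.from_tsv(study_dir(label) / "panel.tsv",
                                       name=label)
          for label in DESIGNS}
ppfcm = pd.read_csv(RESULTS / "ppfcm.tsv", sep="\t", index_col=0)

labels = list(panels)
rows = []
for i in range(len(labels)):
    for j in range(i + 1, len(labels)):
        a, b = labels[i], labels[j]
        jac = set_similarity(panels[a], panels[b])
        rho = matrix_similarity(ppfcm, a, b)
        rows.append({"study_i": a, "study_j": b, "jaccard": jac,
                     "jaccard_percent": percent_truncated(jac),
                     "ppfcm_pearson": rho})
        print(f"{a} vs {b}: protein method {jac:.4f} "
              f"({percent_truncated(jac)}%), pathway-matrix method "
              f"{rho:.4f} ({percent_truncated(rho)}%)")

pd.DataFrame(rows).to_csv(RESULTS / "similarity.tsv", sep="\t", index=False)
print("pathway-level agreement exceeds protein-level overlap when panels "
      "hit the same pathways through different members")
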