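"""Derive candidate biomarker panels against reference sets; Venn overlap.

Reference biomarker sets (standing in for published cell-line studies) are
generated with a controlled overlap to study A's planted truth; each study's
panel is the intersection of its significant proteins with the union of the
references.  A three-way Venn table summarizes cross-study agreement.
"""

import pandas as pd

from common import DESIGNS, MASTER_SEED, RESULTS, study_dir
from plasmapanel import derive_panel, generate_reference_sets, venn_counts
from plasmapanel.panel import BiomarkerSet
from plasmapanel.pipeline import stage_seed

N_REFERENCES = 4
REFERENCE_SIZE = 770   # ~3085 reference biomarkers across 4 sets
REFERENCE_OVERLAP = 30

universe = {f"PROT{i:05d}" for i in
            range(1, DESIGNS["A"].n_proteins + 1)}
truth_a = BiomarkerSet("truth_A", frozenset(
    pd.read_csv(study_dir("A") / "truth.tsv", sep="\t")["protein_id"]))
references = generate_reference_sets(
    universe, N_REFERENCES, REFERENCE_SIZE, overlap_with=truth_a,
    n_overlap=REFERENCE_OVERLAP, seed=stage_seed(MASTER_SEED, "references"))
for ref in references:
    ref.to_tsv(RESULTS / f"{ref.name}.tsv")

panels = []
for label in DESIGNS:
    d = study_dir(label)
    sig = BiomarkerSet.from_tsv(d / "significant.tsv", name=label)
    p = derive_panel(sig, references, rule="any")
    p = BiomarkerSet(label, p.members)
    p.to_tsv(d / "panel.tsv")
    panels.append(p)
    print(f"study {label}: panel of {len(p)} proteins from "
          f"{len(sig)} significant x {N_REFERENCES} references")

table = venn_counts(panels)
table.to_csv(RESULTS / "venn_counts.tsv", sep="\t", index=False)
core = table[(table[[p.name for p in panels]] == 1).all(axis=1)]
print(f"three-way Venn: union {table['count'].sum()}, "
      f"core shared by all studies {int(core['count'].iloc[0])}")
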