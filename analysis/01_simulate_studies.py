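"""Simulate the three case/control plasma studies with known ground truth.

Writes each study's raw peptide intensity matrix, sample->group map,
peptide->protein map and planted truth under results/analysis/study_<X>/.
"""

from common import DESIGNS, study_dir
from plasmapanel import generate_study
from plasmapanel.synthetic import write_peptide_map

for label, design in DESIGNS.items():
    matrix, pep_map, truth = generate_study(design)
    d = study_dir(label)
    matrix.to_tsv(d / "peptides_raw.tsv", d / "groups.tsv",
                  id_label="peptide_id")
    write_peptide_map(pep_map, d / "peptide_map.tsv")
    truth.to_tsv(d / "truth.tsv")
    n_over = sum(1 for v in truth.direction.values() if v == "over")
    print(f"study {label}: {matrix.n_features} peptides -> "
          f"{design.n_proteins} proteins, {design.n_case}+{design.n_control} "
          f"samples, {len(truth.differential_ids)} differential "
          f"({n_over} over / {len(truth.differential_ids) - n_over} under)")
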