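"""Pathway-protein matrices, rankings and Fisher enrichment.

A synthetic pathway annotation over the protein universe stands in for a
curated database.  Outputs: the binary pathway x protein association matrix
for study A's panel, the pathway-protein frequency count matrix (PPFCM) over
all three studies (wide + long form), per-study pathway rankings, and
one-sided Fisher enrichment of study A's panel.
"""

from common import DESIGNS, MASTER_SEED, RESULTS, study_dir
from plasmapanel import (build_association_matrix, build_ppfcm,
                         fisher_enrichment, generate_pathway_annotation,
                         rank_pathways)
from plasmapanel.panel import BiomarkerSet
from plasmapanel.pathway import ppfcm_long
from plasmapanel.pipeline import stage_seed

universe = {f"PROT{i:05d}" for i in range(1, DESIGNS["A"].n_proteins + 1)}
annotation = generate_pathway_annotation(
    universe, n_pathways=30, size_range=(15, 120),
    seed=stage_seed(MASTER_SEED, "pathways"))
annotation.to_gmt(RESULTS / "pathways.gmt")

panels = {label: BiomarkerSet.from_tsv(study_dir(label) / "panel.tsv",
                                       name=label)
          for label in DESIGNS}

assoc = build_association_matrix(panels["A"], annotation)
assoc.to_csv(RESULTS / "association_matrix.tsv", sep="\t")

ppfcm = build_ppfcm(panels, annotation)
ppfcm.to_csv(RESULTS / "ppfcm.tsv", sep="\t")
ppfcm_long(ppfcm).to_csv(RESULTS / "ppfcm_long.tsv", sep="\t", index=False)

with open(RESULTS / "pathway_ranks.tsv", "w") as fh:
    fh.write("study\trank\tpathway\tcount\n")
    for label in panels:
        for i, name in enumerate(rank_pathways(ppfcm, label), 1):
            fh.write(f"{label}\t{i}\t{name}\t{ppfcm.loc[name, label]}\n")

enrich = fisher_enrichment(panels["A"], annotation).sort_values("p_value")
enrich.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

for label in panels:
    top3 = rank_pathways(ppfcm, label)[:3]
    print(f"study {label}: top pathways by panel-member count: "
          f"{', '.join(top3)}")
top = enrich.iloc[0]
print(f"study A enrichment: most enriched {top['pathway']} "
      f"(overlap {int(top['overlap'])}/{int(top['pathway_size'])}, "
      f"p={top['p_value']:.3g})")
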