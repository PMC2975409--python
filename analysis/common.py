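"""Shared paths, seeds and study designs for the numbered analysis scripts.

Three simulated plasma studies mirror the layout of the motivating data:
A and B with 40 cases vs 40 controls, C with 20 vs 20; 1422 proteins with a
many-to-one peptide map, 254 planted differential proteins (208 over / 46
under, 2 log2 units).  Permutation counts are scaled to 20,000 relabelings
per protein, which resolves p-values to 5e-5 — an order of magnitude below
the 0.001 significance level the analysis uses.
"""

from pathlib import Path

from plasmapanel import StudyDesign
from plasmapanel.pipeline import stage_seed

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"

MASTER_SEED = 2021
N_PERM = 20_000
ALPHA = 0.001
STATISTIC = "pooled_t"

DESIGNS = {
    "A": StudyDesign(seed=stage_seed(MASTER_SEED, "simulate", "A")),
    "B": StudyDesign(seed=stage_seed(MASTER_SEED, "simulate", "B")),
    "C": StudyDesign(n_case=20, n_control=20,
                     seed=stage_seed(MASTER_SEED, "simulate", "C")),
}


def study_dir(label: str) -> Path:
    d = RESULTS / f"study_{label}"
    d.mkdir(parents=True, exist_ok=True)
    return d
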