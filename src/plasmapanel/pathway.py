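"""Pathway-protein matrices, Fisher enrichment and biomarker-set similarity.

Two cross-study similarity scores are provided:

* the *protein method* — the Jaccard index of two biomarker sets,
  |intersection| / |union|, conventionally reported as an integer percent
  truncated toward zero;
* the *pathway-protein matrix method* — the Pearson correlation of two
  studies' columns in the pathway-protein frequency count matrix (PPFCM),
  whose cell (pathway, study) counts that study's panel members in the
  pathway.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .panel import BiomarkerSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PathwayAnnotation:
    """Pathway -> member-set map over a protein universe.

    Members outside the universe are dropped (logged); pathways left with no
    members in the universe are removed (logged).
    """

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for name, members in self.pathways.items():
            inside = frozenset(members) & self.universe
            if len(inside) < len(members):
                logger.warning("pathway %s: dropped %d members outside universe",
                               name, len(members) - len(inside))
            if not inside:
                logger.warning("pathway %s has no members in universe; dropped", name)
                continue
            cleaned[name] = inside
        self.pathways = cleaned

    def __len__(self) -> int:
        return len(self.pathways)

    # ---------------------------------------------------------------- I/O

    def to_gmt(self, path: str | Path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name in sorted(self.pathways):
                members = "\t".join(sorted(self.pathways[name]))
                fh.write(f"{name}\t{description}\t{members}\n")

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "PathwayAnnotation":
        pathways: dict[str, frozenset[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = parts[0]
            if name in pathways:
                raise ValueError(f"duplicate pathway name in GMT: {name}")
            pathways[name] = frozenset(p for p in parts[2:] if p)
        if universe is None:
            universe = frozenset().union(*pathways.values()) if pathways else frozenset()
        return cls(pathways=pathways, universe=frozenset(universe))


def build_association_matrix(panel: BiomarkerSet,
                             annotation: PathwayAnnotation) -> pd.DataFrame:
    """Binary pathway x protein membership matrix over the panel members.

    Panel members absent from the annotation universe are logged and dropped.
    """
    if len(annotation) == 0:
        raise ValueError("annotation contains no pathways")
    outside = sorted(panel.members - annotation.universe)
    if outside:
        logger.warning("association matrix: dropped %d panel members outside "
                       "universe: %s", len(outside), outside[:5])
    members = sorted(panel.members & annotation.universe)
    names = sorted(annotation.pathways)
    data = np.zeros((len(names), len(members)), dtype=int)
    for i, name in enumerate(names):
        pw = annotation.pathways[name]
        for j, m in enumerate(members):
            if m in pw:
                data[i, j] = 1
    return pd.DataFrame(data, index=names, columns=members)


def build_ppfcm(panels: Mapping[str, BiomarkerSet] | Iterable[tuple[str, BiomarkerSet]],
                annotation: PathwayAnnotation) -> pd.DataFrame:
    """Pathway-protein frequency count matrix: rows pathways, columns
    studies, cells |pathway ∩ study panel|."""
    items = list(panels.items()) if isinstance(panels, Mapping) else list(panels)
    if not items:
        raise ValueError("at least one study panel required")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate study labels")
    names = sorted(annotation.pathways)
    data = {lab: [len(annotation.pathways[n] & p.members) for n in names]
            for lab, p in items}
    return pd.DataFrame(data, index=names)


def ppfcm_long(ppfcm: pd.DataFrame) -> pd.DataFrame:
    """Long (pathway, study, count) form of the PPFCM for heatmap plotting."""
    long = ppfcm.stack().reset_index()
    long.columns = ["pathway", "study", "count"]
    return long


def rank_pathways(ppfcm: pd.DataFrame, study: str) -> list[str]:
    """Pathways ordered by descending count in one study; ties broken
    lexicographically by pathway name."""
    if study not in ppfcm.columns:
        raise KeyError(f"unknown study {study!r}")
    col = ppfcm[study]
    return sorted(col.index, key=lambda n: (-col[n], n))


def fisher_enrichment(list_set: BiomarkerSet, annotation: PathwayAnnotation,
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-pathway Fisher's exact test of over-representation.

    For each pathway the 2x2 table (in-list x in-pathway over the annotation
    universe) is tested one-sided for over-representation by default
    (equivalently the hypergeometric upper tail); ``alternative="two-sided"``
    gives the two-sided Fisher test.
    """
    universe = annotation.universe
    members = list_set.members & universe
    outside = list_set.members - universe
    if outside:
        logger.warning("enrichment: dropped %d list members outside universe",
                       len(outside))
    if len(universe) < len(members):
        raise ValueError("universe smaller than the query list")
    n_universe = len(universe)
    n_list = len(members)
    rows = []
    for name in sorted(annotation.pathways):
        pw = annotation.pathways[name]
        if not pw:
            continue
        overlap = len(pw & members)
        table = [[overlap, n_list - overlap],
                 [len(pw) - overlap, n_universe - n_list - len(pw) + overlap]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        rows.append({"pathway": name, "overlap": overlap, "list_size": n_list,
                     "pathway_size": len(pw), "universe_size": n_universe,
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def set_similarity(p_i: BiomarkerSet, p_j: BiomarkerSet) -> float:
    """Jaccard similarity |intersection| / |union| of two biomarker sets.

    Two empty sets are defined as identical (similarity 1).
    """
    union = p_i.members | p_j.members
    if not union:
        return 1.0
    return len(p_i.members & p_j.members) / len(union)


def percent_truncated(fraction: float) -> int:
    """Integer percent, truncated toward zero (0.40625 -> 40)."""
    return math.trunc(fraction * 100.0)


def matrix_similarity(ppfcm: pd.DataFrame, study_i: str, study_j: str) -> float:
    """Pearson correlation of two studies' pathway-count columns.

    Returns NaN (with a logged warning) when either column is constant,
    where the correlation is undefined.
    """
    for s in (study_i, study_j):
        if s not in ppfcm.columns:
            raise KeyError(f"unknown study {s!r}")
    if ppfcm.shape[0] < 2:
        raise ValueError("at least two pathways required")
    x = ppfcm[study_i].to_numpy(dtype=float)
    y = ppfcm[study_j].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("matrix_similarity: constant pathway-count column; "
                       "correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
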