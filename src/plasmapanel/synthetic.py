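"""Synthetic case/control plasma-proteomics studies with known ground truth.

The generator emulates the structure of label-free LC-MS/MS plasma profiling
studies: two sample groups (possibly of unequal size), a many-to-one
peptide -> protein map, log2 intensities whose pooled distribution is
detectably non-normal, and a planted subset of differentially expressed
proteins with a controlled over/under-expression split.

The additive model on the log2 scale is

    log2 I[p, s] = baseline(protein) + peptide offset + sample offset
                   + residual + effect(protein) * 1[s in case group]

with protein baselines drawn from a right-skewed gamma (so the pooled log2
distribution fails a Kolmogorov-Smirnov normality test at realistic sizes),
and residuals from a centered log-normal by default (heavy right tail).
Raw-scale intensities are 2**log2.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CASE, CONTROL, IntensityMatrix
from .panel import BiomarkerSet
from .pathway import PathwayAnnotation

logger = logging.getLogger(__name__)

NOISE_MODELS = ("lognormal", "normal", "mixture")

#: log-sd of the log-normal residual component; gives residual sd ~0.60 at
#: noise_scale 1, comparable to typical label-free peptide-level CVs.
_LOGNORMAL_SIGMA = 0.5


@dataclasses.dataclass
class StudyDesign:
    """Parameters of one simulated case/control study.

    Defaults mirror the layout of a 40 vs 40 plasma profiling study with
    4832 peptides mapped onto 1422 proteins, of which 254 are differential
    (208 over- and 46 under-expressed in cases).
    """

    n_case: int = 40
    n_control: int = 40
    n_proteins: int = 1422
    peptides_per_protein: tuple[int, int] = (1, 6)
    n_differential: int = 254
    frac_overexpressed: float = 208 / 254
    effect_size: float = 2.0
    noise_model: str = "lognormal"
    seed: int = 0
    # secondary knobs (units: log2 intensity)
    noise_scale: float = 1.0
    baseline_loc: float = 14.0
    baseline_gamma_shape: float = 3.0
    baseline_gamma_scale: float = 1.5
    sample_effect_sd: float = 0.25
    peptide_effect_sd: float = 1.0
    missing_frac: float = 0.0

    def validate(self) -> None:
        for field in ("n_case", "n_control", "n_proteins"):
            if int(getattr(self, field)) < 1:
                raise ValueError(f"{field} must be a positive integer")
        if self.n_differential < 0:
            raise ValueError("n_differential must be non-negative")
        if self.n_differential > self.n_proteins:
            raise ValueError("n_differential must not exceed n_proteins")
        if not (0.0 <= self.frac_overexpressed <= 1.0):
            raise ValueError("frac_overexpressed must lie in [0, 1]")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must satisfy 1 <= min <= max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must lie in [0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted differential proteins: identities, directions, signed effects."""

    differential_ids: frozenset[str]
    direction: dict[str, str]  # protein id -> "over" | "under"
    effect: dict[str, float]   # protein id -> signed log2 effect

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "protein_id": sorted(self.differential_ids),
        })
        df["direction"] = [self.direction[p] for p in df["protein_id"]]
        df["effect_log2"] = [self.effect[p] for p in df["protein_id"]]
        df.to_csv(path, sep="\t", index=False)


def _residuals(rng: np.random.Generator, model: str, scale: float,
               shape: tuple[int, ...]) -> np.ndarray:
    if model == "normal":
        return rng.normal(0.0, 0.6 * scale, size=shape)
    if model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=_LOGNORMAL_SIGMA, size=shape)
        return scale * (raw - math.exp(_LOGNORMAL_SIGMA ** 2 / 2.0))
    if model == "mixture":
        narrow = rng.normal(0.0, 0.4 * scale, size=shape)
        wide = rng.normal(0.0, 1.2 * scale, size=shape)
        pick = rng.random(size=shape) < 0.2
        return np.where(pick, wide, narrow)
    raise ValueError(f"unknown noise model {model!r}")


def generate_study(design: StudyDesign
                   ) -> tuple[IntensityMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate one study.

    Returns
    -------
    matrix
        Raw-scale peptide-level :class:`IntensityMatrix` with
        ``n_case + n_control`` columns.
    peptide_map
        Two-column DataFrame ``(peptide_id, protein_id)``; every peptide maps
        to exactly one protein and every protein owns at least one peptide.
    truth
        The planted differential proteins with directions and signed effects.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    protein_ids = [f"PROT{i:05d}" for i in range(1, design.n_proteins + 1)]
    lo, hi = design.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=design.n_proteins)
    protein_of_row = np.repeat(np.arange(design.n_proteins), pep_counts)
    n_pep = int(pep_counts.sum())
    peptide_ids = [f"PEP{i:06d}" for i in range(1, n_pep + 1)]
    peptide_map = pd.DataFrame({
        "peptide_id": peptide_ids,
        "protein_id": [protein_ids[j] for j in protein_of_row],
    })

    samples = ([f"case_{i:03d}" for i in range(1, design.n_case + 1)]
               + [f"control_{i:03d}" for i in range(1, design.n_control + 1)])
    groups = {s: (CASE if s.startswith("case_") else CONTROL) for s in samples}
    n_samp = len(samples)
    case_mask = np.array([groups[s] == CASE for s in samples])

    # planted truth: choose proteins, then split directions deterministically
    diff_idx = rng.choice(design.n_proteins, size=design.n_differential,
                          replace=False)
    n_over = int(math.floor(design.n_differential * design.frac_overexpressed + 0.5))
    signed = np.zeros(design.n_proteins)
    direction: dict[str, str] = {}
    effect: dict[str, float] = {}
    for k, j in enumerate(diff_idx):
        sign = 1.0 if k < n_over else -1.0
        signed[j] = sign * design.effect_size
        pid = protein_ids[j]
        direction[pid] = "over" if sign > 0 else "under"
        effect[pid] = signed[j]
    truth = SyntheticTruth(
        differential_ids=frozenset(protein_ids[j] for j in diff_idx),
        direction=direction, effect=effect)

    baseline = design.baseline_loc + rng.gamma(design.baseline_gamma_shape,
                                               design.baseline_gamma_scale,
                                               size=design.n_proteins)
    pep_offset = rng.normal(0.0, design.peptide_effect_sd, size=n_pep)
    samp_offset = rng.normal(0.0, design.sample_effect_sd, size=n_samp)
    resid = _residuals(rng, design.noise_model, design.noise_scale,
                       (n_pep, n_samp))

    log2 = (baseline[protein_of_row][:, None]
            + pep_offset[:, None]
            + samp_offset[None, :]
            + resid
            + signed[protein_of_row][:, None] * case_mask[None, :])
    raw = np.exp2(log2)

    if design.missing_frac > 0.0:
        drop = rng.random(size=raw.shape) < design.missing_frac
        raw = np.where(drop, np.nan, raw)
        logger.info("planted %.1f%% missing values at random",
                    100.0 * design.missing_frac)

    values = pd.DataFrame(raw, index=peptide_ids, columns=samples)
    matrix = IntensityMatrix(values=values, groups=groups, scale="raw")
    logger.info("simulated study: %d peptides / %d proteins, %d+%d samples, "
                "%d differential", n_pep, design.n_proteins, design.n_case,
                design.n_control, design.n_differential)
    return matrix, peptide_map, truth


def generate_reference_sets(universe: set[str], n_sets: int, set_size: int,
                            overlap_with: BiomarkerSet, n_overlap: int,
                            seed: int) -> list[BiomarkerSet]:
    """Draw reference biomarker sets with a fixed overlap to a given set.

    Each returned set has exactly ``set_size`` members drawn from
    ``universe`` and shares exactly ``n_overlap`` members with
    ``overlap_with``.  Used to emulate externally published biomarker lists
    (e.g. cell-line studies) with a controlled degree of agreement.
    """
    universe = set(universe)
    if n_sets < 1:
        raise ValueError("n_sets must be positive")
    if set_size < 1 or set_size > len(universe):
        raise ValueError("set_size must be in [1, |universe|]")
    anchor = set(overlap_with.members) & universe
    if n_overlap > min(set_size, len(anchor)):
        raise ValueError("n_overlap exceeds min(set_size, |overlap_with|)")
    outside = sorted(universe - set(overlap_with.members))
    if set_size - n_overlap > len(outside):
        raise ValueError("not enough non-overlapping identifiers in universe")
    rng = np.random.default_rng(seed)
    anchor_sorted = sorted(anchor)
    out: list[BiomarkerSet] = []
    for k in range(n_sets):
        shared = rng.choice(anchor_sorted, size=n_overlap, replace=False)
        rest = rng.choice(outside, size=set_size - n_overlap, replace=False)
        members = frozenset(shared.tolist()) | frozenset(rest.tolist())
        out.append(BiomarkerSet(name=f"reference_{k + 1}", members=members))
    return out


def generate_pathway_annotation(universe: set[str], n_pathways: int,
                                size_range: tuple[int, int],
                                seed: int) -> PathwayAnnotation:
    """Draw random pathway membership sets from a protein universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if n_pathways < 0:
        raise ValueError("n_pathways must be non-negative")
    lo, hi = size_range
    if lo < 1 or hi < lo or hi > len(universe):
        raise ValueError("size_range must satisfy 1 <= min <= max <= |universe|")
    rng = np.random.default_rng(seed)
    ordered = sorted(universe)
    pathways: dict[str, frozenset[str]] = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ordered, size=size, replace=False)
        pathways[f"pathway_{k + 1:03d}"] = frozenset(members.tolist())
    return PathwayAnnotation(pathways=pathways, universe=frozenset(universe))


def write_peptide_map(peptide_map: pd.DataFrame, path: str | Path) -> None:
    peptide_map.to_csv(path, sep="\t", index=False)


def read_peptide_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("peptide map must have exactly two columns")
    df.columns = ["peptide_id", "protein_id"]
    return df
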