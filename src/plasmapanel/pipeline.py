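"""End-to-end orchestration: simulate -> quantify -> test -> panel ->
pathways -> similarity, with a structured config and a run manifest.

The pipeline runs one or more simulated case/control studies through the
full analysis and writes every stage's outputs as TSV (pathway annotation as
GMT).  A JSON manifest written last records the effective config, per-stage
seeds, software version, timestamps and SHA-256 checksums of every output,
so that a run can be reproduced and intermediates verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import panel as panel_mod
from . import pathway as pathway_mod
from . import permtest, quantify, synthetic
from .panel import BiomarkerSet

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "test", "panel", "pathways", "similarity")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Full-run configuration.

    ``studies`` maps a study label to :class:`synthetic.StudyDesign` keyword
    arguments.  Defaults mirror the analysis the package implements:
    alpha 0.001, 100000 permutations, pooled-variance t, panel rule "any".
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    studies: dict[str, dict[str, Any]] = dataclasses.field(
        default_factory=lambda: {"A": {}})
    statistic: str = "pooled_t"
    n_perm: int = permtest.DEFAULT_N_PERM
    alpha: float = permtest.DEFAULT_ALPHA
    perm_mode: str = "auto"
    rollup_weights: str = "equal"
    panel_rule: str = "any"
    annotation_path: str | None = None
    n_reference_sets: int = 4
    reference_set_size: int = 200
    reference_overlap: int = 25
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (10, 60)

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.statistic not in permtest.STAT_KINDS:
            raise ConfigError(f"statistic must be one of {permtest.STAT_KINDS}")
        if self.panel_rule not in ("any", "all"):
            raise ConfigError("panel_rule must be 'any' or 'all'")
        if not self.studies:
            raise ConfigError("at least one study must be configured")
        if self.annotation_path is not None and not Path(self.annotation_path).exists():
            raise ConfigError(f"annotation file not found: {self.annotation_path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "pathway_size_range" in raw:
            raw["pathway_size_range"] = tuple(raw["pathway_size_range"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        return d


def stage_seed(master: int, stage: str, study: str = "") -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}|{stage}|{study}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    seeds: dict[str, int] = {}
    counts: dict[str, Any] = {}

    def emit(path: Path) -> Path:
        outputs.append(path)
        return path

    studies: dict[str, dict[str, Any]] = {}
    current = "simulate"
    try:
        for label, kwargs in config.studies.items():
            s = stage_seed(config.seed, "simulate", label)
            seeds[f"simulate/{label}"] = s
            design = synthetic.StudyDesign(**{**kwargs, "seed": s})
            matrix, pep_map, truth = synthetic.generate_study(design)
            d = outdir / f"study_{label}"
            d.mkdir(exist_ok=True)
            matrix.to_tsv(emit(d / "peptides_raw.tsv"), emit(d / "groups.tsv"),
                          id_label="peptide_id")
            synthetic.write_peptide_map(pep_map, emit(d / "peptide_map.tsv"))
            truth.to_tsv(emit(d / "truth.tsv"))
            studies[label] = {"design": design, "matrix": matrix,
                              "map": pep_map, "truth": truth, "dir": d}
            counts[f"{label}/peptides"] = matrix.n_features
            counts[f"{label}/proteins"] = design.n_proteins

        current = "quantify"
        for label, st in studies.items():
            d = st["dir"]
            log2 = quantify.log2_transform(st["matrix"])
            pooled = log2.values.to_numpy().ravel()
            quantify.ks_normality_test(pooled).to_tsv(emit(d / "normality.tsv"))
            quantify.qq_export(pooled).to_csv(emit(d / "qq.tsv"), sep="\t",
                                              index=False)
            normed = quantify.quantile_normalize(log2)
            proteins = quantify.rollup_proteins(normed, st["map"],
                                                weights=config.rollup_weights)
            proteins.to_tsv(emit(d / "proteins_log2.tsv"),
                            d / "groups.tsv", id_label="protein_id")
            st["proteins"] = proteins

        current = "test"
        for label, st in studies.items():
            d = st["dir"]
            s = stage_seed(config.seed, "test", label)
            seeds[f"test/{label}"] = s
            results = permtest.permutation_pvalues(
                st["proteins"], kind=config.statistic, n_perm=config.n_perm,
                seed=s, mode=config.perm_mode)
            summary, flagged = permtest.select_significant(results, config.alpha)
            permtest.write_results(flagged, emit(d / "test_results.tsv"))
            summary.to_tsv(emit(d / "significance_summary.tsv"))
            st["significant"] = BiomarkerSet(
                name=label,
                members=frozenset(flagged.index[flagged["significant"]]))
            counts[f"{label}/significant"] = summary.n_significant
            logger.info("study %s: %d/%d significant at alpha=%g "
                        "(PFER=%.4g, FDR=%.4g)", label, summary.n_significant,
                        summary.n_tested, config.alpha, summary.pfer,
                        summary.fdr_nominal)

        current = "panel"
        first = next(iter(studies))
        universe = {f"PROT{i:05d}" for i in
                    range(1, studies[first]["design"].n_proteins + 1)}
        s = stage_seed(config.seed, "references")
        seeds["references"] = s
        anchor = studies[first]["significant"]
        overlap = min(config.reference_overlap,
                      min(config.reference_set_size, len(anchor)))
        references = synthetic.generate_reference_sets(
            universe, config.n_reference_sets, config.reference_set_size,
            overlap_with=anchor, n_overlap=overlap, seed=s)
        for ref in references:
            ref.to_tsv(emit(outdir / f"{ref.name}.tsv"))
        panels: dict[str, BiomarkerSet] = {}
        for label, st in studies.items():
            p = panel_mod.derive_panel(st["significant"], references,
                                       rule=config.panel_rule)
            p = BiomarkerSet(name=label, members=p.members)
            p.to_tsv(emit(st["dir"] / "panel.tsv"))
            panels[label] = p
            counts[f"{label}/panel"] = len(p)
        if 2 <= len(panels) <= 3:
            panel_mod.venn_counts(list(panels.values())).to_csv(
                emit(outdir / "venn_counts.tsv"), sep="\t", index=False)

        current = "pathways"
        if config.annotation_path:
            annotation = pathway_mod.PathwayAnnotation.from_gmt(
                config.annotation_path, universe=universe)
        else:
            s = stage_seed(config.seed, "pathways")
            seeds["pathways"] = s
            annotation = synthetic.generate_pathway_annotation(
                universe, config.n_pathways, config.pathway_size_range, seed=s)
        annotation.to_gmt(emit(outdir / "pathways.gmt"))
        assoc = pathway_mod.build_association_matrix(panels[first], annotation)
        assoc.to_csv(emit(outdir / "association_matrix.tsv"), sep="\t")
        ppfcm = pathway_mod.build_ppfcm(panels, annotation)
        ppfcm.to_csv(emit(outdir / "ppfcm.tsv"), sep="\t")
        pathway_mod.ppfcm_long(ppfcm).to_csv(emit(outdir / "ppfcm_long.tsv"),
                                             sep="\t", index=False)
        ranks = {lab: pathway_mod.rank_pathways(ppfcm, lab) for lab in panels}
        with open(emit(outdir / "pathway_ranks.tsv"), "w") as fh:
            fh.write("study\trank\tpathway\n")
            for lab, names in ranks.items():
                for i, nm in enumerate(names, 1):
                    fh.write(f"{lab}\t{i}\t{nm}\n")
        pathway_mod.fisher_enrichment(panels[first], annotation).to_csv(
            emit(outdir / "enrichment.tsv"), sep="\t", index=False)

        current = "similarity"
        labels = list(panels)
        with open(emit(outdir / "similarity.tsv"), "w") as fh:
            fh.write("study_i\tstudy_j\tjaccard\tjaccard_percent\t"
                     "ppfcm_pearson\n")
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = labels[i], labels[j]
                    jac = pathway_mod.set_similarity(panels[a], panels[b])
                    pct = pathway_mod.percent_truncated(jac)
                    if ppfcm.shape[0] >= 2:
                        rho = pathway_mod.matrix_similarity(ppfcm, a, b)
                    else:
                        rho = float("nan")
                    fh.write(f"{a}\t{b}\t{jac:.6f}\t{pct}\t{rho:.6f}\n")
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise StageError(current, exc) from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    logger.info("pipeline complete: %d outputs under %s", len(outputs), outdir)
    return manifest


def verify_manifest(outdir: str | Path) -> dict[str, bool]:
    """Recompute output checksums against the stored manifest."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return {rel: (outdir / rel).exists() and _sha256(outdir / rel) == digest
            for rel, digest in manifest["outputs"].items()}
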