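"""Biomarker sets, panel derivation against reference sets, and Venn counts."""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclasses.dataclass(frozen=True)
class BiomarkerSet:
    """A named set of protein identifiers (a study's candidates or a
    published reference list)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("BiomarkerSet name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        """One identifier per line, with the set name in a header comment."""
        with open(path, "w") as fh:
            fh.write(f"# {self.name}\n")
            for m in sorted(self.members):
                fh.write(m + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "BiomarkerSet":
        members: list[str] = []
        header_name = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_name is None:
                    header_name = line.lstrip("#").strip()
                continue
            members.append(line)
        resolved = name or header_name or Path(path).stem
        return cls(name=resolved, members=frozenset(members))


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source identifiers to target identifiers,
    for joining sets across namespaces (e.g. IPI vs UniProt names)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError("identifier map must have exactly two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _remap(members: frozenset[str], id_map: Mapping[str, str] | None) -> frozenset[str]:
    if id_map is None:
        return members
    return frozenset(id_map.get(m, m) for m in members)


def derive_panel(significant: BiomarkerSet, references: Iterable[BiomarkerSet],
                 rule: str = "any",
                 id_map: Mapping[str, str] | None = None) -> BiomarkerSet:
    """Intersect a study's significant proteins with reference sets.

    rule="any" keeps significant proteins present in the union of the
    references (membership in at least one published list); rule="all"
    requires presence in every reference.  Matching is exact string equality
    after the optional identifier remapping.
    """
    refs = list(references)
    sig = _remap(significant.members, id_map)
    mapped_refs = [_remap(r.members, id_map) for r in refs]
    if rule == "any":
        pool: frozenset[str] = frozenset().union(*mapped_refs) if mapped_refs else frozenset()
        kept = sig & pool
    elif rule == "all":
        kept = sig
        for r in mapped_refs:
            kept = kept & r
        if not mapped_refs:
            kept = frozenset()
    else:
        raise ValueError("rule must be 'any' or 'all'")
    # report panel members under their original identifiers
    members = frozenset(m for m in significant.members
                        if _remap(frozenset([m]), id_map) <= kept)
    return BiomarkerSet(name=f"{significant.name}_panel", members=members)


def venn_counts(sets: list[BiomarkerSet]) -> pd.DataFrame:
    """Exclusive-region counts for 2 or 3 biomarker sets.

    Returns one row per exclusive region, with a 0/1 indicator column per
    set name and a ``count`` column; region counts sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts requires 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    rows = []
    for pattern in itertools.product((1, 0), repeat=len(sets)):
        if not any(pattern):
            continue
        # inside every flagged set, outside every unflagged one
        region = set.intersection(*[set(s.members) for f, s in zip(pattern, sets) if f])
        for f, s in zip(pattern, sets):
            if not f:
                region -= s.members
        rows.append(dict(zip(names, pattern), count=len(region)))
    return pd.DataFrame(rows)
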