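"""Intensity matrix container shared by every pipeline stage.

An :class:`IntensityMatrix` is a wide table of feature intensities (rows are
peptides or proteins, columns are samples) together with a case/control group
assignment for each sample and a flag saying whether values are on the raw or
log2 scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)
SCALES = ("raw", "log2")


@dataclasses.dataclass
class IntensityMatrix:
    """Feature x sample intensity table with group annotation.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.
    groups
        Mapping sample id -> ``"case"`` or ``"control"``; every column of
        ``values`` must be present and both groups must be non-empty.
    scale
        ``"raw"`` (non-negative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate row identifiers: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        missing = [c for c in cols if c not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group map: {missing[:5]}")
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        labels = {self.groups[c] for c in cols}
        if labels != set(GROUPS):
            raise ValueError("both case and control groups must be non-empty")

    @property
    def case_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == CASE]

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == CONTROL]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        """Return a copy carrying new values but the same group annotation."""
        return IntensityMatrix(values=values, groups=dict(self.groups),
                               scale=self.scale if scale is None else scale)

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path,
               id_label: str = "feature_id") -> None:
        """Write the matrix and its sample->group map as TSV files."""
        out = self.values.copy()
        out.index.name = id_label
        # %.17g round-trips float64 exactly, so downstream stages reading
        # the TSV reproduce in-memory results bit for bit
        out.to_csv(matrix_path, sep="\t", float_format="%.17g")
        gm = pd.DataFrame({"sample_id": list(self.values.columns),
                           "group": [self.groups[c] for c in self.values.columns]})
        gm.to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path,
                 scale: str = "raw") -> "IntensityMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                             float_precision="round_trip")
        values.index = values.index.astype(str)
        values.index.name = None
        gm = pd.read_csv(groups_path, sep="\t", dtype=str)
        groups = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))
        return cls(values=values, groups=groups, scale=scale)
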