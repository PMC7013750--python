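"""Tabular I/O for expression matrices, sample sheets and transcript sets.

Every on-disk artifact is tab-separated UTF-8 text with a mandatory header:

* expression matrix — columns ``tc_id``, ``gene_symbol``, then one column per
  sample, intensities on the *linear* scale (log transforms happen in memory);
* sample sheet — columns ``sample_id``, ``platform``, ``group``;
* transcript set — columns ``tc_id``, ``direction`` plus a ``# source=``
  comment line carrying the comparison label;
* count reports — JSON keyed by comparison/classification label.

Unannotated transcript clusters are encoded by an empty ``gene_symbol``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Platform",
    "Group",
    "GROUPS_BY_PLATFORM",
    "ExpressionMatrix",
    "SampleSheet",
    "TranscriptSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_transcript_set",
    "write_transcript_set",
    "write_count_report",
    "read_count_report",
]


class FormatError(ValueError):
    """An on-disk artifact violates its documented dialect or invariants."""


class Platform(str, Enum):
    """Experimental platform: ground-based facility or suborbital rocket."""

    GBF = "GBF"
    TEXUS = "TEXUS"


class Group(str, Enum):
    """Sample groups across both platforms (see :data:`GROUPS_BY_PLATFORM`)."""

    # ground-based facility (clinostat / centrifuge)
    BL = "BL"                       # baseline: lysed right after pipetting
    CONTROL_1G = "CONTROL_1G"       # 1 g hardware control on the base plate
    CLINOSTAT_2D = "CLINOSTAT_2D"   # 60 rpm 2D clinorotation (vag)
    CENTRIFUGE_9G = "CENTRIFUGE_9G"
    # suborbital rocket mission
    CC = "CC"                       # incubator cell-culture control
    HW_1G_GC = "HW_1G_GC"           # flight-identical hardware, on ground
    IF_1G = "IF_1G"                 # 1 g in-flight reference centrifuge
    TX_HYP_G = "TX_HYP_G"           # 75 s launch hypergravity
    TX_UG = "TX_UG"                 # 5 min flight microgravity


GROUPS_BY_PLATFORM: dict[Platform, tuple[Group, ...]] = {
    Platform.GBF: (Group.BL, Group.CONTROL_1G, Group.CLINOSTAT_2D, Group.CENTRIFUGE_9G),
    Platform.TEXUS: (Group.CC, Group.HW_1G_GC, Group.IF_1G, Group.TX_HYP_G, Group.TX_UG),
}


@dataclass
class ExpressionMatrix:
    """Transcript-cluster x sample matrix of linear fluorescence intensities.

    Parameters
    ----------
    values
        DataFrame indexed by transcript-cluster id (``tc_id``) with one
        column per sample; strictly positive linear intensities.
    gene_symbols
        Per-TC gene symbol, aligned with ``values.index``; empty string for
        unannotated clusters.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate tc_id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = np.argwhere(~(np.isfinite(vals) & (vals > 0)))[0]
            raise ValueError(
                "non-positive intensity at "
                f"tc_id {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        self.gene_symbols = (
            self.gene_symbols.reindex(self.values.index).fillna("").astype(str)
        )

    @property
    def tc_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def annotated(self) -> pd.Series:
        """Boolean per TC: carries a non-empty gene symbol."""
        return self.gene_symbols != ""

    @property
    def n_tc(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), self.gene_symbols)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.gene_symbols.equals(
            other.gene_symbols
        )


@dataclass
class SampleSheet:
    """Assignment of samples to platform and experimental group."""

    table: pd.DataFrame  # columns: sample_id, platform, group

    def __post_init__(self) -> None:
        required = ["sample_id", "platform", "group"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        for _, row in self.table.iterrows():
            try:
                platform = Platform(row["platform"])
                group = Group(row["group"])
            except ValueError as exc:
                raise FormatError(f"sample {row['sample_id']!r}: {exc}") from exc
            if group not in GROUPS_BY_PLATFORM[platform]:
                raise FormatError(
                    f"sample {row['sample_id']!r}: group {group.value} invalid "
                    f"for platform {platform.value}"
                )

    def samples_in_group(self, group: Group | str) -> list[str]:
        group = Group(group)
        mask = self.table["group"] == group.value
        return self.table.loc[mask, "sample_id"].tolist()

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must appear exactly once in the sheet."""
        sheet_ids = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in sheet_ids]
        if missing:
            raise FormatError(f"samples missing from sheet: {missing}")


@dataclass
class TranscriptSet:
    """A set of transcript clusters with per-TC regulation direction.

    A tc_id appears at most once: a transcript cannot be simultaneously up-
    and downregulated within one comparison.
    """

    members: dict[str, str] = field(default_factory=dict)  # tc_id -> "up"/"down"
    source: str = ""

    def __post_init__(self) -> None:
        for tc, direction in self.members.items():
            if direction not in ("up", "down"):
                raise FormatError(f"tc {tc!r}: invalid direction {direction!r}")

    def tc_ids(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, tc_id: str) -> bool:
        return tc_id in self.members


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (tc_id, gene_symbol, then samples)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, keep_default_na=False)
    if list(df.columns[:2]) != ["tc_id", "gene_symbol"]:
        raise FormatError(
            f"{path}: first two columns must be tc_id, gene_symbol, "
            f"got {list(df.columns[:2])}"
        )
    sample_cols = list(df.columns[2:])
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    try:
        values = df[sample_cols].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity ({exc})") from exc
    values.index = pd.Index(df["tc_id"], name="tc_id")
    symbols = pd.Series(df["gene_symbol"].values, index=values.index)
    return ExpressionMatrix(values, symbols)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.insert(0, "tc_id", matrix.tc_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_transcript_set(path: str | Path) -> TranscriptSet:
    source = ""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# source="):
                    source = line[len("# source="):]
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:2] != ["tc_id", "direction"]:
                    raise FormatError(f"{path}: expected header tc_id, direction")
                header = fields
                continue
            rows.append((fields[0], fields[1]))
    members: dict[str, str] = {}
    for tc, direction in rows:
        if tc in members and members[tc] != direction:
            raise FormatError(f"{path}: tc {tc!r} listed as both up and down")
        members[tc] = direction
    return TranscriptSet(members, source)


def write_transcript_set(tset: TranscriptSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# source={tset.source}\n")
        fh.write("tc_id\tdirection\n")
        for tc in sorted(tset.members):
            fh.write(f"{tc}\t{tset.members[tc]}\n")


def write_count_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_count_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
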