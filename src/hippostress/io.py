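"""Readers and writers for the pipeline's plain-text formats.

Fold-change tables are TSV with a ``probe`` and ``gene`` column plus
one column per array comparison; column metadata (group, replicate,
dye orientation) is encoded in the column name as
``group.replicate.a`` / ``group.replicate.b`` (b = dye-swapped).
Two-color raw data can be read from Agilent Feature Extraction
tab-text (the FEATURES block; the header blocks are skipped).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from hippostress.contamination import StressIndexTable
from hippostress.diffexpr import FoldChangeMatrix, TwoColorArray
from hippostress.qpcr import WELL_COLUMNS, QpcrPlate

__all__ = [
    "read_foldchange_tsv",
    "write_foldchange_tsv",
    "parse_column_id",
    "read_agilent_feature_extraction",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "read_stress_index_tsv",
    "write_stress_index_tsv",
]


def parse_column_id(col: str) -> dict:
    """Split 'group.replicate[.a|b]' into metadata."""
    parts = col.split(".")
    if len(parts) == 3 and parts[2] in ("a", "b"):
        return {"group": parts[0], "replicate": parts[1], "swapped": parts[2] == "b"}
    if len(parts) == 2:
        return {"group": parts[0], "replicate": parts[1], "swapped": False}
    raise ValueError(f"cannot parse column id {col!r} as group.replicate[.a|b]")


def read_foldchange_tsv(path: str | Path) -> FoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str})
    for col in ("probe", "gene"):
        if col not in df.columns:
            raise ValueError(f"fold-change TSV lacks required column {col!r}")
    value_cols = [c for c in df.columns if c not in ("probe", "gene")]
    meta = pd.DataFrame([parse_column_id(c) for c in value_cols], index=value_cols)
    values = df.set_index("probe")[value_cols].astype(float)
    gene_map = df.set_index("probe")["gene"]
    return FoldChangeMatrix(values, meta, gene_map)


def write_foldchange_tsv(matrix: FoldChangeMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    gene = matrix.gene_map.reindex(out.index) if matrix.gene_map is not None \
        else pd.Series(out.index, index=out.index)
    out.insert(0, "gene", gene)
    out.index.name = "probe"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_agilent_feature_extraction(path: str | Path, array_id: str = "",
                                    stress_channel: str = "red",
                                    group: str = "", replicate: str = "") -> TwoColorArray:
    """Read one Agilent Feature Extraction tab-text file.

    The file is a stack of blocks (TYPE / FEPARAMS / STATS / FEATURES);
    only the FEATURES block is used.  Required columns: ProbeName,
    rMedianSignal, gMedianSignal, rBGMedianSignal, gBGMedianSignal.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("FEATURES\t") or line.split("\t", 1)[0] == "FEATURES":
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no FEATURES block found")
    block = [lines[header_idx]]
    for line in lines[header_idx + 1:]:
        first = line.split("\t", 1)[0]
        if first == "DATA":
            block.append(line)
        elif first in ("TYPE", "FEPARAMS", "STATS", "FEATURES", "*"):
            break
    df = pd.read_csv(_io.StringIO("\n".join(block)), sep="\t")
    required = ["ProbeName", "rMedianSignal", "gMedianSignal",
                "rBGMedianSignal", "gBGMedianSignal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: FEATURES block lacks columns {missing}")
    return TwoColorArray(
        array_id=array_id or Path(path).stem,
        probes=pd.Index(df["ProbeName"].astype(str)),
        red_fg=df["rMedianSignal"].to_numpy(dtype=float),
        red_bg=df["rBGMedianSignal"].to_numpy(dtype=float),
        green_fg=df["gMedianSignal"].to_numpy(dtype=float),
        green_bg=df["gBGMedianSignal"].to_numpy(dtype=float),
        stress_channel=stress_channel,
        group=group,
        replicate=replicate,
    )


def read_qpcr_csv(path: str | Path) -> QpcrPlate:
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR CSV lacks columns {missing}")
    df["pair_id"] = df["pair_id"].fillna("")
    df["arm"] = df["arm"].fillna("")
    return QpcrPlate(df)


def write_qpcr_csv(plate: QpcrPlate, path: str | Path) -> None:
    plate.wells.to_csv(path, index=False)


def read_stress_index_tsv(path: str | Path) -> StressIndexTable:
    return StressIndexTable(pd.read_csv(path, sep="\t"))


def write_stress_index_tsv(table: StressIndexTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
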