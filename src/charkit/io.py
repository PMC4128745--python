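"""Shared file I/O: assay CSV schemas, FASTA loading, JSON/CSV reports.

CSV dialect: comma-separated, UTF-8, '.' decimal, header mandatory.
Sequence coordinates are 1-based inclusive on input and converted to
0-based half-open internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidInputError, SchemaError
from .genotyping import GenomeRecord
from .kinetics import TiterSeries
from .resistance import ResistancePlating

__all__ = [
    "RunConfig",
    "read_titer_csv",
    "read_resistance_csv",
    "read_od_csv",
    "read_fasta",
    "read_intervals",
    "write_report",
    "format_scientific",
]

TITER_COLUMNS = ("assay", "phage_id", "replicate", "time_min", "titer_pfu_ml")
RESISTANCE_COLUMNS = ("phage_id", "replicate", "colonies", "cells_plated")
OD_COLUMNS = ("condition", "dilution_exponent", "time_h", "replicate", "od600")


@dataclass
class RunConfig:
    """Execution settings shared by the CLI subcommands."""

    seed: int | None = None
    out_dir: Path = Path(".")
    force: bool = False
    verbosity: int = 0
    overrides: dict = field(default_factory=dict)

    def output_path(self, name: str) -> Path:
        p = Path(self.out_dir) / name
        if p.exists() and not self.force:
            raise InvalidInputError(
                f"refusing to overwrite {p}; pass force=True / --force"
            )
        return p


def _load_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_titer_csv(path: str | Path) -> dict[tuple[str, str], TiterSeries]:
    """Load timestamped titers, one TiterSeries per (assay, phage_id).

    Rows are sorted by (replicate, time) on load; non-numeric titers raise
    with the offending row number.
    """
    df = _load_csv(path, TITER_COLUMNS)
    for col in ("time_min", "titer_pfu_ml"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col} at row {int(bad[0]) + 2}"
            )
        df[col] = vals
    if df["titer_pfu_ml"].isna().any() or df["time_min"].isna().any():
        raise SchemaError(f"{path}: empty time/titer cells")
    out: dict[tuple[str, str], TiterSeries] = {}
    for (assay, phage), grp in df.groupby(["assay", "phage_id"], sort=False):
        grp = grp.sort_values(["replicate", "time_min"])
        out[(assay, phage)] = TiterSeries(
            time=grp["time_min"].to_numpy(float),
            titer=grp["titer_pfu_ml"].to_numpy(float),
            replicate=grp["replicate"].to_numpy(int),
            assay=str(assay),
            phage_id=str(phage),
        )
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def read_resistance_csv(path: str | Path) -> dict[str, list[ResistancePlating]]:
    df = _load_csv(path, RESISTANCE_COLUMNS)
    out: dict[str, list[ResistancePlating]] = {}
    for phage, grp in df.groupby("phage_id", sort=False):
        out[str(phage)] = [
            ResistancePlating(
                replicate=int(r.replicate),
                colonies=int(r.colonies),
                cells_plated=float(r.cells_plated),
            )
            for r in grp.itertuples()
        ]
    return out


def read_od_csv(path: str | Path) -> pd.DataFrame:
    """OD600 table rows for the Appelmans analysis (see appelmans.ODTable)."""
    return _load_csv(path, OD_COLUMNS)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Load genomes from FASTA; ids are the first header token, sequences
    uppercased; characters outside ACGTN are rejected naming the record."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise SchemaError(
                    f"{path}: illegal character {ch!r} in record "
                    f"{rec.id!r} at position {i + 1}"
                )
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise SchemaError(f"{path}: no FASTA records")
    return records


def read_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """GFF-like tab file (seqid, start, end), 1-based inclusive coordinates."""
    path = Path(path)
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{ln}: expected seqid<TAB>start<TAB>end")
            seqid, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 1 or end < start:
                raise SchemaError(f"{path}:{ln}: bad interval {start}..{end}")
            out.setdefault(seqid, []).append((start, end))
    return out


def format_scientific(x: float, sig: int = 2) -> str:
    """Scientific notation with ``sig`` significant digits ('1.3e-09')."""
    if x == 0:
        return "0"
    return f"{x:.{sig - 1}e}"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(results: dict, path: str | Path, fmt: str = "json") -> Path:
    """Write an analysis report as JSON (stable key order) or CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        pd.DataFrame(_jsonable(results)).to_csv(path, index=False)
    else:
        raise InvalidInputError(f"unknown report format {fmt!r}")
    return path
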