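"""Readers and writers for the delimited text formats the package uses.

Genotype tables: header row of marker names, one row per individual,
cells in {A, H, B, NA} (A = homozygous recurrent parent, H =
heterozygous, B = homozygous donor parent).  Plant tables add integer
'fertile' and 'total' pollen-count columns.  Locus maps: name,
chromosome, position_cm columns.  Separators are sniffed (comma/tab).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .core import Locus
from .errors import GamselError

VALID_CODES = {"A", "H", "B", "NA"}
COUNT_COLUMNS = ("fertile", "total")


class ParseError(GamselError):
    """Malformed input file; message names row, column and value."""


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#",
                       dtype=str, skip_blank_lines=True)


def read_genotype_table(path) -> pd.DataFrame:
    """Read and validate a genotype (or plant) table.

    Genotype cells outside {A, H, B, NA} raise a ParseError naming the
    offending row (1-based, excluding the header), column and value.
    Count columns, when present, must be non-negative integers with
    fertile <= total.
    """
    table = _read_delimited(path)
    if table.empty and table.columns.empty:
        raise ParseError(f"{path}: empty genotype table")
    geno_cols = [c for c in table.columns if c not in COUNT_COLUMNS]
    for col in geno_cols:
        cells = table[col].fillna("NA").astype(str).str.strip().str.upper()
        bad = ~cells.isin(VALID_CODES)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: invalid genotype code {table[col][bad.idxmax()]!r} "
                f"at row {row}, column {col!r} (expected A/H/B/NA)")
        table[col] = cells
    for col in COUNT_COLUMNS:
        if col in table.columns:
            try:
                table[col] = table[col].astype(int)
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer {col!r} column: {exc}")
            if (table[col] < 0).any():
                raise ParseError(f"{path}: negative values in {col!r}")
    if all(c in table.columns for c in COUNT_COLUMNS):
        if (table["fertile"] > table["total"]).any():
            raise ParseError(f"{path}: fertile exceeds total")
    return table


def write_genotype_table(table: pd.DataFrame, path, seed=None) -> None:
    """Write a genotype/plant table; an optional seed goes into a header
    comment so simulated tables carry their provenance."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.to_csv(fh, index=False)


def read_locus_map(path) -> list[Locus]:
    """Locus map with name, chromosome and position_cm columns."""
    table = _read_delimited(path)
    required = {"name", "chromosome", "position_cm"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: locus map missing columns {sorted(missing)}")
    loci = []
    for _, row in table.iterrows():
        pos = row["position_cm"]
        loci.append(Locus(str(row["name"]), str(row["chromosome"]),
                          None if pd.isna(pos) else float(pos)))
    return loci


def read_count_table(path) -> pd.DataFrame:
    """Pre-aggregated class counts: class, observed[, expected_ratio]."""
    table = _read_delimited(path)
    if "class" not in table.columns or "observed" not in table.columns:
        raise ParseError(f"{path}: count table needs 'class' and 'observed'")
    table["observed"] = table["observed"].astype(int)
    if "expected_ratio" in table.columns:
        table["expected_ratio"] = table["expected_ratio"].astype(float)
    return table


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
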