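"""Readers and writers for the pipeline's text formats.

All tables are UTF-8 with a mandatory header row.  Dialects:

* pileup TSV — 9 tab-separated columns ``seq_id, pos, ref, A, C, G, T,
  depth, mapq``; positions are 1-based.
* counts TSV — ``gene_id, count_SH, count_YK`` (non-negative integers).
* metabolite CSV — ``metabolite, class, experiment, genotype,
  replicate, value`` (long format).
* qPCR CSVs — dilution series ``primer, concentration, replicate, ct``
  and samples ``gene, accession, replicate, ct_target, ct_reference``
  (an empty CT field means no amplification and is read as NaN).

Parsing is strict: a malformed row raises :class:`TableFormatError`
naming the file, 1-based line number, and offending column.  Unknown
extra columns are preserved on round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class TableFormatError(ValueError):
    """Malformed input table; message carries file, line, and column."""


def _fail(path, row_index: int, column: str, message: str):
    # +2: header line plus 1-based numbering
    raise TableFormatError(f"{path}, line {row_index + 2}, column {column!r}: {message}")


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df, path, column, minimum=None, integer=False):
    col = pd.to_numeric(df[column], errors="coerce")
    bad = col.isna() & df[column].notna()
    if df[column].isna().any():
        bad |= df[column].isna()
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]), column, "not a number")
    if integer and not np.array_equal(col, col.astype(np.int64)):
        idx = int(np.flatnonzero((col != col.astype(np.int64)).to_numpy())[0])
        _fail(path, idx, column, "not an integer")
    if minimum is not None and (col < minimum).any():
        idx = int(np.flatnonzero((col < minimum).to_numpy())[0])
        _fail(path, idx, column, f"below minimum {minimum}")
    return col.astype(np.int64) if integer else col


PILEUP_COLUMNS = ["seq_id", "pos", "ref", "A", "C", "G", "T", "depth", "mapq"]


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "ref": str})
    _require_columns(df, PILEUP_COLUMNS, path)
    for col in ("pos", "A", "C", "G", "T", "depth", "mapq"):
        df[col] = _check_numeric(df, path, col, minimum=1 if col == "pos" else 0, integer=True)
    bad = ~df["ref"].isin(list("ACGT"))
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]), "ref", "reference base not ACGT")
    return df


def write_pileup(df: pd.DataFrame, path) -> None:
    ordered = [c for c in PILEUP_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, sep="\t", index=False)


COUNT_COLUMNS = ["gene_id", "count_SH", "count_YK"]


def read_counts(path) -> pd.DataFrame:
    """Counts table indexed by gene id with columns SH, YK."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _require_columns(df, COUNT_COLUMNS, path)
    for col in ("count_SH", "count_YK"):
        df[col] = _check_numeric(df, path, col, minimum=0, integer=True)
    if df["gene_id"].duplicated().any():
        idx = int(np.flatnonzero(df["gene_id"].duplicated().to_numpy())[0])
        _fail(path, idx, "gene_id", "duplicate gene id")
    out = df.set_index("gene_id").rename(columns={"count_SH": "SH", "count_YK": "YK"})
    return out


def write_counts(table: pd.DataFrame, path) -> None:
    """Accepts either the indexed (SH/YK) or flat (gene_id, count_*) layout."""
    out = table.rename(columns={"SH": "count_SH", "YK": "count_YK"})
    if "gene_id" not in out.columns:
        out.index.name = "gene_id"
        out = out.reset_index()
    out.to_csv(path, sep="\t", index=False)


METABOLITE_COLUMNS = ["metabolite", "class", "experiment", "genotype", "replicate", "value"]


def read_metabolites(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"metabolite": str, "class": str, "genotype": str})
    _require_columns(df, METABOLITE_COLUMNS, path)
    df["experiment"] = _check_numeric(df, path, "experiment", minimum=1, integer=True)
    df["replicate"] = _check_numeric(df, path, "replicate", minimum=1, integer=True)
    df["value"] = _check_numeric(df, path, "value", minimum=0.0)
    bad = ~df["genotype"].isin(("SH", "YK", "F1"))
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]), "genotype", "must be SH, YK, or F1")
    key = df[["metabolite", "experiment", "genotype", "replicate"]]
    if key.duplicated().any():
        idx = int(np.flatnonzero(key.duplicated().to_numpy())[0])
        _fail(path, idx, "replicate", "duplicate (metabolite, experiment, genotype, replicate)")
    return df


def write_metabolites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_qpcr_dilutions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"primer": str})
    _require_columns(df, ["primer", "concentration", "replicate", "ct"], path)
    conc = _check_numeric(df, path, "concentration")
    if (conc <= 0).any():
        _fail(path, int(np.flatnonzero((conc <= 0).to_numpy())[0]), "concentration",
              "must be strictly positive")
    df["concentration"] = conc
    df["ct"] = _check_numeric(df, path, "ct")
    return df


def read_qpcr_samples(path) -> pd.DataFrame:
    """Sample CTs; an empty ct_target field is the no-amplification sentinel."""
    df = pd.read_csv(path, dtype={"gene": str, "accession": str})
    _require_columns(
        df, ["gene", "accession", "replicate", "ct_target", "ct_reference"], path
    )
    df["ct_target"] = pd.to_numeric(df["ct_target"], errors="coerce")
    bad = df["ct_reference"].isna()
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]), "ct_reference", "missing CT")
    df["ct_reference"] = _check_numeric(df, path, "ct_reference")
    zero = df["ct_target"] == 0
    if zero.any():
        _fail(path, int(np.flatnonzero(zero.to_numpy())[0]), "ct_target",
              "CT=0 is not a valid no-amplification encoding (leave the field empty)")
    return df


def write_qpcr(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_category_map(path) -> dict[str, list[str]]:
    """Mapping TSV (item_id, category); items may repeat for multi-assignment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["item_id", "category"], path)
    bad = df["category"].isna() | (df["category"].str.len() == 0)
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]), "category", "empty label")
    mapping: dict[str, list[str]] = {}
    for item, cat in zip(df["item_id"], df["category"]):
        mapping.setdefault(item, []).append(cat)
    return mapping


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
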