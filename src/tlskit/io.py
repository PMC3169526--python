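"""File readers/writers: FASTA (clone reads), TSV tables, JSON configs.

TSV files are tab-delimited with a header row, UTF-8, no quoting; CRLF
input is accepted and normalized.  FASTA headers carry the clone id up to
the first whitespace.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IOValidationError",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_json_config",
    "read_manifest",
    "read_counts",
]

MANIFEST_COLUMNS = ["clone_id", "condition_id", "replicate_id", "construct_id"]
COUNTS_COLUMNS = ["condition_id", "replicate_id", "kanR", "cmR"]


class IOValidationError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; empty file or empty record is an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise IOValidationError(f"{path}: no FASTA records")
    for rid, seq in records:
        if not seq:
            raise IOValidationError(f"{path}: record {rid!r} has an empty sequence")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise IOValidationError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_tsv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV with header; missing required columns are named in the error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TSV not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise IOValidationError(f"{path}: empty TSV") from None
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise IOValidationError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_json_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IOValidationError(f"{path}: invalid JSON at line {exc.lineno}") from None
    if not isinstance(data, dict):
        raise IOValidationError(f"{path}: top-level JSON must be an object")
    return data


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=MANIFEST_COLUMNS)
    if df["clone_id"].duplicated().any():
        dup = df.loc[df["clone_id"].duplicated(), "clone_id"].iloc[0]
        raise IOValidationError(f"{path}: duplicate clone_id {dup!r}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=COUNTS_COLUMNS)
    for col in ("kanR", "cmR"):
        try:
            df[col] = df[col].astype(int)
        except ValueError:
            bad = df.loc[~df[col].str.fullmatch(r"\d+"), col].iloc[0]
            raise IOValidationError(f"{path}: non-integer {col} value {bad!r}") from None
        if (df[col] < 0).any():
            raise IOValidationError(f"{path}: negative {col}")
    return df
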