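"""Readers and writers for the pipeline's external formats.

Everything on disk is plain text: FASTA for sequences (via Bio.SeqIO) and
header-carrying TSV for coordinates, annotations and join tables (via
pandas).  Line endings are normalised on read; duplicate FASTA ids and
missing schema columns are hard errors; unknown TSV columns are preserved.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import XorfeomeError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "file_checksum",
]


def read_fasta(path) -> Dict[str, str]:
    """Ordered mapping of id -> sequence; duplicate ids are an error."""
    path = Path(path)
    if not path.exists():
        raise XorfeomeError(f"missing input file: {path}")
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise XorfeomeError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(records: Dict[str, str], path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_table(path, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """TSV with a mandatory header; ``required`` columns must be present."""
    path = Path(path)
    if not path.exists():
        raise XorfeomeError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise XorfeomeError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
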