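"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; tables via pandas with explicit schema checks so a
missing column fails with its name rather than a downstream KeyError.
All tables are UTF-8; CSV on input, TSV on output; CRLF input is accepted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .burial import HydrophobicityScale
from .library import CodonUsageTable

__all__ = [
    "SchemaError",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_scale",
    "read_codon_usage",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, sequence) pairs.

    The record id is the header token up to the first whitespace.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_table(path, required: list[str], sep: str = ",") -> pd.DataFrame:
    """Read a delimited table and verify the required columns exist."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {', '.join(missing)}; found {list(df.columns)}"
        )
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """TSV with header, no index — the output dialect everywhere."""
    df.to_csv(path, sep="\t", index=False)


def read_scale(path, name: str | None = None) -> HydrophobicityScale:
    """Two-column TSV (one-letter residue, hydrophobicity) -> scale."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["aa", "value"])
    values = {str(r.aa).strip().upper(): float(r.value) for r in df.itertuples()}
    return HydrophobicityScale(name=name or Path(path).stem, values=values)


def read_codon_usage(path, organism: str | None = None) -> CodonUsageTable:
    """Kazusa-style TSV (codon, aa, fraction) -> usage table.

    Fractions are relative within each synonymous family; the ``aa``
    column is informational and cross-checked against translation.
    """
    df = read_table(path, required=["codon", "fraction"], sep="\t")
    freq = {str(c).strip().upper(): float(f) for c, f in zip(df["codon"], df["fraction"])}
    return CodonUsageTable(organism=organism or Path(path).stem, freq=freq)
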