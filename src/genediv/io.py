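"""Reading and writing of the package's on-disk formats.

Sequences travel as Biopython ``SeqRecord`` objects (FASTA wrapped at 60
columns, FASTQ with Phred+33 qualities); tabular data as pandas DataFrames
serialised to TSV with a header row.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file, rejecting duplicate sequence ids.

    Raises
    ------
    InputError
        If two records share an id (names the id) or a record is empty.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise InputError(f"empty sequence for id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, 60-column wrapped (Biopython default)."""
    SeqIO.write(list(records), str(path), "fasta")


def write_fastq(
    records: Iterable[SeqRecord], path: str | os.PathLike, quality: int = 30
) -> None:
    """Write records as FASTQ with a constant Phred quality."""
    out = []
    for rec in records:
        if "phred_quality" not in rec.letter_annotations:
            rec = SeqRecord(rec.seq, id=rec.id, description=rec.description)
            rec.letter_annotations["phred_quality"] = [quality] * len(rec.seq)
        out.append(rec)
    SeqIO.write(out, str(path), "fastq")


def read_fastq(path: str | os.PathLike) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def make_record(seq: str, rec_id: str, description: str = "") -> SeqRecord:
    """Convenience constructor for a SeqRecord from a plain string."""
    return SeqRecord(Seq(seq), id=rec_id, description=description)


def read_table(
    path: str | os.PathLike,
    required: Sequence[str] | None = None,
    index_col=None,
) -> pd.DataFrame:
    """Read a TSV table, checking for required columns by name."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(
                f"table {path} is missing required column(s): {', '.join(missing)}"
            )
    return df


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, index: bool = False
) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
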