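"""Sequence records and FASTA input/output.

A :class:`SequenceRecord` is the minimal container used throughout the
package for one protein or nucleotide sequence; FASTA round-trips go
through Biopython's ``SeqIO``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with an identifier and optional taxon metadata."""

    id: str
    seq: str
    taxon: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record requires a non-empty id")
        if not self.seq:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.taxon or "") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
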