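"""Nucleotide sequence records and FASTA input/output.

A :class:`SequenceRecord` is the unit every pipeline stage consumes: an
identified, uppercase IUPAC DNA string with a free-form provenance tag.
FASTA files are read and written through Biopython; on write, sequence
lines are wrapped at 60 columns, and on read the first whitespace-delimited
header token becomes the record id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Unambiguous bases plus the IUPAC ambiguity alphabet.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")
_VALID_RE = re.compile(r"^[ACGTNRYSWKMBDHV]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence with provenance.

    Parameters
    ----------
    id : str
        Unique identifier (first header token in FASTA).
    residues : str
        Uppercase IUPAC DNA, non-empty.
    source_tag : str
        Free-form provenance label (e.g. ``"ncbi_est"``, ``"trimmed"``).
    """

    id: str
    residues: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        up = self.residues.upper()
        if up != self.residues:
            object.__setattr__(self, "residues", up)
        if not _VALID_RE.match(self.residues):
            bad = sorted(set(self.residues) - IUPAC_DNA)
            raise ValueError(f"{self.id}: non-IUPAC characters {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)

    def tagged(self, tag: str) -> "SequenceRecord":
        return replace(self, source_tag=tag)


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, source_tag: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into records; ids must be unique within the file."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), source_tag))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequence lines at 60 columns."""
    bio = (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def iter_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(rec.id, str(rec.seq).upper())
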