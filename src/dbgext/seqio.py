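"""Sequence I/O and core utilities.

FASTA/FASTQ parsing is delegated to :mod:`Bio.SeqIO`; this module wraps the
records in small domain types and implements the quality-trimming rule used
throughout the pipeline: a read is cut immediately before the first base
whose Phred quality drops below a threshold (default 15), discarding that
base and everything to its right.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_QUALITY_THRESHOLD = 15


@dataclass
class Read:
    """A sequencing read with optional per-base Phred qualities."""

    id: str
    seq: str
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )


@dataclass
class TranscriptRecord:
    """One database record: a nucleotide transcript or a protein sequence."""

    id: str
    seq: str
    alphabet: str = "nucleotide"  # "nucleotide" | "protein"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


def trim_read(read: Read, threshold: int = DEFAULT_QUALITY_THRESHOLD) -> Read:
    """Trim ``read`` at the first position whose quality is below ``threshold``.

    All positions including and to the right of the first below-threshold
    position are removed.  Reads without qualities (FASTA input) pass through
    unchanged.  Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if read.quals is None:
        return read
    cut = len(read.seq)
    for i, q in enumerate(read.quals):
        if q < threshold:
            cut = i
            break
    if cut == len(read.seq):
        return read
    return Read(read.id, read.seq[:cut], read.quals[:cut])


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    if not set(seq) <= NUCLEOTIDES:
        bad = sorted(set(seq) - NUCLEOTIDES)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _infer_alphabet(seq: str) -> str:
    return "nucleotide" if set(seq) <= NUCLEOTIDES else "protein"


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[TranscriptRecord]:
    """Load a (possibly line-wrapped) FASTA file.

    ``alphabet`` may be ``"nucleotide"``, ``"protein"`` or ``"auto"`` (infer
    from content, with the constraint that it must be consistent across the
    whole file).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        ab = _infer_alphabet(seq) if alphabet == "auto" else alphabet
        records.append(TranscriptRecord(rec.id, seq, ab))
    if alphabet == "auto" and len({r.alphabet for r in records}) > 1:
        raise ValueError(f"{path}: mixed nucleotide and protein records")
    return records


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (Phred+33)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            rec.id,
            str(rec.seq).upper(),
            list(rec.letter_annotations["phred_quality"]),
        )


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqrecs = (
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    def gen():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = r.quals or [40] * len(r.seq)
            yield rec

    SeqIO.write(gen(), str(path), "fastq")
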