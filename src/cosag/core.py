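"""Core domain types and sequence/IO helpers shared across the pipeline.

A single-amplified genome (SAG) is represented as a :class:`GenomeAssembly`
(a bag of contigs) plus a :class:`ReadSet` (its amplified, sequenced reads).
All downstream stages — read QC, completeness estimation, similarity,
strain grouping and chimera cleaning — operate on these two containers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a parameter or input violates a documented precondition."""


@dataclass(frozen=True)
class Contig:
    contig_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """A genome (SAG, CoSAG, or reference) as a list of contigs."""

    sag_id: str
    contigs: list[Contig]
    source: str = "sag"  # sag | cosag | reference | mag

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate contig ids in assembly {self.sag_id!r}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def sequences(self) -> Iterator[str]:
        for c in self.contigs:
            yield c.seq

    def n50(self) -> int:
        lengths = sorted((len(c) for c in self.contigs), reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for n in lengths:
            acc += n
            if acc >= half:
                return n
        return 0

    def gc_fraction(self) -> float:
        gc = sum(c.seq.count("G") + c.seq.count("C") for c in self.contigs)
        total = self.total_length
        return gc / total if total else 0.0


@dataclass
class Read:
    """A single read with per-base Phred qualities.

    ``mate`` is 1 or 2 for paired reads, 0 for unpaired.
    """

    read_id: str
    seq: str
    quals: list[int]
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ConfigurationError(
                f"read {self.read_id!r}: sequence/quality length mismatch "
                f"({len(self.seq)} vs {len(self.quals)})"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0

    def slice(self, start: int, end: int, new_id: str | None = None) -> "Read":
        """Substring of the read with qualities sliced in register."""
        return Read(
            read_id=new_id if new_id is not None else self.read_id,
            seq=self.seq[start:end],
            quals=self.quals[start:end],
            mate=self.mate,
        )


@dataclass
class ReadSet:
    """An ordered collection of reads with provenance (the SAG they came from)."""

    sag_id: str
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate read ids in read set {self.sag_id!r}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def with_reads(self, reads: list[Read]) -> "ReadSet":
        return ReadSet(sag_id=self.sag_id, reads=reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ IO.  Plain-text formats only; .gz handled transparently.
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, sag_id: str | None = None, source: str = "sag") -> GenomeAssembly:
    from Bio import SeqIO

    path = Path(path)
    contigs = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            contigs.append(Contig(rec.id, str(rec.seq).upper()))
    return GenomeAssembly(sag_id=sag_id or path.stem, contigs=contigs, source=source)


def write_fasta(asm: GenomeAssembly, path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for c in asm.contigs:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def read_fastq(path: str | Path, sag_id: str | None = None) -> ReadSet:
    from Bio import SeqIO

    path = Path(path)
    reads = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                Read(
                    read_id=rec.id,
                    seq=str(rec.seq).upper(),
                    quals=list(rec.letter_annotations["phred_quality"]),
                )
            )
    return ReadSet(sag_id=sag_id or path.stem, reads=reads)


def write_fastq(rs: ReadSet | Iterable[Read], path: str | Path) -> None:
    reads = rs.reads if isinstance(rs, ReadSet) else list(rs)
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")
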