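"""Read quality control: right-end Phred quality trimming, length/N/mean-quality
filters, and decoy-based host-read removal.

The filters mirror the standard short-read QC conventions for single-cell
genomic reads: trim low-quality right ends at Q10, then keep reads of at
least 40 bp with at most one N and mean quality >= Q15; reads that align to
the host decoy genome over most of their length at high identity are removed
as host contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .align import KmerIndex, map_sequence
from .core import ConfigurationError, GenomeAssembly, Read, ReadSet


@dataclass
class QcParams:
    trim_quality: int = 10
    min_length: int = 40
    max_ns: int = 1
    min_avg_quality: float = 15.0
    decoy_min_identity: float = 0.95
    decoy_min_coverage: float = 0.60

    def __post_init__(self) -> None:
        if min(self.trim_quality, self.min_length, self.max_ns) < 0 or self.min_avg_quality < 0:
            raise ConfigurationError("QC parameters must be non-negative")
        if not 0.0 <= self.decoy_min_identity <= 1.0:
            raise ConfigurationError("decoy_min_identity must be in [0, 1]")


@dataclass
class QcReport:
    sag_id: str = ""
    reads_in: int = 0
    reads_trimmed: int = 0
    removed_by_filter: int = 0
    removed_as_host: int = 0
    reads_out: int = 0

    def to_tsv_row(self) -> str:
        return (
            f"{self.sag_id}\t{self.reads_in}\t{self.reads_trimmed}\t"
            f"{self.removed_by_filter}\t{self.removed_as_host}\t{self.reads_out}"
        )

    TSV_HEADER = "sag_id\treads_in\treads_trimmed\tremoved_by_filter\tremoved_as_host\treads_out"


def quality_trim_right(read: Read, trim_quality: int = 10) -> Read:
    """Trim the right end by the classic Phred-style rule: cut at the
    position maximizing the sum of (trim_quality - Q_i) over the removed
    suffix; bases before the cut are untouched."""
    best_cut = len(read)  # cut index: keep read[:cut]
    best_score = 0
    score = 0
    for i in range(len(read) - 1, -1, -1):
        score += trim_quality - read.quals[i]
        if score > best_score:
            best_score = score
            best_cut = i
    if best_cut == len(read):
        return read
    return read.slice(0, best_cut)


def _passes_filters(read: Read, p: QcParams) -> bool:
    if len(read) < p.min_length:
        return False
    if read.seq.count("N") > p.max_ns:
        return False
    if read.mean_quality() < p.min_avg_quality:
        return False
    return True


def filter_reads(rs: ReadSet, p: QcParams | None = None, report: QcReport | None = None) -> ReadSet:
    """Trim right ends, then keep exactly the reads passing the length, N-count
    and mean-quality bounds; order preserved.

    Paired policy: if either mate of a pair fails, both are dropped (pairs
    share a read id stem; unpaired reads are judged alone).
    """
    p = p or QcParams()
    trimmed: list[Read] = []
    n_trimmed = 0
    for r in rs:
        t = quality_trim_right(r, p.trim_quality)
        if len(t) != len(r):
            n_trimmed += 1
        trimmed.append(t)
    keep_flags = [_passes_filters(r, p) for r in trimmed]
    # drop both mates when either fails
    by_stem: dict[str, list[int]] = {}
    for i, r in enumerate(trimmed):
        if r.mate in (1, 2):
            by_stem.setdefault(r.read_id.rsplit("/", 1)[0], []).append(i)
    for idxs in by_stem.values():
        if not all(keep_flags[i] for i in idxs):
            for i in idxs:
                keep_flags[i] = False
    kept = [r for r, k in zip(trimmed, keep_flags) if k]
    if report is not None:
        report.sag_id = rs.sag_id
        report.reads_in = len(rs)
        report.reads_trimmed = n_trimmed
        report.removed_by_filter = len(rs) - len(kept)
        report.reads_out = len(kept)
    return rs.with_reads(kept)


def remove_host_reads(
    rs: ReadSet,
    decoy: GenomeAssembly | KmerIndex,
    p: QcParams | None = None,
    report: QcReport | None = None,
) -> ReadSet:
    """Remove reads whose best local alignment to the decoy covers at least
    ``decoy_min_coverage`` of the read at identity >= ``decoy_min_identity``."""
    p = p or QcParams()
    if isinstance(decoy, KmerIndex):
        index = decoy
    else:
        if not decoy.contigs or decoy.total_length == 0:
            raise ConfigurationError("empty decoy assembly")
        index = KmerIndex(decoy)
    kept: list[Read] = []
    n_host = 0
    for r in rs:
        segments = map_sequence(r.seq, r.read_id, index, min_identity=p.decoy_min_identity)
        covered = sum(s.read_span for s in segments if s.identity >= p.decoy_min_identity)
        if len(r) > 0 and covered / len(r) >= p.decoy_min_coverage:
            n_host += 1
        else:
            kept.append(r)
    if report is not None:
        report.removed_as_host = n_host
        report.reads_out = len(kept)
    return rs.with_reads(kept)


def qc_readset(
    rs: ReadSet, p: QcParams | None = None, decoy: GenomeAssembly | KmerIndex | None = None
) -> tuple[ReadSet, QcReport]:
    """Full QC for one read set: trim + filter, then optional host removal."""
    p = p or QcParams()
    report = QcReport()
    out = filter_reads(rs, p, report)
    if decoy is not None:
        out = remove_host_reads(out, decoy, p, report)
    return out, report


def write_qc_report(reports: list[QcReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(QcReport.TSV_HEADER + "\n")
        for r in reports:
            fh.write(r.to_tsv_row() + "\n")
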