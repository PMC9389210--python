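"""Assembly statistics, marker-based completeness/contamination estimation,
and quality-tier assignment.

Completeness and contamination follow single-copy marker semantics: a marker
set of genes expected exactly once per genome is searched against the
assembly; the fraction found estimates completeness, the fraction with extra
disjoint copies estimates contamination. Tiers follow the conventional
high/medium/low-quality thresholds (HQ: >90% complete, <5% contaminated;
MQ: >=50%, <10%; LQ: <50%, <10%; anything at >=10% contamination is
excluded from analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import edlib

from .align import KmerIndex, _chain_hits
from .core import ConfigurationError, GenomeAssembly, revcomp

MIN_CONTIG_LENGTH = 1000


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    full_length: bool
    seq: str  # extracted assembly sequence, marker orientation


@dataclass
class GenomeQuality:
    sag_id: str
    completeness: float  # percent
    contamination: float  # percent
    tier: str
    markers_found: int
    markers_duplicated: int
    markers_expected: int


def filter_contigs(asm: GenomeAssembly, min_len: int = MIN_CONTIG_LENGTH) -> GenomeAssembly:
    """Retain exactly the contigs of at least ``min_len`` bp, order preserved."""
    kept = [c for c in asm.contigs if len(c) >= min_len]
    return GenomeAssembly(asm.sag_id, kept, asm.source)


def _evaluate_window(
    marker_seq: str, window: str, min_identity: float, min_coverage: float
) -> tuple[float, bool, tuple[int, int] | None]:
    """Best qualifying alignment of a marker against a candidate window.

    Tries the full marker first; if the marker is truncated at a contig or
    dropout boundary, a prefix or suffix covering ``min_coverage`` of the
    marker may still qualify. Returns (identity, full_length, locations).
    """
    L = len(marker_seq)
    k_full = math.floor((1.0 - min_identity) * L)
    res = edlib.align(marker_seq, window, mode="HW", task="locations", k=k_full)
    if res["editDistance"] >= 0:
        loc = res["locations"][0]
        return 1.0 - res["editDistance"] / L, True, (loc[0], loc[1] + 1)
    part = math.ceil(min_coverage * L)
    k_part = math.floor((1.0 - min_identity) * part)
    for sub in (marker_seq[:part], marker_seq[-part:]):
        res = edlib.align(sub, window, mode="HW", task="locations", k=k_part)
        if res["editDistance"] >= 0:
            loc = res["locations"][0]
            return 1.0 - res["editDistance"] / part, False, (loc[0], loc[1] + 1)
    return 0.0, False, None


def find_marker_hits(
    asm: GenomeAssembly | KmerIndex,
    markers: GenomeAssembly,
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
    pad: int = 64,
) -> dict[str, list[MarkerHit]]:
    """Locate qualifying hits of each single-copy marker in the assembly.

    A marker counts as present where it has a local alignment at
    >= ``min_identity`` identity over >= ``min_coverage`` of its length.
    Candidate loci come from exact k-mer seed chains on both strands; each
    candidate is verified with an exact (edlib) alignment. Overlapping
    candidates are merged so each locus is counted once; extra disjoint loci
    are the duplicates contamination is estimated from.
    """
    if not markers.contigs:
        raise ConfigurationError("empty marker set")
    index = asm if isinstance(asm, KmerIndex) else KmerIndex(asm)
    hits_by_marker: dict[str, list[MarkerHit]] = {}
    for marker in markers.contigs:
        L = len(marker.seq)
        candidates: list[MarkerHit] = []
        for strand, query in (("+", marker.seq), ("-", revcomp(marker.seq))):
            for chain in _chain_hits(query, index, step=2):
                if chain.n_seeds < 3:
                    continue
                contig = index.contigs[chain.contig_idx]
                ts = max(0, chain.diag - pad)
                te = min(len(contig.seq), chain.diag + L + pad)
                window = contig.seq[ts:te]
                ident, full, loc = _evaluate_window(query, window, min_identity, min_coverage)
                if loc is None:
                    continue
                hs, he = ts + loc[0], ts + loc[1]
                seq = contig.seq[hs:he]
                if strand == "-":
                    seq = revcomp(seq)
                candidates.append(
                    MarkerHit(marker.contig_id, contig.contig_id, hs, he, strand, ident, full, seq)
                )
        # merge overlapping candidates (same locus seen from several chains/strands)
        candidates.sort(key=lambda h: (-h.identity, h.contig_id, h.start))
        accepted: list[MarkerHit] = []
        for h in candidates:
            if any(
                a.contig_id == h.contig_id
                and min(a.end, h.end) - max(a.start, h.start) > 0.2 * L
                for a in accepted
            ):
                continue
            accepted.append(h)
        if accepted:
            hits_by_marker[marker.contig_id] = sorted(
                accepted, key=lambda h: (h.contig_id, h.start)
            )
    return hits_by_marker


def estimate_quality(
    asm: GenomeAssembly,
    markers: GenomeAssembly,
    hits: dict[str, list[MarkerHit]] | None = None,
) -> GenomeQuality:
    """Marker-based completeness/contamination and quality tier for one assembly."""
    if not markers.contigs:
        raise ConfigurationError("empty marker set")
    if not asm.contigs:
        raise ConfigurationError(f"empty assembly {asm.sag_id!r}")
    if hits is None:
        hits = find_marker_hits(asm, markers)
    expected = len(markers.contigs)
    found = len(hits)
    duplicated = sum(len(h) - 1 for h in hits.values())
    completeness = 100.0 * found / expected
    contamination = 100.0 * duplicated / expected
    return GenomeQuality(
        sag_id=asm.sag_id,
        completeness=completeness,
        contamination=contamination,
        tier=assign_tier(completeness, contamination),
        markers_found=found,
        markers_duplicated=duplicated,
        markers_expected=expected,
    )


def assign_tier(completeness: float, contamination: float) -> str:
    """Quality tier from completeness/contamination percentages.

    HQ requires strictly more than 90% completeness and strictly less than
    5% contamination; MQ at least 50% and under 10%; LQ under 50% and under
    10%; at 10% contamination or more the genome is excluded.
    """
    if contamination >= 10.0:
        return "excluded"
    if completeness > 90.0 and contamination < 5.0:
        return "HQ"
    if completeness >= 50.0:
        return "MQ"
    return "LQ"


def select_for_grouping(q: GenomeQuality) -> bool:
    """Strain-grouping candidate rule: completeness >= 20% and contamination < 10%."""
    return q.completeness >= 20.0 and q.contamination < 10.0


def quality_table_row(asm: GenomeAssembly, q: GenomeQuality) -> str:
    return (
        f"{q.sag_id}\t{q.completeness:.2f}\t{q.contamination:.2f}\t{q.tier}\t"
        f"{asm.n_contigs}\t{asm.total_length}\t{asm.n50()}\t{100 * asm.gc_fraction():.2f}"
    )


QUALITY_TSV_HEADER = "sag_id\tcompleteness\tcontamination\ttier\tn_contigs\ttotal_bp\tN50\tGC"


def write_quality_table(
    rows: list[tuple[GenomeAssembly, GenomeQuality]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(QUALITY_TSV_HEADER + "\n")
        for asm, q in rows:
            fh.write(quality_table_row(asm, q) + "\n")
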