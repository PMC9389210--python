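"""Chimera detection and read cleaning by iterative cross-reference mapping.

MDA produces chimeric molecules joining non-contiguous genomic loci. Within
a same-strain group, each member's reads are mapped against every other
member's assembly: a read that aligns end-to-end somewhere is clean; a read
that is only partially aligned is a potential chimera and is split into its
aligned and unaligned fragments, with fragments shorter than 20 bp
discarded. Cycles of mapping and splitting repeat until a fixpoint (no read
split) or a cycle cap.

A full-alignment veto protects clean reads that happen to span a dropout
boundary of one partner: a genuine chimera cannot align end-to-end to any
real genome, so a read fully explained by ANY partner is kept whole, and
only reads not fully explained by any partner are split — by the partner
whose alignment fragments them the most (a junction is evidence wherever it
is visible, and partner dropout can hide it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentSegment, KmerIndex, map_sequence
from .core import ConfigurationError, GenomeAssembly, Read, ReadSet
from .strain_clustering import StrainGroup

logger = logging.getLogger(__name__)


@dataclass
class SplitParams:
    min_fragment: int = 20
    full_align_fraction: float = 0.95
    min_identity: float = 0.90
    max_cycles: int = 5

    def __post_init__(self) -> None:
        if self.min_fragment < 1:
            raise ConfigurationError("min_fragment must be >= 1")
        for name in ("full_align_fraction", "min_identity"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if self.max_cycles < 1:
            raise ConfigurationError("max_cycles must be >= 1")


def map_read(
    read: Read, target: GenomeAssembly | KmerIndex, p: SplitParams | None = None
) -> list[AlignmentSegment]:
    """Maximal non-overlapping high-identity alignments of a read to a
    same-group partner assembly; empty list = unaligned."""
    p = p or SplitParams()
    index = target if isinstance(target, KmerIndex) else KmerIndex(target)
    return map_sequence(read.seq, read.read_id, index, min_identity=p.min_identity)


def classify_and_split(
    read: Read, segments: list[AlignmentSegment], p: SplitParams | None = None
) -> tuple[list[Read], bool]:
    """Classify a read against one partner's alignment evidence.

    Returns (fragments, was_split). A read with no alignment is returned
    whole (unmapped is not evidence of chimerism — the locus may simply be
    absent from the partner); a read with one alignment covering at least
    ``full_align_fraction`` of it is clean and returned whole; otherwise the
    read is cut at segment boundaries into aligned and interstitial
    unaligned fragments, each a contiguous substring with qualities sliced
    in register, and fragments shorter than ``min_fragment`` are discarded.
    """
    p = p or SplitParams()
    n = len(read)
    if not segments:
        return [read], False
    if any(s.read_span >= p.full_align_fraction * n for s in segments):
        return [read], False
    cuts = sorted({0, n, *(s.read_start for s in segments), *(s.read_end for s in segments)})
    fragments = []
    for start, end in zip(cuts, cuts[1:]):
        if end - start >= p.min_fragment:
            fragments.append(read.slice(start, end, new_id=f"{read.read_id}:{start}-{end}"))
    return fragments, True


@dataclass
class CleaningReport:
    group_id: str = ""
    cycles_run: int = 0
    per_member: dict[str, dict[str, int]] = field(default_factory=dict)

    def member(self, sag_id: str) -> dict[str, int]:
        return self.per_member.setdefault(
            sag_id,
            {"reads_in": 0, "clean": 0, "split": 0, "fragments_out": 0, "bases_in": 0,
             "bases_out": 0, "bases_discarded": 0},
        )

    TSV_HEADER = (
        "group_id\tsag_id\treads_in\tclean\tsplit\tfragments_out\t"
        "bases_in\tbases_out\tbases_discarded\tcycles_run"
    )

    def to_tsv_rows(self) -> list[str]:
        return [
            f"{self.group_id}\t{m}\t{s['reads_in']}\t{s['clean']}\t{s['split']}\t"
            f"{s['fragments_out']}\t{s['bases_in']}\t{s['bases_out']}\t"
            f"{s['bases_discarded']}\t{self.cycles_run}"
            for m, s in sorted(self.per_member.items())
        ]


def _split_against_partners(
    read: Read, partner_indexes: list[KmerIndex], p: SplitParams
) -> tuple[list[Read], bool]:
    """One read vs all partners: full-alignment veto, then the most
    fragmenting partner's split."""
    n = len(read)
    best_split: list[Read] | None = None
    for index in partner_indexes:
        segments = map_sequence(read.seq, read.read_id, index, min_identity=p.min_identity)
        if not segments:
            continue
        if any(s.read_span >= p.full_align_fraction * n for s in segments):
            return [read], False  # fully explained by this partner: clean
        fragments, was_split = classify_and_split(read, segments, p)
        if was_split and (best_split is None or len(fragments) > len(best_split)):
            best_split = fragments
    if best_split is None:
        return [read], False
    return best_split, True


def clean_group_reads(
    group: StrainGroup,
    readsets: dict[str, ReadSet],
    assemblies: dict[str, GenomeAssembly],
    p: SplitParams | None = None,
) -> tuple[ReadSet, CleaningReport]:
    """Chimera-clean and pool the reads of one strain group.

    Per cycle, every member's current reads are checked against every OTHER
    member's assembly; split fragments re-enter the next cycle (a chimera
    can carry more than one junction). Cycles stop at fixpoint (no read
    split) or after ``max_cycles``. The pooled output keeps each member's
    read ids (fragment ids suffixed with their read interval), ready for
    co-assembly. Reads already clean in a cycle are final — with fixed
    assemblies their classification cannot change — so later cycles revisit
    only newly created fragments.
    """
    p = p or SplitParams()
    report = CleaningReport(group_id=group.group_id)
    members = sorted(group.members & set(readsets))
    with_asm = [m for m in members if m in assemblies and assemblies[m].contigs]
    for m in members:
        stats = report.member(m)
        stats["reads_in"] = len(readsets[m])
        stats["bases_in"] = readsets[m].total_bases()
    if len(with_asm) < 2:
        logger.info("group %s: fewer than 2 members with assemblies; reads passed through",
                    group.group_id)
        pooled = []
        for m in members:
            stats = report.member(m)
            stats["clean"] = len(readsets[m])
            stats["bases_out"] = stats["bases_in"]
            pooled.extend(readsets[m].reads)
        return ReadSet(group.group_id, pooled), report

    indexes = {m: KmerIndex(assemblies[m]) for m in with_asm}
    # pending: reads/fragments still to check this cycle, flagged is_fragment
    pending: dict[str, list[tuple[Read, bool]]] = {
        m: [(r, False) for r in readsets[m].reads] for m in members
    }
    final: dict[str, list[Read]] = {m: [] for m in members}
    cycles = 0
    while cycles < p.max_cycles and any(pending.values()):
        cycles += 1
        any_split = False
        for m in members:
            partner_indexes = [indexes[o] for o in with_asm if o != m]
            if not partner_indexes:
                final[m].extend(r for r, _ in pending[m])
                pending[m] = []
                continue
            next_pending: list[tuple[Read, bool]] = []
            stats = report.member(m)
            for read, is_fragment in pending[m]:
                fragments, was_split = _split_against_partners(read, partner_indexes, p)
                if was_split:
                    any_split = True
                    if not is_fragment:
                        stats["split"] += 1
                    next_pending.extend((f, True) for f in fragments)
                else:
                    final[m].append(read)
            pending[m] = next_pending
        if not any_split:
            break
    report.cycles_run = cycles
    pooled: list[Read] = []
    for m in members:
        final[m].extend(r for r, _ in pending[m])  # cycle cap: keep current fragments
        stats = report.member(m)
        out_reads = final[m]
        stats["clean"] = stats["reads_in"] - stats["split"]
        stats["fragments_out"] = len(out_reads)
        stats["bases_out"] = sum(len(r) for r in out_reads)
        stats["bases_discarded"] = stats["bases_in"] - stats["bases_out"]
        pooled.extend(out_reads)
    return ReadSet(group.group_id, pooled), report
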