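"""Strain grouping and genome dereplication.

SAGs are declared same-strain when a pair strictly exceeds all three
similarity thresholds (ANI > 99%, TNF correlation > 0.90, single-copy
marker homology > 99.9% by default); groups are the connected components of
that graph (single linkage, matching the binary same-strain-group reading).
Dereplication clusters genomes at > 99% ANI and keeps the highest-quality
representative per cluster, scored as completeness - 5 x contamination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .core import ConfigurationError, GenomeAssembly
from .genome_metrics import GenomeQuality
from .similarity import SimilarityRecord

logger = logging.getLogger(__name__)


@dataclass
class StrainGroupingParams:
    ani_threshold: float = 99.0  # percent
    tnf_threshold: float = 0.90  # correlation
    marker_threshold: float = 99.9  # percent; 99.0 is a supported variant

    def __post_init__(self) -> None:
        if not 0.0 <= self.ani_threshold <= 100.0:
            raise ConfigurationError("ani_threshold outside [0, 100]")
        if not -1.0 <= self.tnf_threshold <= 1.0:
            raise ConfigurationError("tnf_threshold outside [-1, 1]")
        if not 0.0 <= self.marker_threshold <= 100.0:
            raise ConfigurationError("marker_threshold outside [0, 100]")


@dataclass
class StrainGroup:
    group_id: str
    members: set[str]
    representative: str
    host_id: str = ""


def quality_score(q: GenomeQuality) -> float:
    """Dereplication quality score: completeness - 5 x contamination."""
    return q.completeness - 5.0 * q.contamination


def _passes(rec: SimilarityRecord, p: StrainGroupingParams) -> bool:
    """Strict three-way threshold rule; an undefined measure never passes."""
    return (
        rec.ani is not None
        and rec.ani > p.ani_threshold
        and rec.tnf_corr is not None
        and rec.tnf_corr > p.tnf_threshold
        and rec.marker_homology is not None
        and rec.marker_homology > p.marker_threshold
    )


def _pick_representative(
    members: set[str],
    qualities: dict[str, GenomeQuality],
    assemblies: dict[str, GenomeAssembly] | None,
) -> str:
    def key(sag_id: str):
        q = qualities.get(sag_id)
        score = quality_score(q) if q is not None else float("-inf")
        asm = assemblies.get(sag_id) if assemblies else None
        length = asm.total_length if asm is not None else 0
        return (-score, -length, sag_id)

    return min(members, key=key)


def build_strain_groups(
    records: list[SimilarityRecord],
    qualities: dict[str, GenomeQuality],
    p: StrainGroupingParams | None = None,
    sag_ids: list[str] | None = None,
    host_of: dict[str, str] | None = None,
    cross_host: bool = False,
    assemblies: dict[str, GenomeAssembly] | None = None,
) -> list[StrainGroup]:
    """Partition the selected SAGs into same-strain groups.

    An edge joins each pair strictly exceeding all three thresholds; groups
    are the connected components, so two SAGs may share a group through a
    chain even if their own pair misses a threshold. By default only pairs
    from the same host are linked; ``cross_host=True`` also links across
    hosts (the cohabitant analysis). Output ordering and representative
    choice are deterministic: groups sorted by smallest member id,
    representative = best quality score (ties: longer assembly, then id).
    """
    p = p or StrainGroupingParams()
    if sag_ids is None:
        sag_ids = sorted({r.sag_a for r in records} | {r.sag_b for r in records})
    g = nx.Graph()
    g.add_nodes_from(sag_ids)
    seen_pairs = set()
    for rec in records:
        if rec.sag_a not in g or rec.sag_b not in g:
            continue
        seen_pairs.add(frozenset((rec.sag_a, rec.sag_b)))
        if host_of is not None and not cross_host:
            if host_of.get(rec.sag_a) != host_of.get(rec.sag_b):
                continue
        if _passes(rec, p):
            g.add_edge(rec.sag_a, rec.sag_b)
    n_missing = sum(
        1
        for i, a in enumerate(sag_ids)
        for b in sag_ids[i + 1 :]
        if frozenset((a, b)) not in seen_pairs
    )
    if n_missing:
        logger.warning("%d SAG pairs lack a similarity record; treated as no-edge", n_missing)
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    groups = []
    for i, members in enumerate(components):
        rep = _pick_representative(members, qualities, assemblies)
        host = ""
        if host_of is not None:
            hosts = sorted({host_of.get(m, "") for m in members})
            host = hosts[0] if len(hosts) == 1 else ",".join(hosts)
        groups.append(StrainGroup(f"group_{i:03d}", set(members), rep, host))
    return groups


@dataclass
class DereplicationResult:
    clusters: list[set[str]] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return self.representatives


def dereplicate(
    assemblies: dict[str, GenomeAssembly],
    qualities: dict[str, GenomeQuality],
    records: list[SimilarityRecord],
    ani_threshold: float = 99.0,
) -> DereplicationResult:
    """Reduce a genome set to non-redundant representatives.

    Genomes are clustered at two-way ANI strictly above ``ani_threshold``
    (connected components); each cluster keeps the genome maximizing
    completeness - 5 x contamination, ties broken by larger assembly, then
    lexicographic id.
    """
    g = nx.Graph()
    g.add_nodes_from(assemblies)
    for rec in records:
        if rec.ani is not None and rec.ani > ani_threshold:
            if rec.sag_a in assemblies and rec.sag_b in assemblies:
                g.add_edge(rec.sag_a, rec.sag_b)
    result = DereplicationResult()
    for comp in sorted(nx.connected_components(g), key=lambda c: min(c)):
        rep = _pick_representative(comp, qualities, assemblies)
        result.clusters.append(set(comp))
        result.representatives.append(rep)
    return result


GROUPS_TSV_HEADER = "group_id\thost_id\tsag_id\tis_representative"


def write_groups_table(groups: list[StrainGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write(GROUPS_TSV_HEADER + "\n")
        for grp in groups:
            for sag_id in sorted(grp.members):
                fh.write(
                    f"{grp.group_id}\t{grp.host_id}\t{sag_id}\t"
                    f"{int(sag_id == grp.representative)}\n"
                )


def write_dereplication_table(
    result: DereplicationResult, qualities: dict[str, GenomeQuality], path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsag_id\tscore\tkept\n")
        for i, (cluster, rep) in enumerate(zip(result.clusters, result.representatives)):
            for sag_id in sorted(cluster):
                q = qualities.get(sag_id)
                score = quality_score(q) if q else float("nan")
                fh.write(f"cluster_{i:03d}\t{sag_id}\t{score:.2f}\t{int(sag_id == rep)}\n")
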