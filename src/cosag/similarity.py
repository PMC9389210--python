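"""Pairwise genome-similarity measures for strain grouping.

Three measures, each with its own discriminative band:

* fragment-based two-way ANI — the genome is chopped into fixed-length
  fragments, each fragment's best placement on the partner genome scores a
  percent identity, and qualifying fragments (identity and coverage floors)
  are averaged; the two directions are averaged for symmetry;
* tetranucleotide frequency (TNF) correlation — Pearson correlation of
  canonical (strand-collapsed) 4-mer frequency profiles, a composition
  signature that is high within an organism regardless of which loci each
  SAG happened to recover;
* single-copy marker homology — mean global alignment identity over markers
  found single-copy and full-length in both assemblies.

An undefined value (too few qualifying fragments or shared markers) is
reported as None and treated downstream as "below threshold", never as
missing-at-random.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np

from .align import KmerIndex, _chain_hits, global_identity
from .core import ConfigurationError, GenomeAssembly, revcomp
from .genome_metrics import MarkerHit, find_marker_hits

# --- canonical tetranucleotide machinery -----------------------------------

_ALL_TETRAMERS = ["".join(p) for p in product("ACGT", repeat=4)]
CANONICAL_TETRAMERS = sorted({min(t, revcomp(t)) for t in _ALL_TETRAMERS})
_CANON_BIN = {t: CANONICAL_TETRAMERS.index(min(t, revcomp(t))) for t in _ALL_TETRAMERS}

MIN_PROFILE_LENGTH = 5000


def tetranucleotide_profile(
    asm: GenomeAssembly, min_length: int = MIN_PROFILE_LENGTH
) -> np.ndarray | None:
    """Canonical (strand-symmetric) tetranucleotide frequency vector.

    Each of the 136 bins holds the count of a 4-mer plus its reverse
    complement over all contigs (windows never span contig boundaries;
    windows containing N are skipped), normalized to sum to 1. Exactly
    invariant under reverse complement of the input. None when the assembly
    is shorter than 5 kb (profile too noisy to be meaningful).
    """
    if asm.total_length < min_length:
        return None
    counts = np.zeros(len(CANONICAL_TETRAMERS))
    for seq in asm.sequences():
        c = Counter(seq[i : i + 4] for i in range(len(seq) - 3))
        for tet, n in c.items():
            b = _CANON_BIN.get(tet)
            if b is not None:
                counts[b] += n
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def tnf_correlation(p: np.ndarray | None, q: np.ndarray | None) -> float | None:
    """Pearson correlation of two canonical 4-mer profiles."""
    if p is None or q is None:
        return None
    if np.std(p) == 0 or np.std(q) == 0:
        return None
    return float(np.corrcoef(p, q)[0, 1])


# --- fragment-based ANI -----------------------------------------------------


@dataclass
class AniParams:
    fragment_length: int = 1000
    min_fragment_identity: float = 0.70
    min_fragment_coverage: float = 0.70
    min_fragments: int = 5
    max_chains: int = 8  # candidate placements evaluated per fragment

    def __post_init__(self) -> None:
        if self.fragment_length < 200:
            raise ConfigurationError("fragment_length must be >= 200 bp")
        for name in ("min_fragment_identity", "min_fragment_coverage"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class SimilarityRecord:
    sag_a: str
    sag_b: str
    ani: float | None  # percent
    ani_fragments_used: int
    tnf_corr: float | None
    marker_homology: float | None  # percent
    markers_compared: int


def _best_fragment_placement(
    fragment: str, index: KmerIndex, max_chains: int
) -> tuple[float, float] | None:
    """Best (identity, coverage) placement of a fragment on the indexed genome.

    Seed chains propose (contig, strand, diagonal) placements; each is scored
    by extending along its diagonal to the fragment/contig bounds and counting
    exact base matches (the simulated and assumed data are substitution-
    dominated, so the diagonal extension is the alignment). Coverage is the
    fraction of the fragment for which target sequence exists at that
    placement (a fragment overhanging a contig end is partially covered).
    """
    L = len(fragment)
    best: tuple[float, float] | None = None
    for query in (fragment, revcomp(fragment)):
        q_arr = np.frombuffer(query.encode(), dtype="S1")
        chains = _chain_hits(query, index, step=4)
        chains.sort(key=lambda c: -c.n_seeds)
        for chain in chains[:max_chains]:
            t_arr = index.contig_array(chain.contig_idx)
            # extend to fragment bounds, clipped to the contig
            qs = max(0, -chain.diag)
            qe = min(L, len(t_arr) - chain.diag)
            if qe <= qs:
                continue
            ts, te = qs + chain.diag, qe + chain.diag
            matches = int(np.count_nonzero(q_arr[qs:qe] == t_arr[ts:te]))
            identity = matches / (qe - qs)
            coverage = (qe - qs) / L
            if best is None or identity * coverage > best[0] * best[1]:
                best = (identity, coverage)
        if best is not None and best[0] >= 0.99 and best[1] == 1.0:
            break  # unambiguous full-length placement
    return best


def _fragments(asm: GenomeAssembly, length: int) -> list[str]:
    frags = []
    for seq in asm.sequences():
        for i in range(0, len(seq) - length + 1, length):
            frags.append(seq[i : i + length])
    return frags


def fragment_ani(
    a: GenomeAssembly,
    b: GenomeAssembly | KmerIndex,
    p: AniParams | None = None,
) -> tuple[float | None, int]:
    """One-way fragment ANI of ``a`` against ``b``.

    Chops ``a`` into non-overlapping ``fragment_length`` windows (trailing
    partial windows dropped); each fragment qualifying at the identity and
    coverage floors contributes its percent identity. Returns (mean percent
    identity, fragments used); the mean is None when fewer than
    ``min_fragments`` qualify — an insufficient homologous fraction.
    """
    p = p or AniParams()
    index = b if isinstance(b, KmerIndex) else KmerIndex(b)
    identities = []
    for frag in _fragments(a, p.fragment_length):
        placement = _best_fragment_placement(frag, index, p.max_chains)
        if placement is None:
            continue
        identity, coverage = placement
        if identity >= p.min_fragment_identity and coverage >= p.min_fragment_coverage:
            identities.append(identity)
    if len(identities) < p.min_fragments:
        return None, len(identities)
    return 100.0 * float(np.mean(identities)), len(identities)


def two_way_ani(
    a: GenomeAssembly,
    b: GenomeAssembly,
    p: AniParams | None = None,
    index_a: KmerIndex | None = None,
    index_b: KmerIndex | None = None,
) -> tuple[float | None, int]:
    """Symmetric ANI: mean of the two one-way fragment ANIs, defined only
    when both directions are defined."""
    p = p or AniParams()
    ab, n_ab = fragment_ani(a, index_b or b, p)
    ba, n_ba = fragment_ani(b, index_a or a, p)
    if ab is None or ba is None:
        return None, n_ab + n_ba
    return (ab + ba) / 2.0, n_ab + n_ba


# --- marker homology --------------------------------------------------------

DEFAULT_MIN_SHARED_MARKERS = 10


def marker_homology(
    hits_a: dict[str, list[MarkerHit]],
    hits_b: dict[str, list[MarkerHit]],
    min_shared: int = DEFAULT_MIN_SHARED_MARKERS,
) -> tuple[float | None, int]:
    """Mean global-alignment percent identity over markers found single-copy
    and full-length in both assemblies; None when fewer than ``min_shared``
    markers are comparable."""

    def usable(hits: dict[str, list[MarkerHit]]) -> dict[str, MarkerHit]:
        return {m: h[0] for m, h in hits.items() if len(h) == 1 and h[0].full_length}

    ua, ub = usable(hits_a), usable(hits_b)
    shared = sorted(set(ua) & set(ub))
    if len(shared) < min_shared:
        return None, len(shared)
    idents = [_marker_pair_identity(ua[m].seq, ub[m].seq) for m in shared]
    return 100.0 * float(np.mean(idents)), len(shared)


def _marker_pair_identity(a: str, b: str) -> float:
    """Identity of two extracted marker sequences. Equal lengths align
    globally; a marker truncated at a contig end in one assembly aligns as
    an infix of the other, so the truncation is not charged as divergence."""
    import edlib

    if len(a) == len(b):
        return global_identity(a, b)
    q, t = (a, b) if len(a) < len(b) else (b, a)
    d = edlib.align(q, t, mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(q)


# --- all-pairs driver -------------------------------------------------------


def pairwise_similarity(
    assemblies: dict[str, GenomeAssembly],
    markers: GenomeAssembly,
    ani_params: AniParams | None = None,
    min_shared_markers: int = DEFAULT_MIN_SHARED_MARKERS,
    pairs: list[tuple[str, str]] | None = None,
) -> list[SimilarityRecord]:
    """All three similarity measures for every pair of assemblies (or the
    given pairs), with per-assembly indexes, profiles and marker hits
    computed once."""
    ani_params = ani_params or AniParams()
    ids = sorted(assemblies)
    indexes = {i: KmerIndex(assemblies[i]) for i in ids}
    profiles = {i: tetranucleotide_profile(assemblies[i]) for i in ids}
    marker_hits = {i: find_marker_hits(indexes[i], markers) for i in ids}
    if pairs is None:
        pairs = [(a, b) for ai, a in enumerate(ids) for b in ids[ai + 1 :]]
    records = []
    for a, b in pairs:
        ani, n_frag = two_way_ani(
            assemblies[a], assemblies[b], ani_params,
            index_a=indexes[a], index_b=indexes[b],
        )
        tnf = tnf_correlation(profiles[a], profiles[b])
        hom, n_mark = marker_homology(marker_hits[a], marker_hits[b], min_shared_markers)
        records.append(SimilarityRecord(a, b, ani, n_frag, tnf, hom, n_mark))
    return records


SIMILARITY_TSV_HEADER = (
    "sag_a\tsag_b\tani\tani_fragments_used\ttnf_corr\tmarker_homology\tmarkers_compared"
)


def write_similarity_table(records: list[SimilarityRecord], path) -> None:
    def fmt(x, nd=4):
        return "NA" if x is None else f"{x:.{nd}f}"

    with open(path, "w") as fh:
        fh.write(SIMILARITY_TSV_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.sag_a}\t{r.sag_b}\t{fmt(r.ani)}\t{r.ani_fragments_used}\t"
                f"{fmt(r.tnf_corr)}\t{fmt(r.marker_homology)}\t{r.markers_compared}\n"
            )
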