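"""The three similarity measures: canonical TNF correlation, fragment-based
two-way ANI, and single-copy marker homology."""

import numpy as np
import pytest

from cosag.core import Contig, GenomeAssembly, revcomp
from cosag.genome_metrics import find_marker_hits
from cosag.similarity import (
    AniParams,
    CANONICAL_TETRAMERS,
    fragment_ani,
    marker_homology,
    pairwise_similarity,
    tetranucleotide_profile,
    tnf_correlation,
    two_way_ani,
)
from cosag.synthetic_data import mutate_to_ani, simulate_ancestor


def brute_force_canonical_profile(seq):
    """Oracle: count every 4-mer window plus its reverse complement into
    lexicographically-canonical bins, then normalize."""
    counts = dict.fromkeys(CANONICAL_TETRAMERS, 0)
    for i in range(len(seq) - 3):
        tet = seq[i : i + 4]
        if set(tet) <= set("ACGT"):
            counts[min(tet, revcomp(tet))] += 1
    total = sum(counts.values())
    return np.array([counts[t] / total for t in CANONICAL_TETRAMERS])


class TestTnfProfile:
    def test_136_canonical_bins(self):
        assert len(CANONICAL_TETRAMERS) == 136

    def test_profile_sums_to_one_and_matches_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=6000))
            asm = GenomeAssembly("s", [Contig("c", seq)])
            p = tetranucleotide_profile(asm)
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, brute_force_canonical_profile(seq))

    def test_exact_revcomp_invariance(self):
        rng = np.random.default_rng(78)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8000))
        a = tetranucleotide_profile(GenomeAssembly("s", [Contig("c", seq)]))
        b = tetranucleotide_profile(GenomeAssembly("s", [Contig("c", revcomp(seq))]))
        assert np.array_equal(a, b)

    def test_poly_a_mass_on_single_bin(self):
        p = tetranucleotide_profile(GenomeAssembly("s", [Contig("c", "A" * 6000)]))
        assert p[CANONICAL_TETRAMERS.index("AAAA")] == 1.0
        assert p.sum() == 1.0

    def test_too_short_assembly_undefined(self):
        assert tetranucleotide_profile(GenomeAssembly("s", [Contig("c", "ACGT" * 100)])) is None


class TestTnfCorrelation:
    def test_self_correlation_one(self):
        g = simulate_ancestor(20_000, 0.5, 1)
        p = tetranucleotide_profile(g)
        assert tnf_correlation(p, p) == pytest.approx(1.0)

    def test_same_strain_sags_above_threshold(self, small_cohort):
        ids = sorted(small_cohort.assemblies)
        same = [i for i in ids if i.startswith("h0_s0")]
        p = [tetranucleotide_profile(small_cohort.assemblies[i]) for i in same[:2]]
        assert tnf_correlation(p[0], p[1]) > 0.90

    def test_divergent_gc_genomes_below_threshold(self):
        a = tetranucleotide_profile(simulate_ancestor(50_000, 0.30, 3))
        b = tetranucleotide_profile(simulate_ancestor(50_000, 0.65, 4))
        assert tnf_correlation(a, b) < 0.90

    def test_zero_variance_profile_undefined(self):
        p = np.full(136, 1 / 136)
        assert tnf_correlation(p, p) is None


class TestFragmentAni:
    def test_self_ani_exactly_100(self, ancestor_100k):
        ani, used = two_way_ani(ancestor_100k, ancestor_100k)
        assert ani == 100.0
        assert used == 200  # all 100 fragments in both directions

    def test_calibrated_against_hamming_truth(self, ancestor_100k):
        derived = mutate_to_ani(ancestor_100k, 0.97, seed=5)
        truth = 100 * np.mean(
            [a == b for a, b in zip(ancestor_100k.contigs[0].seq, derived.contigs[0].seq)]
        )
        ani, _ = two_way_ani(ancestor_100k, derived)
        assert ani == pytest.approx(truth, abs=0.3)
        assert abs(ani - 97.0) <= 0.3

    def test_symmetric_by_construction(self, ancestor_100k):
        derived = mutate_to_ani(ancestor_100k, 0.96, seed=6)
        ab, _ = two_way_ani(ancestor_100k, derived)
        ba, _ = two_way_ani(derived, ancestor_100k)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_unrelated_genomes_undefined(self):
        a = simulate_ancestor(20_000, 0.5, 10)
        b = simulate_ancestor(20_000, 0.5, 11)
        ani, used = two_way_ani(a, b)
        assert ani is None

    def test_invariant_to_contig_fragmentation(self, ancestor_100k):
        derived = mutate_to_ani(ancestor_100k, 0.98, seed=7)
        ani_whole, _ = two_way_ani(ancestor_100k, derived)
        rng = np.random.default_rng(99)
        cuts = sorted(rng.choice(np.arange(2000, 98_000), size=10, replace=False).tolist())
        seq = derived.contigs[0].seq
        pieces = [seq[a:b] for a, b in zip([0] + cuts, cuts + [len(seq)])]
        split = GenomeAssembly("d", [Contig(f"c{i}", s) for i, s in enumerate(pieces)])
        ani_split, _ = two_way_ani(ancestor_100k, split)
        assert abs(ani_split - ani_whole) <= 0.2

    def test_min_fragments_floor(self, ancestor_100k):
        small = GenomeAssembly("s", [Contig("c", ancestor_100k.contigs[0].seq[:2500])])
        ani, used = fragment_ani(small, ancestor_100k, AniParams(min_fragments=5))
        assert ani is None and used == 2


class TestMarkerHomology:
    def test_self_homology_100(self, small_cohort):
        hits = find_marker_hits(small_cohort.strains[0], small_cohort.markers)
        hom, n = marker_homology(hits, hits)
        assert hom == 100.0 and n > 0

    def test_divergence_tracks_truth(self, small_cohort, small_cohort_records):
        """SAGs of 0.97-divergent strains show ~97% marker homology, failing
        a 99.9% threshold; same-strain SAGs sit near 99.9%."""
        recs = small_cohort_records
        strain_of = small_cohort.manifest.sag_strain
        for r in recs:
            if r.marker_homology is None:
                continue
            if strain_of[r.sag_a] == strain_of[r.sag_b]:
                assert r.marker_homology >= 99.7
            else:
                assert 96.0 <= r.marker_homology <= 98.0
                assert r.marker_homology < 99.9

    def test_too_few_shared_markers_undefined(self, small_cohort):
        hits = find_marker_hits(small_cohort.strains[0], small_cohort.markers)
        few = dict(list(hits.items())[:3])
        hom, n = marker_homology(few, hits)
        assert hom is None and n == 3
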