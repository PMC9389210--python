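"""Generator fidelity: the simulator must deliver the statistical structure
the pipeline assumes, with exactly known truth."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from cosag.core import ConfigurationError
from cosag.synthetic_data import (
    SimulationConfig,
    mutate_to_ani,
    plant_markers,
    simulate_ancestor,
    simulate_cohort,
    simulate_sag,
    simulate_strains,
)


class TestAncestor:
    def test_length_and_gc_within_binomial_noise(self):
        g = simulate_ancestor(100_000, 0.5, seed=1)
        assert g.total_length == 100_000
        gc = g.gc_fraction() * 100_000
        sd = math.sqrt(100_000 * 0.25)
        assert abs(gc - 50_000) <= 3 * sd

    def test_deterministic_for_fixed_seed(self):
        a = simulate_ancestor(100_000, 0.40, seed=7)
        b = simulate_ancestor(100_000, 0.40, seed=7)
        assert a.contigs[0].seq == b.contigs[0].seq

    def test_short_genome_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_ancestor(5_000, 0.5, seed=1)

    @pytest.mark.parametrize("gc", [0.3, 0.65])
    def test_gc_dial(self, gc):
        g = simulate_ancestor(20_000, gc, seed=2)
        assert abs(g.gc_fraction() - gc) < 0.02


class TestMutateToAni:
    def test_identity_one_is_identity(self, ancestor_100k):
        out = mutate_to_ani(ancestor_100k, 1.0, seed=3)
        assert out.contigs[0].seq == ancestor_100k.contigs[0].seq

    def test_hamming_identity_matches_target(self, ancestor_100k):
        out = mutate_to_ani(ancestor_100k, 0.97, seed=3)
        same = sum(
            a == b for a, b in zip(ancestor_100k.contigs[0].seq, out.contigs[0].seq)
        )
        ident = same / 100_000
        sd = math.sqrt(0.97 * 0.03 / 100_000)
        assert abs(ident - 0.97) <= 3 * sd

    def test_out_of_range_target_rejected(self, ancestor_100k):
        with pytest.raises(ConfigurationError):
            mutate_to_ani(ancestor_100k, 0.5, seed=1)

    def test_star_phylogeny_pairwise_divergence(self, ancestor_100k):
        cfg = SimulationConfig(n_strains=2, between_strain_ani=0.96, seed=9)
        s = simulate_strains(cfg, ancestor_100k)
        same = sum(a == b for a, b in zip(s[0].contigs[0].seq, s[1].contigs[0].seq))
        assert abs(same / 100_000 - 0.96) < 0.005


class TestMarkers:
    def test_planted_markers_are_nonoverlapping_ancestor_substrings(self, ancestor_100k):
        markers, loci = plant_markers(ancestor_100k, 60, 900, seed=4)
        assert len(markers.contigs) == 60
        seq = ancestor_100k.contigs[0].seq
        prev_end = 0
        for (s, e), m in zip(loci, markers.contigs):
            assert s >= prev_end and seq[s:e] == m.seq
            prev_end = e

    def test_too_many_markers_rejected(self):
        cfg = SimulationConfig(genome_length=10_000, n_markers=100)
        with pytest.raises(ConfigurationError):
            cfg.resolved_n_markers()


class TestSimulateSag:
    def test_no_noise_sag_is_window_partition_of_strain(self, ancestor_100k):
        cfg = SimulationConfig(
            target_completeness=1.0, within_strain_ani=1.0, chimera_rate=0.0,
            error_rate=0.0, mean_depth=2.0, seed=5,
        )
        asm, reads, truth = simulate_sag(ancestor_100k, cfg, sag_seed=17)
        assert "".join(asm.sequences()) == ancestor_100k.contigs[0].seq
        # every read maps back verbatim
        genome = ancestor_100k.contigs[0].seq
        for r in list(reads)[:200]:
            assert r.seq in genome

    def test_true_completeness_matches_target(self, ancestor_100k):
        cfg = SimulationConfig(target_completeness=0.6, mean_depth=0.0, seed=5)
        asm, _, truth = simulate_sag(ancestor_100k, cfg, sag_seed=3)
        tc = truth.true_completeness[asm.sag_id]
        assert abs(tc - 0.6) < 0.05
        dropped = sum(e - s for s, e in truth.dropped_intervals[asm.sag_id])
        assert asm.total_length + dropped == 100_000

    def test_chimera_count_binomial(self, ancestor_100k):
        cfg = SimulationConfig(
            target_completeness=1.0, chimera_rate=0.05, mean_depth=15.0, seed=5
        )
        _, reads, truth = simulate_sag(ancestor_100k, cfg, sag_seed=23)
        n = len(reads)
        n_chim = sum(r.is_chimeric for r in truth.rows)
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(n_chim - 0.05 * n) <= 3 * sd
        for row in truth.rows:
            assert (row.junction_pos is not None) == row.is_chimeric

    def test_manifest_covers_reads_exactly(self, read_cohort):
        read_ids = {r.read_id for rs in read_cohort.readsets.values() for r in rs}
        manifest_ids = [r.read_id for r in read_cohort.manifest.rows]
        assert len(manifest_ids) == len(set(manifest_ids))
        assert set(manifest_ids) == read_ids

    def test_depth_variance_increases_with_lognormal_sigma(self, ancestor_100k):
        variances = []
        for sigma in (0.2, 0.8, 1.5):
            cfg = SimulationConfig(
                target_completeness=1.0, lognormal_sigma=sigma, mean_depth=10.0,
                chimera_rate=0.0, seed=5,
            )
            _, reads, truth = simulate_sag(ancestor_100k, cfg, sag_seed=31)
            depth = np.zeros(20)
            for row in truth.rows:
                depth[min(row.origin_start // 5000, 19)] += 1
            variances.append(np.var(depth))
        rho, _ = spearmanr([0.2, 0.8, 1.5], variances)
        assert rho > 0


class TestDeterminism:
    def test_cohort_outputs_byte_identical(self, tmp_path):
        from cosag.synthetic_data import write_cohort

        cfg = SimulationConfig(
            genome_length=20_000, n_strains=2, sags_per_strain=1,
            mean_depth=3.0, seed=42,
        )
        for sub in ("a", "b"):
            write_cohort(simulate_cohort(cfg), tmp_path / sub)
        for rel in ("manifest.tsv", "markers.fa", "config.yaml"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        for p in sorted((tmp_path / "a" / "reads").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / "reads" / p.name).read_bytes()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(chimera_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(read_length=30)
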