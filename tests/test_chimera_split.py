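"""Chimera splitting: per-read classification, interval arithmetic, and the
iterative cross-reference cleaning loop measured against manifest truth."""

import pytest

from cosag.align import AlignmentSegment, KmerIndex
from cosag.chimera_split import (
    SplitParams,
    classify_and_split,
    clean_group_reads,
    map_read,
)
from cosag.core import Read
from cosag.strain_clustering import StrainGroup
from cosag.synthetic_data import SimulationConfig, simulate_cohort


def _read(n=150, rid="r"):
    return Read(rid, "A" * n, [30] * n)


def _seg(rid, start, end):
    return AlignmentSegment(rid, start, end, "c", 0, end - start, "+", 0.99)


class TestClassifyAndSplit:
    def test_fully_aligned_read_returned_whole(self):
        r = _read(150)
        frags, split = classify_and_split(r, [_seg("r", 0, 150)])
        assert not split and frags == [r]
        frags, split = classify_and_split(r, [_seg("r", 3, 150)])  # 98% coverage
        assert not split

    def test_unmapped_read_returned_whole(self):
        r = _read(150)
        frags, split = classify_and_split(r, [])
        assert not split and frags == [r]

    def test_partial_alignment_cut_into_two_fragments(self):
        r = _read(150)
        frags, split = classify_and_split(r, [_seg("r", 0, 100)])
        assert split
        assert [(f.read_id, len(f)) for f in frags] == [("r:0-100", 100), ("r:100-150", 50)]

    def test_short_fragment_below_20bp_discarded(self):
        r = _read(150)
        frags, split = classify_and_split(r, [_seg("r", 0, 140)])
        assert split
        assert [(f.read_id, len(f)) for f in frags] == [("r:0-140", 140)]

    def test_two_segment_chimera_yields_ordered_fragments(self):
        r = _read(150)
        frags, split = classify_and_split(r, [_seg("r", 0, 60), _seg("r", 60, 150)])
        assert split
        assert [f.read_id for f in frags] == ["r:0-60", "r:60-150"]

    def test_qualities_sliced_in_register(self):
        r = Read("r", "ACGT" * 40, list(range(160)))
        frags, _ = classify_and_split(r, [_seg("r", 0, 100)])
        assert frags[0].quals == list(range(100))
        assert frags[1].quals == list(range(100, 160))
        assert frags[0].seq + frags[1].seq == r.seq


class TestMapRead:
    def test_verbatim_and_chimeric_reads(self, read_cohort):
        sags = sorted(read_cohort.assemblies)
        target = read_cohort.assemblies[sags[0]]
        contig = max(target.contigs, key=len)
        seq = contig.seq
        far = len(seq) - 2000  # second locus well away from the first
        verbatim = Read("v", seq[2000:2150], [30] * 150)
        segs = map_read(verbatim, target)
        assert len(segs) == 1 and segs[0].read_span == 150

        chim = Read("x", seq[2000:2060] + seq[far : far + 90], [30] * 150)
        segs = map_read(chim, target)
        assert len(segs) == 2
        assert abs(segs[0].read_end - 60) <= 14  # junction within k-1 of truth


class TestCleanGroupReads:
    def test_no_chimeras_is_fixpoint_at_cycle_one(self):
        cfg = SimulationConfig(
            genome_length=30_000, n_strains=1, sags_per_strain=3,
            target_completeness=1.0, within_strain_ani=1.0, mean_depth=4.0,
            chimera_rate=0.0, error_rate=0.0, seed=21,
        )
        cohort = simulate_cohort(cfg)
        group = StrainGroup("g0", set(cohort.assemblies), min(cohort.assemblies))
        pooled, rep = clean_group_reads(group, cohort.readsets, cohort.assemblies)
        assert rep.cycles_run == 1
        in_reads = sorted(
            (r.read_id, r.seq) for rs in cohort.readsets.values() for r in rs
        )
        out_reads = sorted((r.read_id, r.seq) for r in pooled)
        assert out_reads == in_reads

    def test_singleton_group_passes_reads_through(self, read_cohort):
        sag = sorted(read_cohort.assemblies)[0]
        group = StrainGroup("g0", {sag}, sag)
        pooled, rep = clean_group_reads(group, read_cohort.readsets, read_cohort.assemblies)
        assert len(pooled) == len(read_cohort.readsets[sag])
        assert rep.per_member[sag]["split"] == 0

    def test_manifest_truth_recall_and_precision(self, read_cohort):
        """>= 95% of true chimeras split or discarded; <= 1% of clean reads
        split; base accounting reconciles exactly."""
        group = StrainGroup("g0", set(read_cohort.assemblies), min(read_cohort.assemblies))
        pooled, rep = clean_group_reads(group, read_cohort.readsets, read_cohort.assemblies)
        out_ids = {r.read_id for r in pooled}
        chim = clean = handled = false_split = 0
        for row in read_cohort.manifest.rows:
            if row.is_chimeric:
                chim += 1
                handled += row.read_id not in out_ids
            else:
                clean += 1
                false_split += row.read_id not in out_ids
        assert handled / chim >= 0.95
        assert false_split / clean <= 0.01
        assert min(len(r) for r in pooled) >= 20
        bases_in = sum(rs.total_bases() for rs in read_cohort.readsets.values())
        discarded = sum(s["bases_discarded"] for s in rep.per_member.values())
        assert pooled.total_bases() + discarded == bases_in
        assert rep.cycles_run <= 5

    def test_fixpoint_stability_one_extra_cycle_changes_nothing(self, read_cohort):
        group = StrainGroup("g0", set(read_cohort.assemblies), min(read_cohort.assemblies))
        p5 = SplitParams(max_cycles=5)
        p6 = SplitParams(max_cycles=6)
        pooled5, rep5 = clean_group_reads(group, read_cohort.readsets, read_cohort.assemblies, p5)
        pooled6, _ = clean_group_reads(group, read_cohort.readsets, read_cohort.assemblies, p6)
        assert rep5.cycles_run < 5  # converged before the cap
        assert sorted(r.read_id for r in pooled5) == sorted(r.read_id for r in pooled6)

    def test_split_params_validation(self):
        with pytest.raises(Exception):
            SplitParams(min_fragment=0)
        with pytest.raises(Exception):
            SplitParams(full_align_fraction=1.5)
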