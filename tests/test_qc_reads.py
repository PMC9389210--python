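"""Read QC: right-end quality trimming, length/N/mean-quality filters, and
decoy-based host-read removal, checked against rule-by-rule oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from cosag.core import Read, ReadSet
from cosag.qc_reads import (
    QcParams,
    filter_reads,
    qc_readset,
    quality_trim_right,
    remove_host_reads,
)


def _read(seq, quals, rid="r", mate=0):
    return Read(rid, seq, list(quals), mate)


def brute_force_trim_cut(quals, trimq):
    """Oracle: best suffix cut maximizes sum(trimq - Q_i) over removed bases."""
    best_cut, best_score = len(quals), 0
    for cut in range(len(quals) - 1, -1, -1):
        score = sum(trimq - q for q in quals[cut:])
        if score > best_score:
            best_cut, best_score = cut, score
    return best_cut


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        r = _read("A" * 50, [30] * 50)
        assert quality_trim_right(r, 10).seq == r.seq

    def test_low_quality_tail_removed_exactly(self):
        r = _read("A" * 50, [30] * 45 + [2] * 5)
        t = quality_trim_right(r, 10)
        assert len(t) == 45

    def test_entirely_bad_read_becomes_empty(self):
        r = _read("A" * 30, [2] * 30)
        assert len(quality_trim_right(r, 10)) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=80))
    def test_matches_argmax_oracle(self, quals):
        r = _read("A" * len(quals), quals)
        assert len(quality_trim_right(r, 10)) == brute_force_trim_cut(quals, 10)


class TestFilters:
    @pytest.mark.parametrize(
        "length,n_count,meanq,kept",
        [
            (39, 0, 30.0, False),  # below min length
            (40, 0, 30.0, True),
            (100, 2, 30.0, False),  # too many Ns
            (100, 1, 30.0, True),
            (100, 0, 14.9, False),  # mean quality below bound
            (100, 0, 15.0, True),
        ],
    )
    def test_printed_bounds(self, length, n_count, meanq, kept):
        seq = "N" * n_count + "A" * (length - n_count)
        quals = [int(round(meanq))] * length if meanq == int(meanq) else None
        if quals is None:  # fractional mean: mix two levels
            lo = int(meanq)
            n_hi = int(round((meanq - lo) * 10))
            quals = ([lo + 1] * n_hi + [lo] * (10 - n_hi)) * (length // 10)
        r = _read(seq, quals)
        assert abs(r.mean_quality() - meanq) < 0.05
        out = filter_reads(ReadSet("s", [r]))
        assert (len(out) == 1) == kept

    def test_order_preserved_and_idempotent(self):
        reads = [
            _read("A" * 60, [30] * 55 + [2] * 5, "a"),
            _read("A" * 30, [30] * 30, "b"),  # fails min length
            _read("A" * 60, [30] * 60, "c"),
        ]
        once = filter_reads(ReadSet("s", reads))
        assert [r.read_id for r in once] == ["a", "c"]
        twice = filter_reads(once)
        assert [(r.read_id, r.seq) for r in twice] == [(r.read_id, r.seq) for r in once]

    def test_paired_policy_drops_both_mates(self):
        reads = [
            _read("A" * 100, [30] * 100, "p/1", mate=1),
            _read("A" * 30, [30] * 30, "p/2", mate=2),  # mate fails
            _read("A" * 100, [30] * 100, "q/1", mate=1),
            _read("A" * 100, [30] * 100, "q/2", mate=2),
        ]
        out = filter_reads(ReadSet("s", reads))
        assert [r.read_id for r in out] == ["q/1", "q/2"]


class TestHostRemoval:
    def test_verbatim_host_read_removed_random_read_kept(self, read_cohort):
        decoy = read_cohort.host_decoy
        host_seq = decoy.contigs[0].seq[1000:1150]
        rs = ReadSet("s", [_read(host_seq, [30] * 150, "host"),
                           _read("ACGT" * 38, [30] * 152, "weird")])
        out = remove_host_reads(rs, decoy)
        assert [r.read_id for r in out] == ["weird"]

    def test_manifest_truth_recall_and_false_removal(self, read_cohort):
        """On synthetic reads with 10% host contamination, host removal
        achieves recall >= 0.99 with false-removal rate <= 0.01."""
        truth = read_cohort.manifest.by_read()
        n_host = n_host_removed = n_clean = n_clean_removed = 0
        for sag_id, rs in read_cohort.readsets.items():
            out = remove_host_reads(rs, read_cohort.host_decoy)
            kept = {r.read_id for r in out}
            for r in rs:
                if truth[r.read_id].is_host:
                    n_host += 1
                    n_host_removed += r.read_id not in kept
                else:
                    n_clean += 1
                    n_clean_removed += r.read_id not in kept
        assert n_host_removed / n_host >= 0.99
        assert n_clean_removed / n_clean <= 0.01

    def test_empty_decoy_rejected(self):
        from cosag.core import ConfigurationError, GenomeAssembly

        with pytest.raises(ConfigurationError):
            remove_host_reads(ReadSet("s", []), GenomeAssembly("d", []))


def test_full_qc_report_consistency(read_cohort):
    rs = next(iter(read_cohort.readsets.values()))
    out, rep = qc_readset(rs, QcParams(), read_cohort.host_decoy)
    assert rep.reads_in == len(rs)
    assert rep.reads_out == len(out)
    assert rep.reads_out == rep.reads_in - rep.removed_by_filter - rep.removed_as_host
    in_ids = {r.read_id for r in rs}
    assert all(r.read_id in in_ids for r in out)
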