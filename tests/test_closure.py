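"""Closure scoring: the concordance null, Phred combination, geometry, patching."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapfill import (ClosureKind, GapNullModel, GapRecord, GfaParams,
                     SequenceCollection, apply_patches, call_closures,
                     closure_quality, detect_gaps, gap_concordance_prob,
                     infer_gap_length)
from gapfill.align import Alignment
from gapfill.anchors import DiscordReason, PairStatus, PairVerdict


class TestConcordanceProb:
    def test_zero_deviation_hits_the_floor(self):
        model = GapNullModel()
        assert gap_concordance_prob(0, 1000, model) == model.pg_floor

    def test_large_deviation_tends_to_one(self):
        assert gap_concordance_prob(10**9, 100) == pytest.approx(1.0, abs=1e-3)

    def test_ten_percent_calibration(self):
        # the default null is calibrated so a 10% deviation scores 1e-3,
        # i.e. 30 Phred — the acceptance threshold
        assert gap_concordance_prob(100, 1000) == pytest.approx(1e-3, rel=1e-9)
        assert gap_concordance_prob(1000, 10_000) == pytest.approx(1e-3, rel=1e-9)

    @given(st.integers(-10**6, 10**6), st.integers(1, 10**6))
    def test_symmetric_and_bounded(self, d, L0):
        pg = gap_concordance_prob(d, L0)
        assert gap_concordance_prob(-d, L0) == pg
        assert 0 < pg <= 1

    @given(st.integers(0, 10**5), st.integers(0, 10**5), st.integers(1, 10**6))
    def test_monotone_in_abs_deviation(self, d1, d2, L0):
        lo, hi = sorted((d1, d2))
        assert gap_concordance_prob(lo, L0) <= gap_concordance_prob(hi, L0)

    @given(st.integers(1, 10**5), st.integers(1, 10**4))
    def test_depends_only_on_relative_deviation(self, d, L0):
        # doubling both d and L0 leaves Pg (hence Qg) unchanged
        assert gap_concordance_prob(d, L0) == \
            pytest.approx(gap_concordance_prob(2 * d, 2 * L0), rel=1e-12)

    def test_heavy_tail_not_harsh_at_three_fold(self):
        # deviation of 3x the annotated length still carries positive weight
        qg, _, _ = closure_quality(gap_concordance_prob(3000, 1000), [60])
        assert qg > 0

    def test_invalid_L0_rejected(self):
        with pytest.raises(ValueError):
            gap_concordance_prob(5, 0)


class TestClosureQuality:
    def test_arithmetic_from_definition(self):
        qg, qa, q = closure_quality(0.001, [60, 60])
        assert (qg, qa, q) == (30.0, 60.0, 90.0)

    def test_maximally_discordant_scores_zero(self):
        qg, qa, q = closure_quality(1.0, [0, 40])
        assert q == 0.0

    def test_qa_is_weakest_anchor(self):
        _, qa, _ = closure_quality(0.5, [17, 60])
        assert qa == 17.0

    def test_sum_mode(self):
        _, qa, _ = closure_quality(0.5, [20, 20], combine="sum")
        assert qa == 40.0

    def test_matches_log_identity_recomputation(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            pg = 10 ** rng.uniform(-6, 0)
            mapqs = [int(m) for m in rng.integers(0, 61, size=2)]
            qg, qa, q = closure_quality(pg, mapqs)
            assert qg == pytest.approx(min(60.0, -10.0 * math.log10(pg)))
            assert qa == min(mapqs)
            assert q == pytest.approx(qg + qa)

    def test_invalid_probability_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                closure_quality(bad, [60])

    @given(st.integers(0, 30_000), st.integers(0, 30_000),
           st.integers(0, 60), st.integers(0, 60))
    def test_monotonicity_of_Q(self, d1, d2, m1, m2):
        L0 = 10_000
        lo_d, hi_d = sorted((d1, d2))
        lo_m, hi_m = sorted((m1, m2))
        q_small_d = closure_quality(gap_concordance_prob(lo_d, L0), [hi_m])[2]
        q_large_d = closure_quality(gap_concordance_prob(hi_d, L0), [hi_m])[2]
        assert q_small_d >= q_large_d  # non-increasing in |d|
        q_low_m = closure_quality(gap_concordance_prob(lo_d, L0), [lo_m])[2]
        assert q_small_d >= q_low_m  # non-decreasing in min mapq


def _verdict(l_start, l_end, r_start, r_end, strand="+", contig="ctg"):
    la = Alignment("g/L", contig, l_start, l_end, strand, 60, 1.0, 1.0, 0, True)
    ra = Alignment("g/R", contig, r_start, r_end, strand, 60, 1.0, 1.0, 0, True)
    return PairVerdict("g", PairStatus.CONCORDANT, DiscordReason.NONE, la, ra)


class TestInferGapLength:
    def test_revises_annotated_length(self):
        # annotated 718 bp gap whose donor span measures 731 bp: d = 13
        gap = GapRecord("g", "s", 5_000, 5_718)
        v = _verdict(10_000, 11_000, 11_731, 12_731)
        lg, d, (name, lo, hi) = infer_gap_length(v, gap)
        assert (lg, d) == (731, 13)
        assert (lo, hi) == (11_000, 11_731)

    def test_abutting_anchors_close_to_zero(self):
        gap = GapRecord("g", "s", 100, 400)
        lg, d, _ = infer_gap_length(_verdict(10_000, 11_000, 11_000, 12_000), gap)
        assert (lg, d) == (0, -300)

    def test_minus_strand_interval(self):
        gap = GapRecord("g", "s", 100, 300)
        v = _verdict(11_500, 12_500, 10_000, 11_000, strand="-")
        lg, d, (name, lo, hi) = infer_gap_length(v, gap)
        assert lg == 500 and (lo, hi) == (11_000, 11_500)

    def test_non_concordant_rejected(self):
        gap = GapRecord("g", "s", 100, 300)
        bad = PairVerdict("g", PairStatus.DISCORDANT, DiscordReason.OVERLAPPING)
        with pytest.raises(ValueError, match="concordant"):
            infer_gap_length(bad, gap)

    def test_planted_fill_lengths_recovered(self, small_pair):
        target, donor, truth = small_pair
        result = call_closures(target, donor)
        planted = {(g.seq_name, g.start, g.end): g for g in truth.gaps}
        assert len(result.candidates) == len(truth.gaps)
        for c in result.candidates:
            g = planted[(c.seq_name, c.target_start, c.target_end)]
            assert c.Lg == len(g.fill)
            assert c.d == g.deviation


class TestApplyPatches:
    def test_full_closure_splices_donor(self):
        target = SequenceCollection({"s": "ACNNNNGT"})
        donor = SequenceCollection({"d": "AAACTTTTGTTT"})
        from gapfill.closure import ClosureCandidate
        c = ClosureCandidate("gap_1", ClosureKind.FULL, "s", 2, 6, "d", 4, 8,
                             "+", 4, 4, 0, 1e-6, 60.0, 60.0, 120.0, True, 0)
        patched, agp, report = apply_patches(target, [c], donor)
        assert patched["s"] == "ACTTTTGT"
        assert report["bp_filled"] == 4

    def test_minus_strand_inserts_revcomp(self):
        target = SequenceCollection({"s": "ACNNNNGT"})
        donor = SequenceCollection({"d": "AAAACGGACA"})
        from gapfill.closure import ClosureCandidate
        c = ClosureCandidate("gap_1", ClosureKind.FULL, "s", 2, 6, "d", 3, 7,
                             "-", 4, 4, 0, 1e-6, 60.0, 60.0, 120.0, True, 0)
        patched, _, _ = apply_patches(target, [c], donor)
        assert patched["s"] == "AC" + "CCGT" + "GT"  # revcomp of donor[3:7]

    def test_extension_keeps_residual_n(self):
        target = SequenceCollection({"s": "ACNNNNGT"})
        donor = SequenceCollection({"d": "CCCCTT"})
        from gapfill.closure import ClosureCandidate
        c = ClosureCandidate("gap_1", ClosureKind.EXTEND_LEFT, "s", 2, 4,
                             "d", 4, 6, "+", 4, 2, -2, 1.0, 0.0, 60.0, 60.0,
                             True, 2)
        patched, _, report = apply_patches(target, [c], donor)
        assert patched["s"] == "ACTTNNGT"
        assert report["n_extensions"] == 1

    def test_rescan_yields_residual_gaps_only(self, small_pair):
        target, donor, truth = small_pair
        result = call_closures(target, donor)
        patched, agp, report = apply_patches(target, result.accepted, donor,
                                             all_gaps=result.gaps)
        closed = {c.gap_id for c in result.accepted}
        residual = detect_gaps(patched)
        expected_bp = sum(g.L0 for g in result.gaps if g.gap_id not in closed)
        expected_bp += sum(c.residual_N for c in result.accepted)
        assert sum(g.L0 for g in residual) == expected_bp

    def test_unaccepted_closure_rejected(self):
        from gapfill.closure import ClosureCandidate
        target = SequenceCollection({"s": "ACNNNNGT"})
        donor = SequenceCollection({"d": "ACGTACGT"})
        c = ClosureCandidate("gap_1", ClosureKind.FULL, "s", 2, 6, "d", 0, 4,
                             "+", 4, 4, 0, 1.0, 0.0, 0.0, 0.0, False, 0)
        with pytest.raises(ValueError, match="not accepted"):
            apply_patches(target, [c], donor)

    def test_agp_rows_tile_patched_objects(self, small_pair):
        target, donor, truth = small_pair
        result = call_closures(target, donor)
        patched, agp, _ = apply_patches(target, result.accepted, donor,
                                        all_gaps=result.gaps)
        by_obj = {}
        for row in agp:
            by_obj.setdefault(row.object, []).append(row)
        for obj, rows in by_obj.items():
            assert rows[0].object_beg == 1
            for r1, r2 in zip(rows, rows[1:]):
                assert r2.object_beg == r1.object_end + 1
                assert r2.part_number == r1.part_number + 1
            assert rows[-1].object_end == len(patched[obj])


class TestCallClosures:
    def test_unmapped_locus_yields_no_candidate(self):
        rng = np.random.default_rng(8)
        B = np.frombuffer(b"ACGT", dtype=np.uint8)
        mk = lambda n: B[rng.integers(0, 4, n)].tobytes().decode()  # noqa: E731
        left, fill, right = mk(20_000), "X" * 0 + mk(500), mk(20_000)
        target = SequenceCollection({"s": left + "N" * 500 + right})
        donor = SequenceCollection({"c": mk(40_000)})  # unrelated sequence
        result = call_closures(target, donor)
        assert result.candidates == []
        assert result.verdicts[0].status is PairStatus.UNMAPPED

    def test_extension_when_contig_breaks_inside_gap(self):
        from gapfill import PairConfig, simulate_pair
        target, donor, truth = simulate_pair(
            3, PairConfig(n_seqs=1, seq_len=1_500_000, n_gaps=3, break_in_gap=1))
        result = call_closures(target, donor)
        ext = [c for c in result.candidates if c.kind is not ClosureKind.FULL]
        assert len(ext) >= 1
        for c in ext:
            assert c.residual_N > 0
            assert c.Qg == 0.0 and c.Q == c.Qa
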