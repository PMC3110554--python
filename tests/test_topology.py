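"""Landmark derivation, pair analyses, TMU segmentation, KD comparison."""

import numpy as np
import pytest

from hpulse import (
    FixtureSpec,
    annotation_from_segments,
    context_association,
    count_pulses_between_tmhs,
    derive_landmarks,
    detect_hpulses,
    kd_classic,
    localize_g2,
    make_tm_protein,
    segment_tmus,
    successive_pairs,
    undetected_tms_rescue,
)
from hpulse.errors import SequenceError
from hpulse.pulses import PulseTrack


def ann(length, helices, tms, kinks=()):
    return annotation_from_segments("t", length, helices, tms, kinks)


def pt(positions):
    return PulseTrack(sequence_id="t", group="G2", pulses=tuple(sorted(positions)))


class TestDeriveLandmarks:
    def test_single_helix_covering_tms(self):
        frames = derive_landmarks(ann(60, [(10, 40)], [(15, 35)]))
        f = frames[0]
        assert (f.A, f.B, f.C, f.D) == (10, 15, 35, 40)

    def test_two_helices_intersecting_one_tms_smallest_cover(self):
        frames = derive_landmarks(ann(60, [(10, 20), (23, 40)], [(15, 35)]))
        f = frames[0]
        assert (f.A, f.D) == (10, 40)

    def test_helix_equal_to_tms_gives_zero_length_caps(self):
        f = derive_landmarks(ann(60, [(15, 35)], [(15, 35)]))[0]
        assert f.A == f.B and f.C == f.D

    def test_tms_without_helix_flagged_helixless(self):
        frames = derive_landmarks(ann(80, [(10, 30)], [(12, 28), (50, 70)]))
        assert not frames[0].helixless
        assert frames[1].helixless

    def test_frames_ordered_by_tms_start(self):
        frames = derive_landmarks(
            ann(120, [(5, 30), (50, 80)], [(55, 75), (10, 25)])
        )
        assert [f.B for f in frames] == [10, 55]


class TestSuccessivePairs:
    def base(self, loop=10, cap=2, L=200):
        # two TMHs with caps of `cap` residues and a loop of `loop`
        h1 = (10, 10 + cap + 20 + cap - 1)
        b1, c1 = 10 + cap, 10 + cap + 19
        e2 = h1[1] + loop + 1
        h2 = (e2, e2 + cap + 20 + cap - 1)
        b2, c2 = e2 + cap, e2 + cap + 19
        return ann(L, [h1, h2], [(b1, c1), (b2, c2)])

    def test_clean_pair_included_with_span(self):
        pairs, rejected = successive_pairs(derive_landmarks(self.base()))
        assert len(pairs) == 1 and not rejected
        p = pairs[0]
        assert p.span == (
            (p.first.B + p.first.C) // 2,
            (p.second.B + p.second.C) // 2,
        )

    def test_long_loop_excluded(self):
        pairs, rejected = successive_pairs(derive_landmarks(self.base(loop=45)))
        assert not pairs
        assert "smaller than 40" in rejected[0][1]

    def test_zero_length_cap_excluded(self):
        pairs, rejected = successive_pairs(derive_landmarks(self.base(cap=0)))
        assert not pairs
        assert "strictly positive" in rejected[0][1]

    def test_de_length_boundary_at_40(self):
        # length of [D;E] is the coordinate difference E - D; with a gap of
        # `loop` residues strictly between the helices, E - D = loop + 1
        assert not successive_pairs(derive_landmarks(self.base(loop=39)))[0]
        assert successive_pairs(derive_landmarks(self.base(loop=38)))[0]


class TestLocalizeG2:
    def pair(self):
        pairs, _ = successive_pairs(
            derive_landmarks(TestSuccessivePairs().base(loop=10))
        )
        return pairs

    def test_mid_loop_pulse_classified_de_and_summary_100pct(self):
        pairs = self.pair()
        D, E = pairs[0].D, pairs[0].E
        per_pair, summary = localize_g2(pairs, pt([(D + E) // 2]))
        assert per_pair[0].locus == "[D;E]"
        assert summary.pulse_pct()["[D;E]"] == 100.0

    def test_pulse_exactly_at_e_belongs_to_ef(self):
        pairs = self.pair()
        per_pair, _ = localize_g2(pairs, pt([pairs[0].E]))
        assert per_pair[0].locus == "[E;F]"

    def test_pulse_at_e_minus_one_belongs_to_de(self):
        pairs = self.pair()
        per_pair, _ = localize_g2(pairs, pt([pairs[0].E - 1]))
        assert per_pair[0].locus == "[D;E]"

    def test_no_pulse_in_span_reports_none(self):
        per_pair, summary = localize_g2(self.pair(), pt([]))
        assert per_pair[0].locus == "none"
        assert summary.n_none == 1

    def test_surplus_pulse_discarded_keeping_closest_to_e(self):
        pairs = self.pair()
        D, E = pairs[0].D, pairs[0].E
        per_pair, summary = localize_g2(pairs, pt([D + 1, E - 1]))
        assert per_pair[0].selected == E - 1
        assert per_pair[0].discarded == (D + 1,)
        assert summary.n_discarded == 1

    def test_residue_and_pulse_fractions_each_sum_to_100(self):
        fx = make_tm_protein(FixtureSpec(n_tmh=4, seed=3))
        pairs, _ = successive_pairs(derive_landmarks(fx.annotation))
        g2 = detect_hpulses(fx.sequence, "G2")
        _, summary = localize_g2(pairs, g2)
        assert sum(summary.residue_pct().values()) == pytest.approx(100.0)
        assert sum(summary.pulse_pct().values()) == pytest.approx(100.0)

    def test_classification_exhaustive_and_exclusive(self):
        pairs = self.pair()
        C, F = pairs[0].C, pairs[0].F
        lo, hi = pairs[0].span
        for p in range(lo, hi + 1):
            per_pair, _ = localize_g2(pairs, pt([p]))
            assert per_pair[0].locus in {"TMS", "[C;D]", "[D;E]", "[E;F]"}


class TestSegmentTmus:
    def test_no_pulses_single_tmu_spanning_region(self):
        a = ann(100, [(10, 30)], [(12, 28)])
        tmus = segment_tmus(pt([]), a)
        assert len(tmus) == 1
        assert (tmus[0].start, tmus[0].end) == (1, 100)

    @pytest.mark.parametrize("seed", range(10))
    def test_k_pulses_tile_region_without_gaps(self, seed):
        rng = np.random.default_rng(seed)
        a = ann(200, [(10, 30)], [(12, 28)])
        pulses = sorted(set(rng.integers(2, 200, size=rng.integers(0, 8)).tolist()))
        tmus = segment_tmus(pt(pulses), a)
        assert tmus[0].start == 1 and tmus[-1].end == 200
        for t1, t2 in zip(tmus, tmus[1:]):
            assert t2.start == t1.end + 1  # no gap, no overlap
        assert len(tmus) == len(pulses) + 1

    def test_interfacial_helix_without_pulse_shares_tmu_with_tmh(self):
        fx = make_tm_protein(
            FixtureSpec(n_tmh=2, loop_length=24, interfacial_helix=True, seed=5)
        )
        g2 = detect_hpulses(fx.sequence, "G2")
        tmus = segment_tmus(g2, fx.annotation)
        counts = [len(t.members) for t in tmus if t.members]
        # the short surrounding helix travels with a TMH inside one TMU
        assert max(counts) >= 2

    def test_helices_assigned_by_start_position(self):
        a = ann(100, [(10, 30), (40, 60)], [(12, 28)])
        tmus = segment_tmus(pt([35]), a)
        assert tmus[0].members == ((10, 30),)
        assert tmus[1].members == ((40, 60),)


class TestCountPulsesBetweenTmhs:
    def test_empty_pair_list_gives_zero_table(self):
        table = count_pulses_between_tmhs([], pt([5]), ann(50, [(5, 20)], [(6, 18)]))
        assert int(table.to_numpy().sum()) == 0

    def test_loop_pulse_without_helix(self):
        base = TestSuccessivePairs().base(loop=10)
        pairs, _ = successive_pairs(derive_landmarks(base))
        D, E = pairs[0].D, pairs[0].E
        table = count_pulses_between_tmhs(pairs, pt([(D + E) // 2]), base)
        assert table.loc["1", "no helix"] == 1

    def test_loop_with_interfacial_helix_and_pulse(self):
        # insert an 8-residue helix strictly inside the loop
        h1, h2 = (10, 33), (44, 67)
        mid_h = (36, 41)
        a = ann(100, [h1, mid_h, h2], [(12, 31), (46, 65)])
        pairs, _ = successive_pairs(derive_landmarks(a))
        D, E = pairs[0].D, pairs[0].E
        table = count_pulses_between_tmhs(pairs, pt([(D + E) // 2]), a)
        assert table.loc["1", "one helix"] == 1


class TestContextAssociation:
    def synthetic_annotation(self, rng, L=1000):
        helices, tms = [], []
        pos = 20
        while pos + 30 < L - 20:
            helices.append((pos, pos + 24))
            tms.append((pos + 2, pos + 22))
            pos += 60
        return ann(L, helices, tms)

    def test_pulses_at_nonhelical_tm_residues_highly_significant(self):
        rng = np.random.default_rng(0)
        a = self.synthetic_annotation(rng)
        tm = a.tm_context_mask(40)
        nonhel_tm = np.flatnonzero(tm & ~a.helical) + 1
        pulses = rng.choice(nonhel_tm, size=60, replace=False)
        table = context_association(pt(pulses.tolist()), a)
        assert table.p_tm < 1e-4

    def test_uniform_pulses_not_significant(self):
        rng = np.random.default_rng(1)
        a = self.synthetic_annotation(rng)
        pulses = rng.choice(np.arange(1, a.length + 1), size=60, replace=False)
        table = context_association(pt(pulses.tolist()), a)
        assert table.p_tm > 0.01

    def test_null_calibration_about_five_percent(self):
        # with pulses uniform over residues, p < 0.05 should occur ~5% of runs
        rng = np.random.default_rng(42)
        a = self.synthetic_annotation(rng)
        hits = 0
        reps = 100
        for _ in range(reps):
            pulses = rng.choice(np.arange(1, a.length + 1), size=60, replace=False)
            if context_association(pt(pulses.tolist()), a).p_tm < 0.05:
                hits += 1
        assert 0 <= hits <= 12

    def test_zero_pulses_degenerate_table_undefined_p(self):
        a = self.synthetic_annotation(np.random.default_rng(2))
        table = context_association(pt([]), a)
        assert np.isnan(table.p_tm) and np.isnan(table.p_non_tm)
        assert table.counts["pulses"].sum() == 0

    def test_counts_sum_to_evaluated_positions(self):
        a = self.synthetic_annotation(np.random.default_rng(3))
        table = context_association(pt([50, 100, 150]), a)
        assert table.counts["residues"].sum() == a.length
        assert table.counts["pulses"].sum() == 3


class TestKdClassic:
    def test_poly_isoleucine_every_position_peaks(self):
        profile = kd_classic("I" * 40)
        defined = profile.averages[~np.isnan(profile.averages)]
        assert np.allclose(defined, 4.5)
        assert profile.has_peak(1, 40)

    def test_poly_glycine_never_peaks(self):
        profile = kd_classic("G" * 40)
        assert not profile.has_peak(1, 40)

    def test_window_mean_matches_direct_sum(self):
        from hpulse import KD_SCALE
        rng = np.random.default_rng(9)
        from conftest import random_sequence
        seq = random_sequence(rng, 60)
        profile = kd_classic(seq)
        for i in range(10, 51):  # 1-based centres with full window
            window = seq[i - 10 : i + 9]
            expect = sum(KD_SCALE[a] for a in window) / 19
            assert profile.averages[i - 1] == pytest.approx(expect)

    def test_short_sequence_rejected(self):
        with pytest.raises(SequenceError, match="19"):
            kd_classic("A" * 10)


class TestUndetectedTmsRescue:
    def weak_middle_fixture(self):
        # 3 TMS; the middle one alternates M/S, whose 19-window mean
        # (~0.6 KD) never reaches the 1.6 peak threshold
        seq = (
            "S" * 15 + "I" * 21 + "S" * 15
            + "MS" * 10 + "M"
            + "S" * 15 + "I" * 21 + "S" * 15
        )
        L = len(seq)
        t1 = (16, 36)
        t2 = (52, 72)
        t3 = (88, 108)
        a = ann(L, [t1, t2, t3], [t1, t2, t3])
        return seq, a

    def test_weak_middle_tms_is_unpeaked_and_rescued(self):
        seq, a = self.weak_middle_fixture()
        profile = kd_classic(seq)
        g2 = detect_hpulses(seq, "G2")
        report = undetected_tms_rescue(a, profile, g2)
        assert report[0].peaked and report[2].peaked
        middle = report[1]
        assert not middle.peaked
        # brute-force interval scan: any pulse strictly between TMS1 end
        # and TMS2 end?
        expect = any(36 < p < 72 for p in g2.pulses)
        assert middle.rescued == expect

    def test_unpeaked_tms_without_preceding_pulse_not_rescued(self):
        a = ann(100, [(20, 40)], [(20, 40)])
        profile = kd_classic("G" * 100)
        report = undetected_tms_rescue(a, profile, pt([]))
        assert report[0].peaked is False and report[0].rescued is False

    def test_first_tms_counts_pulses_from_sequence_start(self):
        a = ann(100, [(20, 40)], [(20, 40)])
        profile = kd_classic("G" * 100)
        report = undetected_tms_rescue(a, profile, pt([10]))
        assert report[0].rescued is True
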