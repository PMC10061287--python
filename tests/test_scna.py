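"""SCNA segment scoring, event classification, burden levels."""

import numpy as np
import pandas as pd
import pytest

from clonarch.records import ArmModel, SegmentRecord
from clonarch.scna import (
    classify_segments,
    coalesce_segments,
    frequent_arm_events,
    score_levels,
    segment_score,
)

TOY_ARMS = ArmModel(
    {
        "1": {"p": (1, 40_000_000), "q": (40_000_001, 100_000_000)},
        "2": {"p": (1, 30_000_000), "q": (30_000_001, 80_000_000)},
        "3": {"q": (1, 60_000_000)},
        "4": {"p": (1, 20_000_000), "q": (20_000_001, 70_000_000)},
    }
)


def toy_segments(sample="T1"):
    """Hand-constructed 20-segment genome with hand-computed scores:

    chrom 1: both arms > 50% deleted -> chromosome deletion (ChromL 1+1)
    chrom 2: 2p 80% amplified -> arm amplification (ArmL 1);
             2q focal (2,1) and (3,0) -> FocalL 1+2
    chrom 3 (q-only): 55% + 28% deleted -> chromosome deletion (ChromL 1+1)
    chrom 4: three focal events (2,2), (1,0), (2,0) -> FocalL 1+1+2
    """
    return [
        SegmentRecord(sample, "1", 1, 24_000_000, 1, 0),
        SegmentRecord(sample, "1", 24_000_001, 40_000_000, 1, 1),
        SegmentRecord(sample, "1", 40_000_001, 82_000_000, 1, 0),
        SegmentRecord(sample, "1", 82_000_001, 100_000_000, 1, 1),
        SegmentRecord(sample, "2", 1, 24_000_000, 2, 1),
        SegmentRecord(sample, "2", 24_000_001, 30_000_000, 1, 1),
        SegmentRecord(sample, "2", 30_000_001, 40_000_000, 2, 1),
        SegmentRecord(sample, "2", 40_000_001, 45_000_000, 3, 0),
        SegmentRecord(sample, "2", 45_000_001, 80_000_000, 1, 1),
        SegmentRecord(sample, "3", 1, 33_000_000, 1, 0),
        SegmentRecord(sample, "3", 33_000_001, 50_000_000, 0, 0),
        SegmentRecord(sample, "3", 50_000_001, 60_000_000, 1, 1),
        SegmentRecord(sample, "4", 1, 5_000_000, 2, 2),
        SegmentRecord(sample, "4", 5_000_001, 20_000_000, 1, 1),
        SegmentRecord(sample, "4", 20_000_001, 30_000_000, 1, 1),
        SegmentRecord(sample, "4", 30_000_001, 34_000_000, 1, 0),
        SegmentRecord(sample, "4", 34_000_001, 50_000_000, 1, 1),
        SegmentRecord(sample, "4", 50_000_001, 52_000_000, 2, 0),
        SegmentRecord(sample, "4", 52_000_001, 60_000_000, 1, 1),
        SegmentRecord(sample, "4", 60_000_001, 70_000_000, 1, 1),
    ]


def all_normal(sample="N1"):
    out = []
    for chrom, arm_map in TOY_ARMS.arms.items():
        for s, e in arm_map.values():
            out.append(SegmentRecord(sample, chrom, s, e, 1, 1))
    return out


class TestSegmentScore:
    @pytest.mark.parametrize(
        "major,minor,expected",
        [
            (1, 1, 0),
            (3, 0, 2),
            (2, 0, 2),
            (1, 0, 1),
            (2, 1, 1),
            (0, 0, 1),
            (2, 2, 1),
            (5, 2, 1),
        ],
    )
    def test_case_analysis(self, major, minor, expected):
        assert segment_score(major, minor) == expected

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            segment_score(1, -1)


class TestClassify:
    def test_single_arm_deletion_is_arm_level_only(self):
        segs = [
            SegmentRecord("T", "1", 1, 40_000_000, 1, 0),  # 1p fully deleted
            SegmentRecord("T", "1", 40_000_001, 100_000_000, 1, 1),
        ]
        events, scopes = classify_segments(segs, TOY_ARMS)
        assert [(e.scope, e.sign) for e in events] == [("arm", "deletion")]
        assert scopes == ["arm", None]

    def test_both_arms_same_sign_is_chromosome_event(self):
        segs = [
            SegmentRecord("T", "1", 1, 25_000_000, 2, 1),  # 62.5% of 1p
            SegmentRecord("T", "1", 25_000_001, 40_000_000, 1, 1),
            SegmentRecord("T", "1", 40_000_001, 77_000_000, 2, 1),  # 61.7% of 1q
            SegmentRecord("T", "1", 77_000_001, 100_000_000, 1, 1),
        ]
        events, scopes = classify_segments(segs, TOY_ARMS)
        assert [(e.scope, e.sign) for e in events] == [
            ("chromosome", "amplification")
        ]
        assert scopes == ["chromosome", None, "chromosome", None]

    def test_below_threshold_is_focal(self):
        segs = [
            SegmentRecord("T", "1", 1, 4_000_000, 1, 0),  # 10% of 1p
            SegmentRecord("T", "1", 4_000_001, 40_000_000, 1, 1),
        ]
        events, scopes = classify_segments(segs, TOY_ARMS)
        assert [(e.scope, e.sign) for e in events] == [("focal", "deletion")]
        assert scopes == ["focal", None]

    def test_exactly_half_does_not_trigger_arm_event(self):
        segs = [SegmentRecord("T", "1", 1, 20_000_000, 1, 0),
                SegmentRecord("T", "1", 20_000_001, 40_000_000, 1, 1)]
        events, _ = classify_segments(segs, TOY_ARMS)
        assert events[0].scope == "focal"

    def test_segment_beyond_arm_model_rejected(self):
        with pytest.raises(ValueError, match="extends beyond"):
            classify_segments(
                [SegmentRecord("T", "1", 39_999_999, 41_000_000, 1, 0)], TOY_ARMS
            )

    def test_partition_every_altered_segment_has_one_scope(self):
        events, scopes = classify_segments(toy_segments(), TOY_ARMS)
        segs = toy_segments()
        for seg, scope in zip(segs, scopes):
            if segment_score(seg.major, seg.minor) > 0:
                assert scope in ("chromosome", "arm", "focal")
            else:
                assert scope is None

    def test_event_ccfs_are_length_weighted(self):
        segs = [
            SegmentRecord("T", "1", 1, 30_000_000, 1, 0),
            SegmentRecord("T", "1", 30_000_001, 40_000_000, 1, 0),
            SegmentRecord("T", "1", 40_000_001, 100_000_000, 1, 1),
        ]
        events, _ = classify_segments(segs, TOY_ARMS, segment_ccfs=[1.0, 0.4, np.nan])
        arm_ev = [e for e in events if e.scope == "arm"][0]
        assert arm_ev.ccf == pytest.approx((30 * 1.0 + 10 * 0.4) / 40)
        assert arm_ev.clonality == "subclonal"


class TestScoreLevels:
    def test_toy_genome_hand_computed_scores(self):
        cohort = {"T1": toy_segments(), "N1": all_normal()}
        scores = score_levels(cohort, TOY_ARMS)
        assert scores.loc["T1", "ChromL"] == 4
        assert scores.loc["T1", "ArmL"] == 1
        assert scores.loc["T1", "FocalL"] == 7
        assert scores.loc["N1", ["ChromL", "ArmL", "FocalL"]].tolist() == [0, 0, 0]
        assert scores.loc["N1", "total_normalized"] == 0.0
        assert scores.loc["T1", "total_normalized"] == pytest.approx(
            12 / 310_000_000
        )

    def test_z_scores_standardised(self):
        cohort = {"T1": toy_segments(), "N1": all_normal()}
        scores = score_levels(cohort, TOY_ARMS)
        for col in ("z_ChromL", "z_ArmL", "z_FocalL"):
            assert scores[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert scores[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_splitting_invariance(self):
        def bisect(seg):
            if seg.length < 2:
                return [seg]
            mid = seg.start + seg.length // 2 - 1
            return [
                SegmentRecord(seg.sample_id, seg.chrom, seg.start, mid, seg.major, seg.minor),
                SegmentRecord(seg.sample_id, seg.chrom, mid + 1, seg.end, seg.major, seg.minor),
            ]

        split = [piece for seg in toy_segments() for piece in bisect(seg)]
        base = score_levels({"T1": toy_segments(), "N1": all_normal()}, TOY_ARMS)
        resplit = score_levels({"T1": split, "N1": all_normal()}, TOY_ARMS)
        pd.testing.assert_frame_equal(base, resplit)

    def test_whole_genome_doubling_surrogate_increases_chroml(self):
        doubled = [
            SegmentRecord(s.sample_id, s.chrom, s.start, s.end, s.major + 1, s.minor + 1)
            for s in all_normal("T1")
        ]
        scores = score_levels({"T1": doubled, "N1": all_normal()}, TOY_ARMS)
        assert scores.loc["T1", "ChromL"] > 0

    def test_single_sample_cohort_rejected(self):
        with pytest.raises(ValueError):
            score_levels({"T1": toy_segments()}, TOY_ARMS)


class TestCoalesce:
    def test_merges_contiguous_same_state_within_arm(self):
        segs = [
            SegmentRecord("T", "4", 1, 10_000_000, 1, 1),
            SegmentRecord("T", "4", 10_000_001, 20_000_000, 1, 1),  # same arm
            SegmentRecord("T", "4", 20_000_001, 70_000_000, 1, 1),  # q arm
        ]
        merged = coalesce_segments(segs, TOY_ARMS)
        assert len(merged) == 2  # p and q runs stay separate


class TestFrequentArms:
    def _events(self, freq_fraction, n=10):
        from clonarch.scna import ScnaEvent

        events = {}
        n_carry = int(round(freq_fraction * n))
        for i in range(n):
            sample = f"S{i}"
            events[sample] = (
                [ScnaEvent(sample, "arm", "9", "p", "deletion")] if i < n_carry else []
            )
        return events

    def test_boundary_inclusive_at_30_percent(self):
        kept = frequent_arm_events(self._events(0.3), min_freq=0.30)
        assert len(kept) == 1
        dropped = frequent_arm_events(self._events(0.2), min_freq=0.30)
        assert len(dropped) == 0

    def test_chromosome_events_count_for_their_arms(self):
        from clonarch.scna import ScnaEvent

        events = {
            f"S{i}": [ScnaEvent(f"S{i}", "chromosome", "1", None, "deletion")]
            for i in range(10)
        }
        kept = frequent_arm_events(events, min_freq=0.30, arms=TOY_ARMS)
        assert set(map(tuple, kept[["chrom", "arm"]].values)) == {("1", "p"), ("1", "q")}
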