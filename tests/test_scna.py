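"""Copy-number concordance: GI, binning, correlation, focal matching.

The gi_score and bin_profile implementations are checked against per-base
brute-force oracles materialized as numpy arrays over a small toy genome.
"""

import numpy as np
import pandas as pd
import pytest

from pdxevo.errors import DegenerateDataError
from pdxevo.scna import (
    ArmDefinition,
    FocalEvent,
    Segment,
    bin_profile,
    call_wgd,
    detect_focal,
    gi_score,
    match_focal,
    profile_correlation,
    rescue_focal,
)

ARM = ArmDefinition("chr1", "p", 0, 40_000_000)


class TestWgd:
    @pytest.mark.parametrize("ploidy,expected", [(2.6, True), (2.5, False), (1.9, False)])
    def test_strict_threshold(self, ploidy, expected):
        assert call_wgd(ploidy) is expected


# --- per-base oracles -------------------------------------------------------

def _per_base_array(segments, chrom, length):
    arr = np.full(length, np.nan)
    for seg in segments:
        if seg.chrom == chrom:
            arr[seg.start:seg.end] = seg.log2_ratio
    return arr


def _oracle_gi(segments, arms, threshold=0.3):
    per_arm = {}
    for arm in arms:
        arr = _per_base_array(segments, arm.chrom, arm.end)[arm.start:arm.end]
        covered = ~np.isnan(arr)
        if covered.sum() == 0:
            continue
        per_arm[arm.name] = (np.abs(arr[covered]) > threshold).mean()
    return per_arm, float(np.mean(list(per_arm.values())))


def _oracle_bins(segments, chrom_lengths, bin_size):
    values = {}
    for chrom, length in chrom_lengths.items():
        arr = _per_base_array(segments, chrom, length)
        for start in range(0, length, bin_size):
            chunk = arr[start:start + bin_size]
            values[(chrom, start)] = (
                np.nan if np.isnan(chunk).all() else np.nanmean(chunk)
            )
    return pd.Series(values)


def _random_segmentation(rng, chrom="chr1", length=10_000_000, n_breaks=12):
    breaks = np.sort(rng.choice(np.arange(1, length), size=n_breaks, replace=False))
    bounds = np.concatenate([[0], breaks, [length]])
    ratios = rng.choice([-1.0, -0.5, -0.2, 0.0, 0.2, 0.35, 0.58, 1.0], len(bounds) - 1)
    return [
        Segment(chrom, int(a), int(b), float(r))
        for a, b, r in zip(bounds[:-1], bounds[1:], ratios)
    ]


class TestGiScore:
    def test_flat_genome_scores_zero(self):
        segs = [Segment("chr1", 0, 40_000_000, 0.0)]
        _, total = gi_score(segs, [ARM])
        assert total == 0.0

    def test_fully_gained_genome_scores_one(self):
        segs = [Segment("chr1", 0, 40_000_000, 0.5)]
        _, total = gi_score(segs, [ARM])
        assert total == 1.0

    def test_partial_arm_alteration_and_mean_over_arms(self):
        arms = [ARM, ArmDefinition("chr2", "p", 0, 50_000_000)]
        segs = [
            Segment("chr1", 0, 10_000_000, 0.4),
            Segment("chr1", 10_000_000, 40_000_000, 0.0),
            Segment("chr2", 0, 50_000_000, 0.0),
        ]
        per_arm, total = gi_score(segs, arms)
        assert per_arm["chr1p"] == pytest.approx(0.25)
        assert total == pytest.approx(0.25 / 2)

    def test_threshold_is_strict(self):
        segs = [Segment("chr1", 0, 40_000_000, 0.3)]
        _, total = gi_score(segs, [ARM])
        assert total == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        segs = _random_segmentation(rng)
        arms = [
            ArmDefinition("chr1", "p", 0, 4_500_000),
            ArmDefinition("chr1", "q", 5_500_000, 10_000_000),
        ]
        per_arm, total = gi_score(segs, arms)
        o_per_arm, o_total = _oracle_gi(segs, arms)
        for name in o_per_arm:
            assert per_arm[name] == pytest.approx(o_per_arm[name], abs=1e-12)
        assert total == pytest.approx(o_total, abs=1e-12)

    def test_no_coverage_signalled(self):
        with pytest.raises(DegenerateDataError):
            gi_score([Segment("chr9", 0, 100, 0.0)], [ARM])


class TestBinProfile:
    LENGTHS = {"chr1": 10_000_000}

    def test_full_bin_takes_segment_value(self):
        segs = [Segment("chr1", 0, 1_000_000, 0.3)]
        prof = bin_profile(segs, self.LENGTHS)
        assert prof[("chr1", 0)] == pytest.approx(0.3)
        assert np.isnan(prof[("chr1", 1_000_000)])

    def test_half_bins_average_by_overlap(self):
        segs = [
            Segment("chr1", 0, 500_000, 0.4),
            Segment("chr1", 500_000, 1_000_000, 0.0),
        ]
        prof = bin_profile(segs, self.LENGTHS)
        assert prof[("chr1", 0)] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_agrees_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        segs = _random_segmentation(rng)
        prof = bin_profile(segs, self.LENGTHS)
        oracle = _oracle_bins(segs, self.LENGTHS, 1_000_000)
        for key in oracle.index:
            if np.isnan(oracle[key]):
                assert np.isnan(prof[key])
            else:
                assert prof[key] == pytest.approx(oracle[key], abs=1e-12)


class TestProfileCorrelation:
    def _profile(self, values):
        idx = pd.MultiIndex.from_tuples(
            [("chr1", i) for i in range(len(values))], names=["chrom", "bin_start"]
        )
        return pd.Series(values, index=idx, dtype=float)

    def test_identical_profiles_are_perfectly_correlated(self):
        a = self._profile([0.1, 0.5, -0.3, 0.0, 0.2])
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_negated_profile_is_anticorrelated(self):
        a = self._profile([0.1, 0.5, -0.3, 0.0, 0.2])
        assert profile_correlation(a, -a) == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.5, -0.1, 0.4, 0.0, -0.2, 0.25])
        y = np.array([0.05, 0.0, 0.25, 0.2, 0.45, 0.0, 0.5, -0.1, -0.15, 0.3])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r = profile_correlation(self._profile(x), self._profile(y))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_signalled(self):
        flat = self._profile([0.2, 0.2, 0.2, 0.2])
        with pytest.raises(DegenerateDataError):
            profile_correlation(flat, self._profile([0.1, 0.2, 0.3, 0.4]))

    def test_too_few_joint_bins_signalled(self):
        a = self._profile([0.1, np.nan, np.nan, 0.3])
        b = self._profile([0.2, 0.1, 0.4, np.nan])
        with pytest.raises(DegenerateDataError):
            profile_correlation(a, b)


class TestDetectFocal:
    def test_short_gained_segment_is_an_amplification(self):
        segs = [Segment("chr1", 5_000_000, 15_000_000, 0.5)]
        events = detect_focal(segs, [ARM])
        assert len(events) == 1 and events[0].direction == "amplification"

    def test_segment_covering_most_of_the_arm_is_not_focal(self):
        segs = [Segment("chr1", 0, 30_000_000, 0.5)]  # 75% of a 40-Mb arm
        assert detect_focal(segs, [ARM]) == []

    def test_ratio_threshold_is_strict(self):
        segs = [Segment("chr1", 5_000_000, 15_000_000, 0.3)]
        assert detect_focal(segs, [ARM]) == []


def _event(start, end, ratio=0.5, chrom="chr1"):
    direction = "amplification" if ratio > 0 else "deletion"
    return FocalEvent(Segment(chrom, start, end, ratio), "chr1p", direction)


class TestMatchFocal:
    def test_identical_events_match(self):
        a, b = _event(1_000_000, 2_000_000), _event(1_000_000, 2_000_000)
        matched, un_a, un_b = match_focal([a], [b])
        assert len(matched) == 1 and not un_a and not un_b

    def test_window_boundary_10kb_inclusive(self):
        a = _event(1_000_000, 2_000_000)
        within = _event(1_010_000, 2_000_000)
        beyond = _event(1_010_001, 2_000_000)
        assert len(match_focal([a], [within])[0]) == 1
        assert len(match_focal([a], [beyond])[0]) == 0

    def test_opposite_directions_never_match(self):
        a = _event(1_000_000, 2_000_000, 0.5)
        b = _event(1_000_000, 2_000_000, -0.5)
        matched, un_a, un_b = match_focal([a], [b])
        assert not matched and un_a == [a] and un_b == [b]

    def test_matching_is_symmetric(self):
        evs_a = [_event(1_000_000, 2_000_000), _event(5_000_000, 5_400_000)]
        evs_b = [_event(1_004_000, 2_003_000), _event(5_002_000, 5_408_000),
                 _event(9_000_000, 9_500_000)]
        fwd, _, _ = match_focal(evs_a, evs_b)
        rev, _, _ = match_focal(evs_b, evs_a)
        assert {(a.segment.start, b.segment.start) for a, b in fwd} == {
            (b.segment.start, a.segment.start) for a, b in rev
        }

    def test_ties_resolved_by_smallest_breakpoint_distance(self):
        a = _event(1_000_000, 2_000_000)
        near = _event(1_000_500, 2_000_500)
        far = _event(1_009_000, 2_009_000)
        matched, _, un_b = match_focal([a], [far, near])
        assert matched[0][1] is near and un_b == [far]


class TestRescueFocal:
    def test_paired_segment_above_relaxed_threshold_rescues(self):
        event = _event(1_000_000, 2_000_000, 0.5)
        paired = [Segment("chr1", 1_002_000, 2_001_000, 0.15)]
        rescued = rescue_focal([event], paired)
        assert len(rescued) == 1 and rescued[0][1].provenance == "rescued"

    def test_relaxed_threshold_is_strict_at_point_one(self):
        event = _event(1_000_000, 2_000_000, 0.5)
        assert rescue_focal([event], [Segment("chr1", 1_000_000, 2_000_000, 0.1)]) == []
        assert len(
            rescue_focal([event], [Segment("chr1", 1_000_000, 2_000_000, 0.100001)])
        ) == 1

    def test_weak_or_distant_paired_segments_do_not_rescue(self):
        event = _event(1_000_000, 2_000_000, 0.5)
        assert rescue_focal([event], [Segment("chr1", 1_000_000, 2_000_000, 0.05)]) == []
        assert rescue_focal([event], [Segment("chr1", 1_020_000, 2_000_000, 0.5)]) == []

    def test_deletion_needs_negative_paired_ratio(self):
        event = _event(1_000_000, 2_000_000, -0.5)
        assert rescue_focal([event], [Segment("chr1", 1_000_000, 2_000_000, 0.2)]) == []
        assert len(
            rescue_focal([event], [Segment("chr1", 1_000_000, 2_000_000, -0.2)])
        ) == 1
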