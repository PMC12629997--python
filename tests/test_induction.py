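import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inductr.coverage import BinnedCoverage
from inductr.induction import (
    DEFAULT_HALLMARK_CUTOFFS,
    HallmarkHit,
    InductionStatistics,
    call_induction,
    cohens_d,
    derive_length_cutoff,
    filter_hallmarks,
    fold_change,
    refine_boundaries,
    region_statistics,
    zscore_ave,
)
from inductr.regions import ProphageRegion, merge_overlapping

from conftest import naive_cohens_d, naive_zscore_ave


def track_from(host, phage):
    host, phage = list(map(float, host)), list(map(float, phage))
    depths = np.array(host + phage)
    labels = np.array(["host"] * len(host) + ["p"] * len(phage), dtype=object)
    return BinnedCoverage("c", 100, len(depths) * 100, depths, labels)


class TestZScoreAve:
    def test_phage_at_host_median_is_zero(self):
        assert zscore_ave(track_from([8, 9, 10, 11, 12], [10, 10]), "p") == 0

    def test_hand_example(self):
        # host median 10, MAD 1; phage bins at 20 -> 0.6745 * 10
        t = track_from([8, 9, 10, 10, 10, 11, 12], [20, 20])
        assert zscore_ave(t, "p") == pytest.approx(6.745, abs=1e-12)

    def test_flat_host_gives_nan_not_exception(self):
        assert math.isnan(zscore_ave(track_from([10] * 5, [50, 50]), "p"))

    def test_no_host_bins_is_error(self):
        t = track_from([10], [50, 50])
        with pytest.raises(ValueError):
            zscore_ave(t, "p")


class TestCohensD:
    def test_identical_distributions_zero(self):
        assert cohens_d(track_from([10, 12, 8, 10], [10, 12, 8, 10]), "p") == 0

    def test_sign_negative_for_elevated_region(self):
        d = cohens_d(track_from([8, 12, 10, 10], [18, 22, 20, 20]), "p")
        assert d == pytest.approx(-6.123724356957945)

    def test_both_sides_constant_gives_nan(self):
        assert math.isnan(cohens_d(track_from([10, 10], [10, 10]), "p"))

    def test_too_few_bins_is_error(self):
        with pytest.raises(ValueError):
            cohens_d(track_from([10, 11, 12], [50]), "p")


class TestOracleEquivalence:
    """Vectorized statistics match the naive per-bin loop references."""

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        host=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=3, max_size=60),
        phage=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=30),
    )
    def test_agree_with_loop_oracle(self, host, phage):
        t = track_from(host, phage)
        for fast, slow in [
            (zscore_ave(t, "p"), naive_zscore_ave(host, phage)),
            (cohens_d(t, "p"), naive_cohens_d(host, phage)),
        ]:
            if math.isnan(slow):
                assert math.isnan(fast)
            else:
                assert fast == pytest.approx(slow, abs=1e-9, rel=1e-9)


class TestFoldChange:
    def test_at_host_median_is_one(self):
        assert fold_change(track_from([9, 10, 11], [10, 10]), "p") == 1.0

    def test_hand_arithmetic(self):
        assert fold_change(track_from([9, 10, 11], [30, 50]), "p") == 4.0

    def test_zero_host_gives_nan(self):
        assert math.isnan(fold_change(track_from([0, 0, 0], [5, 5]), "p"))

    def test_mean_baseline_option(self):
        t = track_from([0, 10, 20], [30, 30])
        assert fold_change(t, "p", baseline="mean") == 3.0
        assert fold_change(t, "p", baseline="median") == 3.0


class TestCallRule:
    @pytest.mark.parametrize(
        "z, fold, d, expected",
        [
            (3.5, 1.0, 0.0, True),  # z clause alone at the threshold
            (2.0, 2.0, -0.71, True),  # fold + |d| clause
            (2.0, 1.9, -5.0, False),  # fold below 2 blocks the second clause
            (2.0, 5.0, -0.7, False),  # |d| must exceed 0.7 strictly
            (3.49, 1.0, 0.0, False),
            (math.nan, 2.5, -1.0, True),  # undefined z fails only its clause
            (4.0, math.nan, math.nan, True),
            (math.nan, math.nan, math.nan, False),
        ],
    )
    def test_decision_table(self, z, fold, d, expected):
        stats = InductionStatistics("r", z_ave=z, fold_change=fold, cohens_d=d)
        assert call_induction(stats) is expected

    def test_region_statistics_end_to_end(self):
        t = track_from([8, 9, 10, 10, 11, 12, 10, 9], [40, 42, 38, 41])
        stats = region_statistics(t, "p", sample_id="s1")
        assert stats.induced
        assert stats.fold_change > 2 and abs(stats.cohens_d) > 0.7


class TestRefineBoundaries:
    def track(self, bins):
        return BinnedCoverage("c", 100, len(bins) * 100, np.array(bins, float))

    def test_flanking_low_bins_trimmed(self):
        t = self.track([1, 1, 50, 60, 55, 1])
        refined = refine_boundaries(t, ProphageRegion("c", 0, 600, "r"))
        assert (refined.start, refined.end) == (200, 500)

    def test_uniform_region_unchanged(self):
        t = self.track([50] * 6)
        r = ProphageRegion("c", 0, 600, "r")
        assert refine_boundaries(t, r) == r

    def test_interior_dip_survives(self):
        t = self.track([50, 1, 50])
        r = ProphageRegion("c", 0, 300, "r")
        assert refine_boundaries(t, r) == r

    def test_zero_coverage_region_unchanged(self):
        # threshold is 25% of the region's own mean, so a region can never
        # trim itself empty; an all-zero region has threshold 0 and survives
        t = self.track([0.0, 0.0, 100.0])
        r = ProphageRegion("c", 0, 200, "r")
        assert refine_boundaries(t, r) == r

    def test_idempotent_and_contained(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            bins = rng.uniform(0, 100, size=rng.integers(3, 30))
            t = self.track(list(bins))
            r = ProphageRegion("c", 0, t.contig_length, "r")
            once = refine_boundaries(t, r)
            if once is None:
                continue
            assert r.start <= once.start <= once.end <= r.end
            assert refine_boundaries(t, once) == once


class TestMergeOverlapping:
    def test_overlap_merges(self):
        merged = merge_overlapping(
            [ProphageRegion("c", 10, 100), ProphageRegion("c", 50, 150)]
        )
        assert [(r.start, r.end) for r in merged] == [(10, 150)]

    def test_half_open_abutting_does_not_merge(self):
        merged = merge_overlapping(
            [ProphageRegion("c", 10, 100), ProphageRegion("c", 100, 150)]
        )
        assert [(r.start, r.end) for r in merged] == [(10, 100), (100, 150)]

    def test_sweep_example(self):
        merged = merge_overlapping(
            [
                ProphageRegion("c", 0, 50),
                ProphageRegion("c", 40, 90),
                ProphageRegion("c", 200, 300),
            ]
        )
        assert [(r.start, r.end) for r in merged] == [(0, 90), (200, 300)]

    def test_completeness_is_max_of_members(self):
        merged = merge_overlapping(
            [
                ProphageRegion("c", 0, 50, completeness=30),
                ProphageRegion("c", 40, 90, completeness=80),
            ]
        )
        assert merged[0].completeness == 80

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 100)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_invariant_and_span_conserved(self, raw):
        regions = [ProphageRegion("c", s, s + l) for s, l in raw]
        merged = merge_overlapping(regions)
        reversed_merge = merge_overlapping(regions[::-1])
        assert [(r.start, r.end) for r in merged] == [
            (r.start, r.end) for r in reversed_merge
        ]
        covered = set()
        for r in regions:
            covered.update(range(r.start, r.end))
        merged_cov = set()
        for r in merged:
            span = set(range(r.start, r.end))
            assert not (merged_cov & span)  # pairwise disjoint
            merged_cov |= span
        assert merged_cov == covered


class TestHallmarks:
    def test_cutoff_all_equal(self):
        assert derive_length_cutoff([500] * 6) == 250

    def test_cutoff_middle_eighty(self):
        assert derive_length_cutoff(list(range(1, 101))) == pytest.approx(25.25)

    def test_cutoff_needs_five_values(self):
        with pytest.raises(ValueError):
            derive_length_cutoff([100, 200])

    @pytest.mark.parametrize(
        "gene, length, retained",
        [
            ("terminase_large", 300, True),
            ("terminase_large", 200, False),
            ("portal", 245, True),
            ("major_head", 185, False),
        ],
    )
    def test_published_cutoffs(self, gene, length, retained):
        hits = [HallmarkHit("ctg", gene, length)]
        assert (("ctg" in filter_hallmarks(hits)) is retained)

    def test_no_hits_drops_contig(self):
        assert filter_hallmarks([]) == set()

    def test_unknown_class_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="no cut-off"):
            assert filter_hallmarks([HallmarkHit("ctg", "mystery", 999)]) == set()

    def test_default_cutoffs_match_published_values(self):
        assert DEFAULT_HALLMARK_CUTOFFS == {
            "terminase_large": 265,
            "portal": 245,
            "major_head": 186,
        }
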