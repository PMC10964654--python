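"""Distance ranges, distance arrays, refinement, and log-odds histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hippo as hp
from hippo.cg_model import CGStructure
from hippo.errors import PotentialError
from hippo.pose_pool import LABEL_NEAR, LABEL_NON, Pose, PosePool
from hippo.potential import (
    NEAR_COL,
    NON_COL,
    DistanceArray,
    RangeSet,
    RankStrata,
    derive_histogram,
    refine_distance_array,
)


class TestRangeSet:
    def test_default_discretization(self):
        rs = hp.make_range_set()
        assert len(rs) == 27
        assert rs.interval(0) == (0.0, 2.0)
        assert rs.interval(1) == (2.0, 2.25)
        assert rs.interval(26) == (14.5, math.inf)

    def test_coarse_variant_enumerated_by_hand(self):
        rs = hp.make_range_set(fine_step=5.0, coarse_step=7.5)
        assert [rs.interval(k) for k in range(len(rs))] == [
            (0.0, 2.0), (2.0, 7.0), (7.0, 14.5), (14.5, math.inf)
        ]

    def test_right_closed_boundaries(self):
        rs = hp.make_range_set()
        assert rs.bin_of(2.0) == 0  # 2.0 belongs to (0, 2]
        assert rs.bin_of(2.25) == 1
        assert rs.bin_of(3.1) == rs.bin_of(3.25)
        assert rs.interval(int(rs.bin_of(3.1))) == (3.0, 3.25)
        assert rs.bin_of(100.0) == 26

    def test_non_dividing_step_rejected(self):
        with pytest.raises(PotentialError):
            hp.make_range_set(fine_step=0.3)


class TestRankStrata:
    def test_reference_bounds(self):
        s = RankStrata()
        assert s.bounds == (0, 100_000, 1_000_000, 10_000_000)
        assert list(s.stratum_of([0, 99_999, 100_000, 999_999, 1_000_000])) == [
            0, 0, 1, 1, 2,
        ]

    def test_scaled_preserves_proportions(self):
        s = RankStrata.scaled(6000)
        assert s.bounds == (0, 60, 600, 6000)
        assert s.n_strata == 3

    def test_rank_outside_cover_rejected(self):
        with pytest.raises(PotentialError):
            RankStrata.scaled(100).stratum_of([100])


def _one_contact_pool():
    """One near-native + one non-native pose, single receptor bead."""
    rec = CGStructure.from_arrays("protein", [1], [[0.0, 0.0, 0.0]])
    near = Pose("n", [[3.1, 0.0, 0.0]], asf_rank=0, lrmsd=1.0, label=LABEL_NEAR)
    non = Pose("x", [[9.0, 0.0, 0.0]], asf_rank=1, lrmsd=9.0, label=LABEL_NON)
    return PosePool("T1-A", rec, np.array([1]), [near, non])


class TestDistanceArray:
    def test_single_contact_lands_in_its_bin(self):
        pool = _one_contact_pool()
        strata = RankStrata((0, 2))
        da = hp.build_distance_array(pool, (1, 1), strata=strata)
        rs = da.ranges
        k = int(rs.bin_of(3.1))
        assert rs.interval(k) == (3.0, 3.25)
        assert da.counts[0, k, NEAR_COL] == 1
        assert da.counts[0, :, NEAR_COL].sum() == 1
        assert da.counts[0, int(rs.bin_of(9.0)), NON_COL] == 1
        assert da.A[0] == 1 and da.B[0] == 1
        assert da.w[0] == pytest.approx(1 / 60)

    def test_absent_pair_is_all_zero(self):
        pool = _one_contact_pool()
        da = hp.build_distance_array(pool, (5, 9), strata=RankStrata((0, 2)))
        assert da.counts.sum() == 0
        assert da.A[0] == 0 and da.B[0] == 0 and da.w[0] == 0

    def test_matches_brute_force_double_loop(self, small_pool):
        ranges = hp.make_range_set()
        strata = RankStrata.scaled(len(small_pool))
        pair = (23, 1)
        da = hp.build_distance_array(small_pool, pair, ranges, strata)
        expected = np.zeros_like(da.counts)
        for pose in small_pool.poses:
            if pose.label == LABEL_NEAR:
                col = NEAR_COL
            elif pose.label == LABEL_NON:
                col = NON_COL
            else:
                continue
            s = int(strata.stratum_of([pose.asf_rank])[0])
            for bi, ti in zip(
                small_pool.receptor.coords, small_pool.receptor.type_indices
            ):
                if ti != pair[0]:
                    continue
                for bj, tj in zip(pose.coords, small_pool.fragment_types):
                    if tj != pair[1]:
                        continue
                    k = int(ranges.bin_of(float(np.linalg.norm(bi - bj))))
                    expected[s, k, col] += 1
        assert np.array_equal(da.counts, expected)


def _array_from_columns(near, non):
    n = len(near)
    edges = np.linspace(0, n - 1, n).tolist() + [math.inf]
    rs = RangeSet(tuple([0.0] + edges[1:]))
    counts = np.stack([near, non], axis=1)[None]
    return DistanceArray(
        pair=(1, 1), ranges=rs, strata=RankStrata((0, 1)), counts=counts
    )


class TestRefinement:
    def test_no_merge_when_all_rows_pass(self):
        da = _array_from_columns([1, 1, 1, 1, 56], [5, 5, 5, 5, 5])
        # A = 60, w = 1: every near count meets the threshold
        refined = refine_distance_array(da)
        assert len(refined.parts[0].counts) == 5
        assert np.array_equal(refined.parts[0].counts[:, NEAR_COL], [1, 1, 1, 1, 56])

    def test_hand_traced_merge(self):
        da = _array_from_columns([0, 2, 1, 1, 56], [1, 2, 3, 4, 5])
        refined = refine_distance_array(da)
        part = refined.parts[0]
        # row 0 (count 0 < w=1) merges into row 1
        assert np.array_equal(part.counts[:, NEAR_COL], [2, 1, 1, 56])
        assert np.array_equal(part.counts[:, NON_COL], [3, 3, 4, 5])
        assert len(part.counts) == 4

    def test_trailing_deficit_merges_backwards(self):
        da = _array_from_columns([59, 1, 0, 0, 0], [1, 1, 1, 1, 1])
        refined = refine_distance_array(da)
        part = refined.parts[0]
        # w = 1; tail rows never reach it and fold into the last passing row
        assert part.counts[-1, NEAR_COL] >= part.w or len(part.counts) == 1
        assert part.counts[:, NEAR_COL].sum() == 60
        assert part.counts[:, NON_COL].sum() == 5
        assert math.isinf(part.edges[-1])

    def test_zero_near_stratum_flagged_unusable(self):
        da = _array_from_columns([0, 0, 0], [1, 2, 3])
        refined = refine_distance_array(da)
        assert not refined.parts[0].usable
        assert not refined.usable

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_and_threshold(self, seed):
        rng = np.random.default_rng(seed)
        near = rng.integers(0, 30, 27)
        non = rng.integers(0, 500, 27)
        da = _array_from_columns(list(near), list(non))
        refined = refine_distance_array(da)
        part = refined.parts[0]
        if near.sum() == 0:
            assert not part.usable
            return
        assert part.counts[:, NEAR_COL].sum() == near.sum()
        assert part.counts[:, NON_COL].sum() == non.sum()
        # every refined near count except possibly the tail reaches w
        assert np.all(part.counts[:-1, NEAR_COL] >= part.w)
        # merged edges are a coarsening of the original edge set
        assert set(part.edges).issubset(set(da.ranges.edge_array))


class TestHistogram:
    def test_proportional_columns_are_zero(self):
        da = _array_from_columns([10, 20, 30], [100, 200, 300])
        hist = derive_histogram(refine_distance_array(da))
        assert np.allclose(hist.parts[0].values, 0.0)

    def test_single_row_value_is_ln2(self):
        # one refined row (2, 1) with A = 2, B = 1: ln2 - ln1 - (ln2 - ln1) = 0;
        # two rows with equal totals isolate the ln2 of a 2:1 row
        da = _array_from_columns([2, 2], [1, 3])
        hist = derive_histogram(refine_distance_array(da))
        v = hist.parts[0].values
        assert v[0] == pytest.approx(math.log(2) - math.log(1) - math.log(4 / 4))
        assert v[1] == pytest.approx(math.log(2) - math.log(3) - math.log(4 / 4))

    def test_doubling_non_native_counts_cancels(self):
        rng = np.random.default_rng(8)
        near = list(rng.integers(1, 40, 10))
        non = list(rng.integers(1, 200, 10))
        h1 = derive_histogram(refine_distance_array(_array_from_columns(near, non)))
        h2 = derive_histogram(
            refine_distance_array(_array_from_columns(near, [2 * x for x in non]))
        )
        assert np.allclose(h1.parts[0].values, h2.parts[0].values)

    def test_scaling_near_counts_cancels(self):
        rng = np.random.default_rng(9)
        near = list(rng.integers(1, 40, 10))
        non = list(rng.integers(1, 200, 10))
        h1 = derive_histogram(refine_distance_array(_array_from_columns(near, non)))
        h3 = derive_histogram(
            refine_distance_array(_array_from_columns([3 * x for x in near], non))
        )
        assert np.allclose(h1.parts[0].values, h3.parts[0].values)

    def test_matches_independent_arithmetic(self):
        rng = np.random.default_rng(10)
        near = list(rng.integers(0, 50, 27))
        non = list(rng.integers(0, 400, 27))
        da = _array_from_columns(near, non)
        refined = refine_distance_array(da)
        hist = derive_histogram(refined)
        part_r, part_h = refined.parts[0], hist.parts[0]
        A = float(sum(near))
        B = float(sum(non))
        for x in range(len(part_h.values)):
            d1 = float(part_r.counts[x, NEAR_COL])
            d2 = float(max(part_r.counts[x, NON_COL], 1))
            expected = math.log(d1) - math.log(d2) - (math.log(A) - math.log(B))
            assert abs(part_h.values[x] - expected) < 1e-12


class TestHistogramSet:
    def test_key_set_equals_observed_pairs(self, small_pool, small_hset):
        observed = {
            (int(i), int(j))
            for i in small_pool.receptor.type_indices
            for j in small_pool.fragment_types
        }
        assert set(small_hset.pairs()) <= observed
        # nearly every observed pair has near and non-native mass in some stratum
        assert len(small_hset) > 0.8 * len(observed)

    def test_identical_near_and_non_pose_gives_zero_histograms(self):
        rec = CGStructure.from_arrays(
            "protein", [1, 2], [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]
        )
        c = np.array([[3.0, 1.0, 0.0], [6.0, 2.0, 0.0]])
        poses = [
            Pose("n", c, asf_rank=0, lrmsd=1.0, label=LABEL_NEAR),
            Pose("x", c, asf_rank=1, lrmsd=9.0, label=LABEL_NON),
        ]
        pool = PosePool("T1-A", rec, np.array([1, 2]), poses)
        h = hp.derive_histogram_set(
            pool, strata=RankStrata((0, 2)), allow_small=True
        )
        for hist in h.histograms.values():
            for part in hist.parts:
                assert part is not None and np.allclose(part.values, 0.0)

    def test_sampling_problem_rejected(self, small_pool):
        with pytest.raises(PotentialError):
            hp.derive_histogram_set(small_pool, min_near=10_000)

    def test_json_roundtrip_lossless(self, tmp_path, small_hset):
        path = tmp_path / "h.json"
        small_hset.save(path)
        back = hp.HistogramSet.load(path)
        assert back.case_id == small_hset.case_id
        assert back.pairs() == small_hset.pairs()
        assert back.strata.bounds == small_hset.strata.bounds
        assert np.allclose(back.ranges.edge_array[:-1], small_hset.ranges.edge_array[:-1])
        for pair in small_hset.pairs():
            for p1, p2 in zip(back[pair].parts, small_hset[pair].parts):
                if p2 is None:
                    assert p1 is None
                    continue
                assert np.array_equal(p1.edges, p2.edges)
                assert np.array_equal(p1.values, p2.values)
                assert (p1.A, p1.B, p1.w) == (p2.A, p2.B, p2.w)

    def test_label_shuffle_null(self, small_pool, small_hset):
        """Shuffling labels destroys the signal: |H| collapses towards zero."""
        import dataclasses

        rng = np.random.default_rng(0)
        labels = small_pool.labels.copy()
        rng.shuffle(labels)
        shuffled = dataclasses.replace(
            small_pool,
            poses=[
                dataclasses.replace(p, label=str(lab), lrmsd=None)
                for p, lab in zip(small_pool.poses, labels)
            ],
        )
        h0 = hp.derive_histogram_set(shuffled)

        def mean_abs(h):
            vals = np.concatenate(
                [p.values for hist in h.histograms.values() for p in hist.parts if p is not None]
            )
            return float(np.abs(vals).mean())

        assert mean_abs(h0) < 0.5
        assert mean_abs(h0) < mean_abs(small_hset) / 2
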