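"""Region linking, chain optimality, fused-object splitting."""

from itertools import permutations, product

import numpy as np
import pytest

from cender.core import NeuronObject, Region2D
from cender.merging import (
    enforce_z_bound,
    evaluate_merging,
    group_by_frame,
    iou,
    link_volume,
    match_adjacent,
    split_all,
    split_fused,
)


def R(x, y, w=4, h=4, z=0, intensity=1.0):
    return Region2D(x, y, w, h, z, mean_intensity=intensity)


class TestIou:
    def test_identical(self):
        assert iou(R(0, 0), R(0, 0)) == 1.0

    def test_disjoint(self):
        assert iou(R(0, 0), R(10, 10)) == 0.0

    def test_pixel_counting_example(self):
        assert np.isclose(iou(R(0, 0, 4, 4), R(2, 2, 4, 4)), 4 / 28)

    def test_matches_pixel_set_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            x1, y1, x2, y2 = rng.integers(0, 12, 4)
            w1, h1, w2, h2 = rng.integers(1, 10, 4)
            a, b = R(x1, y1, w1, h1), R(x2, y2, w2, h2)
            grid = np.zeros((40, 40, 2), dtype=bool)
            grid[y1 : y1 + h1, x1 : x1 + w1, 0] = True
            grid[y2 : y2 + h2, x2 : x2 + w2, 1] = True
            inter = (grid[..., 0] & grid[..., 1]).sum()
            union = (grid[..., 0] | grid[..., 1]).sum()
            assert np.isclose(iou(a, b), inter / union)

    def test_symmetric(self):
        a, b = R(0, 0, 5, 3), R(2, 1, 4, 6)
        assert iou(a, b) == iou(b, a)


def brute_force_matching(w, tau=0.05):
    """Exhaustive maximum-total-weight one-to-one assignment with weights
    below tau zeroed."""
    w = np.where(w >= tau, w, 0.0)
    n, m = w.shape
    best = 0.0
    k = min(n, m)
    rows_sets = list(permutations(range(n), k))
    for rows in rows_sets:
        for cols in permutations(range(m), k):
            best = max(best, sum(w[i, j] for i, j in zip(rows, cols)))
    return best


class TestMatchAdjacent:
    def test_empty_frame_no_edges(self):
        assert match_adjacent([R(0, 0)], []) == []

    def test_single_pair(self):
        edges = match_adjacent([R(0, 0)], [R(2, 2, 4, 4, 1)])
        assert len(edges) == 1
        assert np.isclose(edges[0][2], 4 / 28)

    def test_below_tau_discarded(self):
        # IoU 1/31 < 0.05
        assert match_adjacent([R(0, 0)], [R(3, 3, 4, 4, 1)]) == []

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, m = rng.integers(1, 6, 2)
            a = [R(int(rng.integers(0, 10)), int(rng.integers(0, 10)), 6, 6, 0)
                 for _ in range(n)]
            b = [R(int(rng.integers(0, 10)), int(rng.integers(0, 10)), 6, 6, 1)
                 for _ in range(m)]
            edges = match_adjacent(a, b)
            total = sum(w for _i, _j, w in edges)
            w = np.array([[iou(x, y) for y in b] for x in a])
            assert np.isclose(total, brute_force_matching(w), atol=1e-12)
            # one-to-one: no shared vertices
            assert len({i for i, _j, _w in edges}) == len(edges)
            assert len({j for _i, j, _w in edges}) == len(edges)


class TestLinkVolume:
    def test_disjoint_regions_all_singletons(self):
        frames = [[R(0, 0, 4, 4, 0)], [R(20, 20, 4, 4, 1)], [R(40, 0, 4, 4, 2)]]
        objs = link_volume(frames)
        assert len(objs) == 3
        assert all(len(o.regions) == 1 for o in objs)

    def test_stacked_boxes_single_object(self):
        frames = [[R(5, 5, 6, 6, z)] for z in range(4)]
        objs = link_volume(frames)
        assert len(objs) == 1
        assert objs[0].zs == [0, 1, 2, 3]

    def test_partition_covers_every_region_once(self):
        rng = np.random.default_rng(5)
        frames = [
            [R(int(rng.integers(0, 30)), int(rng.integers(0, 30)), 6, 6, z)
             for _ in range(rng.integers(0, 5))]
            for z in range(5)
        ]
        objs = link_volume(frames)
        flat_in = [id(r) for fr in frames for r in fr]
        flat_out = [id(r) for o in objs for r in o.regions]
        assert sorted(flat_in) == sorted(flat_out)

    def test_synthetic_ground_truth_relinks_accurately(self, dataset):
        """The full merging stage (link + split) applied to the generator's
        own region lists recovers the generated objects at high F1 — the
        annotated-regions merging experiment."""
        for vol, gt in dataset[:3]:
            frames = group_by_frame(gt.regions, vol.red.shape[0])
            objs = split_all(link_volume(frames), max_len=4)
            _p, _r, f1 = evaluate_merging(objs, gt.objects)
            assert f1 >= 0.9

    def test_equals_chain_brute_force(self):
        """Total linked IoU equals the exhaustive optimum over all chain
        matchings of 3 frames (the objective separates per adjacent pair)."""
        rng = np.random.default_rng(2)

        def rand_frame(z, n):
            return [
                R(int(rng.integers(0, 12)), int(rng.integers(0, 12)), 6, 6, z)
                for _ in range(n)
            ]

        for _ in range(100):
            frames = [rand_frame(z, int(rng.integers(0, 5))) for z in range(3)]
            objs = link_volume(frames)
            total = 0.0
            for o in objs:
                for a, b in zip(o.regions, o.regions[1:]):
                    v = iou(a, b)
                    total += v if v >= 0.05 else 0.0

            def pair_best(fa, fb):
                if not fa or not fb:
                    return 0.0
                w = np.array([[iou(a, b) for b in fb] for a in fa])
                return brute_force_matching(w)

            expected = pair_best(frames[0], frames[1]) + pair_best(frames[1], frames[2])
            assert np.isclose(total, expected, atol=1e-12)


class TestSplit:
    def test_monotone_profile_unchanged(self):
        obj = NeuronObject(regions=[R(0, 0, 4, 4, z, intensity=i)
                                    for z, i in enumerate([3, 5, 8])])
        assert split_fused(obj) == [obj]

    def test_single_frame_unchanged(self):
        obj = NeuronObject(regions=[R(0, 0, 4, 4, 0, intensity=5)])
        assert split_fused(obj) == [obj]

    def test_splits_at_interior_minimum(self):
        obj = NeuronObject(regions=[R(0, 0, 4, 4, z, intensity=i)
                                    for z, i in enumerate([5, 9, 4, 8, 6])])
        parts = split_fused(obj)
        assert len(parts) == 2
        assert parts[0].zs == [0, 1]  # minimum frame joins the later object
        assert parts[1].zs == [2, 3, 4]

    def test_multiple_minima_recursive(self):
        prof = [9, 3, 8, 2, 7]
        obj = NeuronObject(regions=[R(0, 0, 4, 4, z, intensity=i)
                                    for z, i in enumerate(prof)])
        parts = split_fused(obj)
        assert [p.zs for p in parts] == [[0], [1, 2], [3, 4]]

    def test_plateau_not_a_minimum(self):
        obj = NeuronObject(regions=[R(0, 0, 4, 4, z, intensity=i)
                                    for z, i in enumerate([9, 4, 4, 8])])
        assert len(split_fused(obj)) == 1

    def test_never_merges_and_conserves_regions(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            prof = rng.uniform(1, 10, rng.integers(1, 8))
            obj = NeuronObject(regions=[R(0, 0, 4, 4, z, intensity=i)
                                        for z, i in enumerate(prof)])
            parts = split_fused(obj)
            assert len(parts) >= 1
            combined = [r for p in parts for r in p.regions]
            assert sorted(id(r) for r in combined) == sorted(id(r) for r in obj.regions)

    def test_z_bound_resplits_at_weakest_link(self):
        regions = [R(0, 0, 6, 6, 0), R(1, 0, 6, 6, 1), R(4, 3, 6, 6, 2),
                   R(5, 3, 6, 6, 3), R(5, 4, 6, 6, 4)]
        obj = NeuronObject(regions=regions)
        parts = enforce_z_bound(obj, 4)
        assert [p.zs for p in parts] == [[0, 1], [2, 3, 4]]

    def test_z_bound_off_by_default(self):
        regions = [R(0, 0, 6, 6, z) for z in range(6)]
        assert len(split_all([NeuronObject(regions=regions)])) == 1


class TestEvaluateMerging:
    def test_perfect(self):
        gt = [NeuronObject(regions=[R(0, 0, 4, 4, z) for z in range(3)]),
              NeuronObject(regions=[R(10, 10, 4, 4, 1)])]
        assert evaluate_merging(gt, gt) == (1.0, 1.0, 1.0)

    def test_singletons_lose_recall(self):
        gt = [NeuronObject(regions=[R(0, 0, 4, 4, z) for z in range(3)])]
        pred = [NeuronObject(regions=[R(0, 0, 4, 4, z)]) for z in range(3)]
        _p, r, _f = evaluate_merging(pred, gt)
        assert r < 1.0

    def test_hand_built_counts(self):
        gt = [
            NeuronObject(regions=[R(0, 0, 4, 4, z) for z in range(3)]),
            NeuronObject(regions=[R(10, 10, 4, 4, z) for z in range(2)]),
            NeuronObject(regions=[R(20, 0, 4, 4, 2)]),
        ]
        pred = [
            NeuronObject(regions=[R(0, 0, 4, 4, z) for z in range(3)]),  # TP
            NeuronObject(regions=[R(30, 30, 4, 4, 0)]),  # FP
        ]
        p, r, f = evaluate_merging(pred, gt)
        assert (p, r) == (0.5, 1 / 3)
        assert np.isclose(f, 2 / (1 / p + 1 / r))

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            evaluate_merging([], [])
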