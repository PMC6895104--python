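"""Contraction forest: labelling, cycles, lineage, origins, ASC/ASTC."""

import numpy as np
import pandas as pd
import pytest

from ardic.tree import (
    asc_map,
    astc_table,
    build_forest,
    find_origins,
    label_regions,
    origin_lags,
    segment_cycles,
)

GX = np.arange(10) * 24.0 + 16
GY = np.arange(10) * 24.0 + 16
PX = 1.0
BLOCK = 576.0  # (24 px * 1 um/px)^2


def forest_from(masks, min_area=0.0, fps=5.0):
    return build_forest(masks, BLOCK, min_area, GX, GY, PX, fps)


def disk(centre, r, shape=(10, 10)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= r**2


class TestLabelRegions:
    def test_empty_mask(self):
        regs = label_regions(np.zeros((5, 5), bool), BLOCK, 0.0, GX, GY, PX)
        assert regs == []

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        regs = label_regions(mask, BLOCK, 0.0, GX, GY, PX)
        assert len(regs) == 1
        assert len(regs[0].cells) == 2

    def test_min_area_filter(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True  # 1 block
        mask[3:6, 3:6] = True  # 9 blocks
        regs = label_regions(mask, BLOCK, 5 * BLOCK, GX, GY, PX)
        assert len(regs) == 1
        assert len(regs[0].cells) == 9

    def test_matches_flood_fill_oracle(self, rng):
        """Component count equals a brute-force 8-connected flood fill."""
        mask = rng.uniform(size=(12, 12)) < 0.35

        def flood_count(m):
            seen = np.zeros_like(m, dtype=bool)
            count = 0
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    if m[i, j] and not seen[i, j]:
                        count += 1
                        stack = [(i, j)]
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            for da in (-1, 0, 1):
                                for db in (-1, 0, 1):
                                    na, nb = a + da, b + db
                                    if (0 <= na < m.shape[0]
                                            and 0 <= nb < m.shape[1]
                                            and m[na, nb]
                                            and not seen[na, nb]):
                                        seen[na, nb] = True
                                        stack.append((na, nb))
            return count

        gx = np.arange(12) * 24.0
        gy = np.arange(12) * 24.0
        regs = label_regions(mask, BLOCK, 0.0, gx, gy, PX)
        assert len(regs) == flood_count(mask)
        assert sum(len(r.cells) for r in regs) == mask.sum()


class TestSegmentCycles:
    def test_all_empty(self):
        assert segment_cycles([0, 0, 0, 0]) == []

    def test_three_pulses(self):
        assert segment_cycles([0, 1, 1, 0, 2, 0, 0, 1, 0]) == [
            (1, 2), (4, 4), (7, 7),
        ]

    def test_pulse_at_video_end_closed(self):
        assert segment_cycles([0, 0, 1, 1]) == [(2, 3)]


class TestBuildForest:
    def test_growing_region_forms_single_path(self):
        """Monotone growth over 5 frames: leaf at the first frame, depth 4."""
        masks = {t: disk((5, 5), 1 + t) for t in range(5)}
        forest = forest_from(masks)
        assert len(forest.roots) == 1
        root = forest.nodes[forest.roots[0]]
        assert root.frame_index == 4 and root.depth == 0
        leaves = forest.leaves
        assert len(leaves) == 1
        leaf = forest.nodes[leaves[0]]
        assert leaf.frame_index == 0 and leaf.depth == 4
        assert forest.max_depth == 4

    def test_merge_makes_two_leaves_one_root(self):
        m0 = disk((2, 2), 1) | disk((7, 7), 1)
        m1 = np.ones((10, 10), bool)
        forest = forest_from({0: m0, 1: m1})
        assert len(forest.roots) == 1
        assert len(forest.leaves) == 2
        for leaf in forest.leaves:
            assert forest.nodes[leaf].depth == 1

    def test_isolated_region_is_singleton(self):
        forest = forest_from({0: disk((4, 4), 2)})
        assert forest.singletons == forest.roots == forest.leaves
        assert forest.nodes[forest.roots[0]].depth == 0

    def test_depth_consistency_and_partition(self):
        masks = {t: disk((5, 5), 1 + t) | disk((1, 8), 1) for t in range(4)}
        forest = forest_from(masks)
        seen = set()
        for root in forest.roots:
            members = forest.tree_members(root)
            assert not (seen & set(members))
            seen |= set(members)
        assert seen == set(forest.nodes)
        for node in forest.nodes.values():
            if node.parent is not None:
                parent = forest.nodes[node.parent]
                assert node.depth == parent.depth + 1
                assert parent.frame_index > node.frame_index

    def test_frame_gap_tolerated_within_cycle(self):
        # region briefly drops out at frame 1 but the cycle stays open
        masks = {
            0: disk((5, 5), 1),
            1: disk((1, 1), 1),  # other region keeps the cycle alive
            2: disk((5, 5), 3) | disk((1, 1), 1),
        }
        forest = forest_from(masks)
        first = [n for n in forest.nodes.values()
                 if n.frame_index == 0][0]
        assert first.parent is not None
        assert forest.nodes[first.parent].frame_index == 2


class TestFindOrigins:
    def test_single_path_sole_origin(self):
        masks = {t: disk((5, 5), 1 + t) for t in range(5)}
        origins, singles = find_origins(forest_from(masks))
        assert len(origins) == 1 and singles == []
        assert origins[0].max_depth == 4

    def test_all_singletons_no_origins(self):
        masks = {0: disk((2, 2), 1), 2: disk((7, 7), 1)}
        origins, singles = find_origins(forest_from(masks))
        assert origins == []
        assert len(singles) == 2

    def test_staggered_onsets_ranked_by_lead(self):
        """Earlier onset gives a deeper lineage and a higher rank."""
        masks = {}
        for t in range(6):
            m = np.zeros((10, 10), bool)
            m |= disk((2, 2), 1 + 0.5 * t)  # onset frame 0
            if t >= 2:
                m |= disk((7, 7), 1 + 0.5 * (t - 2))  # onset frame 2
            masks[t] = m
        origins, _ = find_origins(forest_from(masks), consolidate=True)
        assert len(origins) == 2
        assert origins[0].max_depth > origins[1].max_depth
        assert origins[0].centroid_grid[0] < 5  # the early origin at (2, 2)


class TestAscMap:
    def test_single_path_peak_depth(self):
        masks = {t: disk((5, 5), 1 + t) for t in range(5)}
        forest = forest_from(masks)
        asc = asc_map(forest)
        assert asc.max() == 4
        assert asc[5, 5] == 4

    def test_empty_forest_zero_map(self):
        forest = forest_from({0: np.zeros((10, 10), bool)})
        assert not asc_map(forest).any()

    def test_disjoint_trees_superpose(self):
        ma = {t: disk((2, 2), 1 + 0.4 * t) for t in range(3)}
        mb = {t: disk((7, 7), 1 + 0.4 * t) for t in range(3)}
        both = {t: ma[t] | mb[t] for t in range(3)}
        asc_a = asc_map(forest_from(ma))
        asc_b = asc_map(forest_from(mb))
        asc_ab = asc_map(forest_from(both))
        assert np.array_equal(asc_ab, np.maximum(asc_a, asc_b))


class TestAstc:
    @staticmethod
    def _two_origin_masks(lag_frames=2, n_cycles=5, period=10, dur=4):
        masks = {}
        n = n_cycles * period
        for t in range(n):
            m = np.zeros((10, 10), bool)
            ta = t % period
            if ta < dur:
                m |= disk((2, 2), 1 + ta)
            tb = (t - lag_frames) % period
            if t >= lag_frames and tb < dur:
                m |= disk((7, 7), 1 + tb)
            masks[t] = m
        return masks

    def test_lag_recovered_within_quantisation(self):
        """A fixed 0.4 s onset lag at 5 FPS is measured within one frame."""
        forest = forest_from(self._two_origin_masks(lag_frames=2))
        onsets, lags = origin_lags(forest)
        assert len(lags) == 1
        assert lags.iloc[0]["mean_lag_s"] == pytest.approx(0.4, abs=0.2)

    def test_synchronised_origins_lag_below_frame_period(self):
        forest = forest_from(self._two_origin_masks(lag_frames=0))
        _, lags = origin_lags(forest)
        assert abs(lags.iloc[0]["mean_lag_s"]) <= 0.2

    def test_tables_round_trip_csv(self, tmp_path):
        forest = forest_from(self._two_origin_masks())
        nodes, edges = astc_table(forest)
        nodes.to_csv(tmp_path / "n.csv", index=False)
        edges.to_csv(tmp_path / "e.csv", index=False)
        nodes2 = pd.read_csv(tmp_path / "n.csv")
        edges2 = pd.read_csv(tmp_path / "e.csv")
        pd.testing.assert_frame_equal(nodes, nodes2, check_dtype=False)
        pd.testing.assert_frame_equal(edges, edges2, check_dtype=False)
        # every edge references known nodes, child earlier than parent
        ids = set(nodes["id"])
        for _, e in edges.iterrows():
            assert e["parent_id"] in ids and e["child_id"] in ids
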