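"""Decision-tree projectome construction: map-set priority, candidacy, labels."""

import numpy as np
import pytest

from lumbocord.activation_glm import StatMap
from lumbocord.cord_geometry import ThresholdSpec
from lumbocord.projectome import (
    Component,
    MapSetEntry,
    build_map_set,
    build_projectome,
    classify_pool,
    default_expected_ranges,
    evaluate_candidate,
    extract_components,
)


def statmap_from_mask(shape, voxels, level=2, corrected=False, z_threshold=2.3,
                      cluster_p=None, z_value=5.0):
    z = np.zeros(shape)
    active = np.zeros(shape, bool)
    for v in voxels:
        z[tuple(v)] = z_value
        active[tuple(v)] = True
    spec = ThresholdSpec(
        z_threshold=z_threshold,
        correction="cluster" if corrected else "none",
        cluster_p=cluster_p if corrected else None,
    )
    return StatMap(z=z, threshold_spec=spec, corrected=corrected,
                   analysis_level=level, active_mask=active)


def entry(shape, voxels, muscle="TA", **kw):
    return MapSetEntry(statmap=statmap_from_mask(shape, voxels, **kw), muscle=muscle)


class TestDefaultExpectedRanges:
    def test_all_six_muscles_with_ordered_ranges(self):
        from lumbocord.cord_geometry import LEVEL_NAMES

        table = default_expected_ranges()
        assert set(table) == {"TA", "Gas", "Qd", "Il", "BF", "GMax"}
        for rostral, caudal in table.values():
            assert LEVEL_NAMES.index(rostral) <= LEVEL_NAMES.index(caudal)
        assert table["TA"] == ("L4", "S1")
        assert table["Gas"] == ("L4", "S2")


class TestBuildMapSet:
    shape = (4, 4, 4)

    def test_third_level_before_second(self):
        e2c = entry(self.shape, [(0, 0, 0)], level=2, corrected=True, cluster_p=0.05)
        e2u = entry(self.shape, [(0, 0, 0)], level=2, corrected=False)
        e3c = entry(self.shape, [(0, 0, 0)], level=3, corrected=True, cluster_p=0.05)
        ordered = build_map_set([e2c, e2u, e3c])
        assert ordered[0] is e3c
        assert ordered[1] is e2c and ordered[2] is e2u

    def test_stricter_z_first(self):
        lo = entry(self.shape, [(0, 0, 0)], corrected=True, z_threshold=2.3, cluster_p=0.05)
        hi = entry(self.shape, [(0, 0, 0)], corrected=True, z_threshold=3.1, cluster_p=0.05)
        assert build_map_set([lo, hi])[0] is hi

    def test_stable_for_ties(self):
        a = entry(self.shape, [(0, 0, 0)])
        b = entry(self.shape, [(1, 1, 1)])
        assert build_map_set([a, b]) == [a, b]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_map_set([])


class TestExtractComponents:
    def test_single_voxel_cog(self, small_geometry, small_partition):
        lm = small_geometry.true_level_map()
        vox = np.argwhere(lm.maps["L4"])[0]
        sm = statmap_from_mask(small_geometry.grid_shape, [vox])
        comps = extract_components(sm, lm, small_partition)
        assert len(comps) == 1
        assert comps[0].center_of_gravity == tuple(vox.astype(float))
        assert comps[0].level_at_cog == "L4"

    def test_two_separated_blobs(self, small_geometry, small_partition):
        lm = small_geometry.true_level_map()
        a = np.argwhere(lm.maps["L2"])[0]
        b = np.argwhere(lm.maps["S1"])[-1]
        sm = statmap_from_mask(small_geometry.grid_shape, [a, b])
        comps = extract_components(sm, lm, small_partition)
        assert len(comps) == 2

    def test_l_shaped_blob_level_by_centroid(self, small_geometry, small_partition):
        # blob straddling the L4/L5 boundary with more voxels in L5:
        # the centroid falls on the L5 side
        lm = small_geometry.true_level_map()
        lo4, _ = small_geometry.true_level_bounds["L4"]
        x, y = 11, 11
        voxels = [(x, y, lo4), (x, y, lo4 - 1), (x, y, lo4 - 2), (x + 1, y, lo4 - 1)]
        sm = statmap_from_mask(small_geometry.grid_shape, voxels)
        comps = extract_components(sm, lm, small_partition)
        assert len(comps) == 1
        assert comps[0].level_at_cog == "L5"

    def test_unthresholded_map_rejected(self, small_geometry, small_partition):
        sm = StatMap(z=np.zeros(small_geometry.grid_shape))
        with pytest.raises(ValueError, match="threshold"):
            extract_components(sm, small_geometry.true_level_map(), small_partition)


def component(level="L4", tallies=None, size=5, cog=(0.0, 0.0, 0.0)):
    return Component(
        voxels=np.zeros((size, 3), int),
        size=size,
        center_of_gravity=cog,
        level_at_cog=level,
        tallies=tallies or {"left": 0, "right": size, "dorsal": 0, "ventral": size},
    )


class TestEvaluateCandidate:
    def test_in_range_kept(self):
        kept, reason = evaluate_candidate(component("L4"), "TA", default_expected_ranges())
        assert kept and reason is None

    def test_out_of_range_rejected_with_reason(self):
        kept, reason = evaluate_candidate(component("L1"), "TA", default_expected_ranges())
        assert not kept and "L1" in reason and "L4-S1" in reason

    def test_caudal_extreme_kept_for_gas(self):
        kept, _ = evaluate_candidate(component("S2"), "Gas", default_expected_ranges())
        assert kept

    def test_outside_levels_rejected(self):
        kept, reason = evaluate_candidate(component("outside"), "TA", default_expected_ranges())
        assert not kept and "outside" in reason

    def test_unknown_muscle_rejected(self):
        with pytest.raises(ValueError, match="Soleus"):
            evaluate_candidate(component("L4"), "Soleus", default_expected_ranges())


class TestClassifyPool:
    def test_all_ventral_is_motor(self):
        t = {"left": 0, "right": 5, "dorsal": 0, "ventral": 5}
        pool, side = classify_pool(component(tallies=t))
        assert pool == "motor" and side == "right"

    def test_all_dorsal_is_sensory(self):
        t = {"left": 5, "right": 0, "dorsal": 5, "ventral": 0}
        pool, side = classify_pool(component(tallies=t))
        assert pool == "sensory" and side == "left"

    def test_within_margin_is_mixed(self):
        # dv = 0.1 with margin 0.2 -> mixed
        t = {"left": 0, "right": 20, "dorsal": 11, "ventral": 9}
        pool, _ = classify_pool(component(tallies=t), margin=0.2)
        assert pool == "mixed"

    def test_lr_tie_goes_right(self):
        t = {"left": 5, "right": 5, "dorsal": 0, "ventral": 10}
        _, side = classify_pool(component(tallies=t))
        assert side == "right"


class TestBuildProjectome:
    def _planted_map_sets(self, geometry, level, third_corrected=True):
        from lumbocord.synthetic_data import quadrant_mask

        region = quadrant_mask(geometry, level, "right-ventral")
        voxels = np.argwhere(region)[:10]
        sm3 = statmap_from_mask(
            geometry.grid_shape, voxels, level=3,
            corrected=third_corrected, cluster_p=0.05 if third_corrected else None,
        )
        return {"TA": [MapSetEntry(statmap=sm3, muscle="TA")]}, voxels

    def test_planted_cluster_high_confidence(self, small_geometry, small_partition):
        map_sets, _ = self._planted_map_sets(small_geometry, "L4")
        entries = build_projectome(
            map_sets, small_geometry.true_level_map(), small_partition
        )
        e = entries[0]
        assert (e.muscle, e.assigned_level, e.side, e.confidence) == (
            "TA", "L4", "right", "high",
        )
        assert e.pool == "motor"

    def test_all_maps_empty_not_estimable(self, small_geometry, small_partition):
        sm = statmap_from_mask(small_geometry.grid_shape, [])
        entries = build_projectome(
            {"TA": [MapSetEntry(statmap=sm, muscle="TA")]},
            small_geometry.true_level_map(),
            small_partition,
        )
        assert not entries[0].estimable
        assert entries[0].assigned_level is None

    def test_fallback_to_second_level_standard_confidence(
        self, small_geometry, small_partition
    ):
        from lumbocord.synthetic_data import quadrant_mask

        empty3 = statmap_from_mask(
            small_geometry.grid_shape, [], level=3, corrected=True, cluster_p=0.05
        )
        voxels = np.argwhere(quadrant_mask(small_geometry, "L5", "right-dorsal"))[:8]
        sm2 = statmap_from_mask(small_geometry.grid_shape, voxels, level=2)
        entries = build_projectome(
            {"TA": [MapSetEntry(statmap=empty3, muscle="TA"),
                    MapSetEntry(statmap=sm2, muscle="TA")]},
            small_geometry.true_level_map(),
            small_partition,
        )
        e = entries[0]
        assert e.confidence == "standard"
        assert e.source_level == 2 and e.assigned_level == "L5"

    def test_priority_soundness(self, small_geometry, small_partition):
        # third-level corrected holds an L4 candidate; a second-level map
        # pointing at S1 must not influence the result
        from lumbocord.synthetic_data import quadrant_mask

        map_sets, _ = self._planted_map_sets(small_geometry, "L4")
        decoy_vox = np.argwhere(quadrant_mask(small_geometry, "S1", "left-dorsal"))[:20]
        sm2 = statmap_from_mask(small_geometry.grid_shape, decoy_vox, level=2)
        map_sets["TA"].append(MapSetEntry(statmap=sm2, muscle="TA"))
        entries = build_projectome(
            map_sets, small_geometry.true_level_map(), small_partition
        )
        assert entries[0].assigned_level == "L4" and entries[0].side == "right"

    def test_out_of_range_clusters_never_assigned(
        self, small_geometry, small_partition
    ):
        from lumbocord.synthetic_data import quadrant_mask

        decoy_vox = np.argwhere(quadrant_mask(small_geometry, "L1", "right-ventral"))[:15]
        sm = statmap_from_mask(small_geometry.grid_shape, decoy_vox, level=3,
                               corrected=True, cluster_p=0.05)
        entries = build_projectome(
            {"TA": [MapSetEntry(statmap=sm, muscle="TA")]},
            small_geometry.true_level_map(),
            small_partition,
        )
        assert not entries[0].estimable  # L1 is outside TA's L4-S1 range

    def test_largest_kept_component_wins(self, small_geometry, small_partition):
        from lumbocord.synthetic_data import quadrant_mask

        big = np.argwhere(quadrant_mask(small_geometry, "L4", "right-ventral"))[:12]
        small = np.argwhere(quadrant_mask(small_geometry, "S1", "left-dorsal"))[:3]
        sm = statmap_from_mask(
            small_geometry.grid_shape, np.vstack([big, small]), level=2
        )
        entries = build_projectome(
            {"TA": [MapSetEntry(statmap=sm, muscle="TA")]},
            small_geometry.true_level_map(),
            small_partition,
        )
        assert entries[0].assigned_level == "L4"
        assert entries[0].component_size == 12

    def test_confidence_is_pure_function_of_source(self, small_geometry, small_partition):
        for level, corrected, expected in [
            (3, True, "high"), (3, False, "standard"), (2, True, "standard"),
        ]:
            map_sets, _ = self._planted_map_sets(small_geometry, "L4")
            sm = map_sets["TA"][0].statmap
            sm.analysis_level = level
            sm.corrected = corrected
            entries = build_projectome(
                {"TA": [MapSetEntry(statmap=sm, muscle="TA")]},
                small_geometry.true_level_map(),
                small_partition,
            )
            assert entries[0].confidence == expected
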