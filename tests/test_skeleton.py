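"""Skeletonization, graph condensation, pruning, and morphometry."""

import networkx as nx
import numpy as np
import pytest

from glandmorph import skeleton as sk
from glandmorph import synthetic as syn
from glandmorph.evaluate import match_glands, recovery_table
from glandmorph.skeleton import (
    MorphometryRecord,
    branch_category_table,
    count_branch_points,
    gland_length,
    prune_spurs,
    skeleton_to_graph,
    skeletonize_3d,
)

from conftest import capsule_mask


class TestSkeletonize:
    def test_cylinder_thins_to_path(self):
        mask = capsule_mask((20, 20, 50), [((10, 10, 5), (10, 10, 45))], 4)
        skel = skeletonize_3d(mask)
        assert skel.sum() < mask.sum()
        assert (skel & ~mask).sum() == 0
        g = skeleton_to_graph(skel, (1, 1, 1))
        ends = [n for n in g.nodes if g.degree(n) == 1]
        assert len(ends) == 2
        assert count_branch_points(g) == 0

    def test_y_tube_has_one_branch_point(self):
        mask = capsule_mask(
            (30, 44, 44),
            [((15, 22, 4), (15, 22, 22)), ((15, 8, 38), (15, 22, 22)), ((15, 36, 38), (15, 22, 22))],
            3.5,
        )
        skel = skeletonize_3d(mask)
        g = prune_spurs(skeleton_to_graph(skel, (1, 1, 1)), 6.0)
        assert count_branch_points(g) == 1

    def test_solid_ball_has_no_branches(self):
        mask = capsule_mask((26, 26, 26), [((13, 13, 13), (13, 13, 13))], 9)
        skel = skeletonize_3d(mask)
        g = prune_spurs(skeleton_to_graph(skel, (1, 1, 1)), 6.0)
        assert count_branch_points(g) == 0

    def test_multi_component_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2, 2, 2] = True
        mask[7, 7, 7] = True
        with pytest.raises(ValueError, match="components"):
            skeletonize_3d(mask)

    def test_skeleton_single_component(self, noiseless_segmentation):
        from scipy import ndimage

        scene, truth, mask, glands = noiseless_segmentation
        for g in glands[:3]:
            box = g.bounding_box(pad=2, shape=mask.shape)
            skel = skeletonize_3d(g.mask(mask.shape)[box], scene.spec.voxel_size_um)
            _, n = ndimage.label(skel, structure=np.ones((3, 3, 3)))
            assert n == 1


class TestSkeletonGraph:
    def test_straight_line_length_weighted_by_anisotropy(self):
        skel = np.zeros((3, 12, 3), bool)
        skel[1, 1:11, 1] = True  # 10 voxels along y
        g = skeleton_to_graph(skel, (7.0, 1.52, 1.52))
        assert g.number_of_edges() == 1
        (_, _, d), = g.edges(data=True)
        assert d["length_um"] == pytest.approx(9 * 1.52)

    def test_perfect_y_graph_shape(self):
        skel = np.zeros((3, 21, 21), bool)
        skel[1, 10, 1:11] = True
        for i in range(1, 10):
            skel[1, 10 - i, 10 + i] = True
            skel[1, 10 + i, 10 + i] = True
        g = skeleton_to_graph(skel, (1, 1, 1))
        degs = sorted(dict(g.degree).values())
        assert degs == [1, 1, 1, 3]
        assert g.number_of_edges() == 3

    def test_random_tree_isomorphic_to_ground_truth(self):
        spec = syn.SceneSpec(
            volume_shape_voxels=(28, 512, 288),
            n_glands=2,
            branch_counts=[3, 5],
            gland_length_range_um=(100, 150),
            seed=21,
        )
        scene = syn.make_gland_scene(spec)
        truth = syn.rasterize_labels(scene)
        from glandmorph import segmentation as seg

        vol = syn.render_volume(scene, syn.ImagingParams.noiseless(), ["gland_marker"])
        mask = seg.fill_holes_3d(seg.binarize(vol.data.astype(float), "fixed:60"))
        glands = seg.separate_glands(mask, truth.labels == 1, spec.voxel_size_um)
        matched = match_glands(glands, truth.labels)
        for lab, (g, _) in matched.items():
            tree = scene.gland_trees[lab - 2]
            rec_box = g.bounding_box(pad=2, shape=mask.shape)
            skel = skeletonize_3d(g.mask(mask.shape)[rec_box], spec.voxel_size_um)
            graph = prune_spurs(skeleton_to_graph(skel, spec.voxel_size_um), 12.0)
            # condense the ground-truth polyline tree to its topology
            t = nx.Graph(tree.edges)
            changed = True
            while changed:
                changed = False
                for n in list(t.nodes):
                    if t.degree(n) == 2:
                        a, b = t.neighbors(n)
                        t.remove_node(n)
                        t.add_edge(a, b)
                        changed = True
            assert nx.is_isomorphic(nx.Graph(graph), t)


class TestPruning:
    def test_zero_threshold_is_identity(self):
        mask = capsule_mask((20, 20, 40), [((10, 10, 4), (10, 10, 36))], 3)
        g = skeleton_to_graph(skeletonize_3d(mask), (1, 1, 1))
        g2 = prune_spurs(g, 0.0)
        assert g2.number_of_edges() == g.number_of_edges()

    def test_short_arm_pruned_from_y(self):
        # Y with one 1-voxel arm: pruning at 5 gives a straight path
        skel = np.zeros((3, 9, 16), bool)
        skel[1, 4, 1:13] = True
        skel[1, 5, 13] = True
        skel[1, 3, 13] = True  # 1-long second arm tip
        g = skeleton_to_graph(skel, (1, 1, 1))
        pruned = prune_spurs(g, 5.0)
        assert count_branch_points(pruned) == 0

    def test_idempotent_at_fixpoint(self, noiseless_segmentation):
        scene, truth, mask, glands = noiseless_segmentation
        g0 = glands[0]
        box = g0.bounding_box(pad=2, shape=mask.shape)
        skel = skeletonize_3d(g0.mask(mask.shape)[box], scene.spec.voxel_size_um)
        g = skeleton_to_graph(skel, scene.spec.voxel_size_um)
        p1 = prune_spurs(g, 12.0)
        p2 = prune_spurs(p1, 12.0)
        assert p1.number_of_edges() == p2.number_of_edges()
        assert count_branch_points(p1) == count_branch_points(p2)

    def test_never_deletes_last_edge(self):
        skel = np.zeros((3, 3, 6), bool)
        skel[1, 1, 1:5] = True
        g = skeleton_to_graph(skel, (1, 1, 1))
        pruned = prune_spurs(g, 1e6)
        assert pruned.number_of_edges() == 1


class TestGlandLength:
    def test_three_four_five(self):
        g = nx.MultiGraph()
        g.add_node(0, coord_um=np.array([0.0, 0.0, 0.0]))
        g.add_node(1, coord_um=np.array([0.0, 30.0, 40.0]))
        g.add_edge(0, 1, path=[], length_um=55.0)
        chord, geo = gland_length(np.zeros(3), g)
        assert chord == pytest.approx(50.0)
        assert geo == pytest.approx(55.0)

    def test_furthest_tip_not_nearest(self):
        g = nx.MultiGraph()
        g.add_node(0, coord_um=np.array([0.0, 0.0, 0.0]))
        g.add_node(1, coord_um=np.array([0.0, 0.0, 10.0]))
        g.add_node(2, coord_um=np.array([0.0, 0.0, 60.0]))
        g.add_node(3, coord_um=np.array([0.0, 25.0, 10.0]))
        g.add_edge(0, 1, path=[], length_um=10.0)
        g.add_edge(1, 2, path=[], length_um=50.0)
        g.add_edge(1, 3, path=[], length_um=25.0)
        chord, _ = gland_length(np.zeros(3), g)
        assert chord == pytest.approx(60.0)

    def test_no_endpoints_returns_zero(self):
        g = nx.MultiGraph()
        g.add_node(0, coord_um=np.zeros(3))
        g.add_node(1, coord_um=np.ones(3))
        g.add_node(2, coord_um=2 * np.ones(3))
        for a, b in ((0, 1), (1, 2), (2, 0)):
            g.add_edge(a, b, path=[], length_um=1.0)
        g.add_edge(0, 1, path=[], length_um=1.0)  # all degrees >= 2
        chord, geo = gland_length(np.zeros(3), g)
        assert chord == 0.0 and geo == 0.0


class TestRecordsAndCategories:
    def test_category_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MorphometryRecord(
                gland_label=1,
                sample_id="s",
                length_um=10,
                geodesic_length_um=11,
                n_branch_points=5,
                branch_category="0",
            )

    @pytest.mark.parametrize(
        "n,cat", [(0, "0"), (1, "1-3"), (3, "1-3"), (4, ">3"), (9, ">3")]
    )
    def test_category_boundaries(self, n, cat):
        r = MorphometryRecord(
            gland_label=1, sample_id="s", length_um=1, geodesic_length_um=1, n_branch_points=n
        )
        assert r.branch_category == cat

    def test_category_table_percentages(self):
        recs = [
            MorphometryRecord(i, "s", 10, 10, k)
            for i, k in enumerate([0] * 9 + [1])
        ]
        tab = branch_category_table(recs)
        by = tab.set_index("branch_category")["percent"]
        assert by["0"] == pytest.approx(90.0)
        assert by["1-3"] == pytest.approx(10.0)
        assert by[">3"] == pytest.approx(0.0)
        assert tab["percent"].sum() == pytest.approx(100.0)

    def test_all_heavily_branched(self):
        recs = [MorphometryRecord(i, "s", 10, 10, 5) for i in range(4)]
        tab = branch_category_table(recs).set_index("branch_category")
        assert tab.loc[">3", "percent"] == 100.0

    def test_empty_group_rejected(self):
        import pandas as pd

        recs = [MorphometryRecord(1, "s1", 10, 10, 0)]
        groups = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "group": ["control", "mutant"]}
        )
        with pytest.raises(ValueError, match="no records"):
            branch_category_table(recs, groups)

    def test_recovery_on_shared_scene(self, noiseless_segmentation):
        scene, truth, mask, glands = noiseless_segmentation
        records = [
            sk.measure_gland(g, mask.shape, scene.spec.voxel_size_um) for g in glands
        ]
        df = recovery_table(scene, glands, records)
        assert df["matched"].all()
        assert (df["true_branch_points"] == df["measured_branch_points"]).all()
        err = (df["measured_length_um"] - df["true_length_um"]).abs()
        diag = 2 * np.linalg.norm(scene.spec.voxel_size_um)
        assert err.mean() <= diag
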