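"""Per-branch measurements, Raabe labelling and generation summaries."""

import numpy as np
import pandas as pd
import pytest

from airwaymorph.centerline import Branch, CenterlineNetwork, Node, build_network, skeletonize
from airwaymorph.morphometry import (
    airway_length,
    assign_labels,
    branch_angle,
    branch_vector,
    generation_averages,
    generation_counts,
    gravity_angle,
    gravity_vector,
    hydraulic_diameter,
)

from conftest import make_cylinder
from test_qc import _branch, bifurcating_tree, make_network


class TestVectorsAndLengths:
    def test_branch_vector_is_node_to_node(self):
        b = _branch(0, 0, 1, [0, 0, 0], [0, 0, 2])
        assert np.allclose(branch_vector(b), [0, 0, 2])

    def test_reversed_orientation_negates(self):
        b = _branch(0, 0, 1, [1, 2, 3], [4, 5, 6])
        r = _branch(1, 1, 0, [4, 5, 6], [1, 2, 3])
        assert np.allclose(branch_vector(b), -branch_vector(r))

    def test_length_is_vector_norm(self):
        b = _branch(0, 0, 1, [0, 0, 0], [0, 3, 4])
        assert airway_length(b) == pytest.approx(5.0)
        assert airway_length(b) == pytest.approx(np.linalg.norm(branch_vector(b)))

    def test_curved_branch_chord_below_arc(self):
        t = np.linspace(0, np.pi, 30)
        pts = np.column_stack([np.sin(t), t, np.zeros_like(t)])
        b = Branch(0, 0, 1, pts)
        assert airway_length(b) < b.arc_length


class TestAngles:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([0, 1, 0], [0, 2, 0], 0.0),
            ([0, 1, 0], [1, 0, 0], 90.0),
            ([0, 1, 0], [0, -1, 0], 180.0),
            ([1, 0, 0], [1, 1, 0], 45.0),
        ],
    )
    def test_branch_angle_closed_forms(self, u, v, expected):
        assert branch_angle(np.array(u, float), np.array(v, float)) == \
            pytest.approx(expected)

    def test_zero_vector_flagged_as_nan(self):
        assert np.isnan(branch_angle(np.zeros(3), np.array([1.0, 0, 0])))


class TestGravity:
    def test_hand_computed_construction(self):
        # trachea along +y, bronchi average along (0, 1, -1)/sqrt(2):
        # the Gram-Schmidt residual is exactly -z
        net = bifurcating_tree()
        g = gravity_vector(net)
        assert np.allclose(g, [0, 0, -1], atol=1e-12)

    def test_orthogonal_to_trachea_hence_90_degrees(self):
        net = bifurcating_tree()
        g = gravity_vector(net)
        t = branch_vector(net.branches[net.root_branch])
        assert abs(g @ t) < 1e-12
        assert gravity_angle(t, g) == pytest.approx(90.0)

    def test_parallel_and_antiparallel_branches(self):
        g = np.array([0.0, 0.0, -1.0])
        assert gravity_angle(np.array([0, 0, -2.0]), g) == pytest.approx(0.0)
        assert gravity_angle(np.array([0, 0, 2.0]), g) == pytest.approx(180.0)

    def test_covariant_under_rigid_rotation(self):
        from scipy.spatial.transform import Rotation
        net = bifurcating_tree()
        g = gravity_vector(net)
        angles = [gravity_angle(branch_vector(b), g) for b in net.branches.values()]
        rot = Rotation.from_euler("xyz", [31.0, -47.0, 112.0], degrees=True)
        rotated = net.copy()
        for b in rotated.branches.values():
            b.points = rot.apply(b.points)
        for n in rotated.nodes.values():
            n.position = rot.apply(n.position)
        g2 = gravity_vector(rotated)
        angles2 = [gravity_angle(branch_vector(b), g2) for b in rotated.branches.values()]
        assert np.allclose(angles, angles2, atol=1e-9)

    def test_degenerate_bronchi_parallel_to_trachea_rejected(self):
        nodes = [
            Node(0, np.array([0.0, 0.0, 0.0]), "root"),
            Node(1, np.array([0.0, 2.0, 0.0]), "bifurcation"),
            Node(2, np.array([1.0, 3.0, 0.0]), "terminal"),
            Node(3, np.array([-1.0, 3.0, 0.0]), "terminal"),
        ]
        branches = [
            _branch(0, 0, 1, nodes[0].position, nodes[1].position),
            _branch(1, 1, 2, nodes[1].position, nodes[2].position, parent=0),
            _branch(2, 1, 3, nodes[1].position, nodes[3].position, parent=0),
        ]
        net = make_network(nodes, branches)
        with pytest.raises(ValueError, match="degenerate"):
            gravity_vector(net)


class TestHydraulicDiameter:
    def test_circular_and_square_closed_forms(self):
        # Dh = 4A/P: 2r for a circle, s for a square
        r, s = 1.3, 0.8
        assert 4 * np.pi * r**2 / (2 * np.pi * r) == pytest.approx(2 * r)
        assert 4 * s**2 / (4 * s) == pytest.approx(s)

    def test_voxel_cylinder_recovered_within_5_percent(self, cylinder_mask):
        net = build_network(skeletonize(cylinder_mask), cylinder_mask.spacing,
                            mask=cylinder_mask)
        bid = max(net.branches, key=lambda k: net.branches[k].arc_length)
        dh, ok = hydraulic_diameter(bid, cylinder_mask, net)
        true = 20 * cylinder_mask.spacing / 1000.0
        assert ok
        assert abs(dh - true) / true < 0.05

    def test_square_duct_recovered_within_5_percent(self):
        from airwaymorph.volume import BinaryMask
        values = np.zeros((33, 33, 60), bool)
        values[6:27, 6:27, :] = True  # 21-voxel square duct along z
        mask = BinaryMask(values=values, spacing=10.0)
        net = build_network(skeletonize(mask), mask.spacing, mask=mask)
        bid = max(net.branches, key=lambda k: net.branches[k].arc_length)
        dh, ok = hydraulic_diameter(bid, mask, net)
        true = 21 * mask.spacing / 1000.0
        assert ok
        assert abs(dh - true) / true < 0.05

    def test_branch_outside_short_mask_is_invalid(self):
        # a stub far shorter than its diameter: every station is excluded
        cyl = make_cylinder(diameter_vox=20, length_vox=6)
        net = build_network(skeletonize(cyl), cyl.spacing, mask=cyl,
                            extend_terminals=False, refine_nodes=False)
        bid = next(iter(net.branches))
        dh, ok = hydraulic_diameter(bid, cyl, net)
        assert not ok and dh == 0.0


class TestLabels:
    def test_major_daughter_gets_11_minor_gets_12(self):
        net = bifurcating_tree()
        labels = assign_labels(net, {0: 1.2, 1: 1.0, 2: 0.8})
        assert labels[0] == "1" and labels[1] == "11" and labels[2] == "12"

    def test_swapping_diameters_swaps_labels(self):
        net = bifurcating_tree()
        labels = assign_labels(net, {0: 1.2, 1: 0.7, 2: 0.9})
        assert labels[2] == "11" and labels[1] == "12"

    def test_tie_breaks_on_subtree_size_deterministically(self):
        net = bifurcating_tree()
        # extend branch 1 with two children: bigger subtree wins the tie
        end = net.branches[1].points[-1]
        for i, (nid, off) in enumerate([(4, [0.5, 1, 0]), (5, [-0.5, 1, 0])]):
            net.nodes[nid] = Node(nid, end + np.array(off, float), "terminal")
            net.branches[3 + i] = _branch(3 + i, 2, nid, end, net.nodes[nid].position,
                                          parent=1, radius=0.2)
        labels = assign_labels(net, {0: 1.2, 1: 0.9, 2: 0.9, 3: 0.5, 4: 0.4})
        assert labels[1] == "11"  # three-branch subtree beats the leaf

    def test_complete_tree_labels_prefix_closed(self, small_tree, small_mask):
        net = build_network(skeletonize(small_mask), small_mask.spacing,
                            mask=small_mask, origin_um=small_mask.origin)
        diam = {b.id: b.mean_radius for b in net.branches.values()}
        labels = set(assign_labels(net, diam).values())
        assert len(labels) == len(net.branches)
        assert all(lab == "1" or lab[:-1] in labels for lab in labels)

    def test_non_bifurcating_network_rejected(self):
        from test_qc import trifurcating_network
        net = trifurcating_network()
        with pytest.raises(ValueError, match="bifurcating"):
            assign_labels(net, {i: 1.0 for i in net.branches})


class TestGenerationSummaries:
    def table(self):
        return pd.DataFrame({
            "label": ["1", "11", "12", "111", "112"],
            "length_mm": [3.0, 2.4, 2.0, 1.8, 1.5],
            "diameter_mm": [1.2, 1.0, 0.8, 0.0, 0.6],
            "diameter_valid": [True, True, True, False, True],
            "branch_angle_deg": [np.nan, 20.0, 30.0, 25.0, 35.0],
            "gravity_angle_deg": [90.0, 70.0, 60.0, 50.0, 40.0],
        })

    def test_counts_per_generation(self):
        counts = generation_counts(self.table())
        assert counts.to_dict() == {1: 1, 2: 2, 3: 2}

    def test_single_branch_counts(self):
        t = self.table().iloc[:1]
        assert generation_counts(t).to_dict() == {1: 1}

    def test_averages_match_hand_arithmetic(self):
        avg = generation_averages(self.table()).set_index("generation")
        assert avg.loc[2, "length_mm_mean"] == pytest.approx((2.4 + 2.0) / 2)
        assert avg.loc[2, "length_mm_sd"] == pytest.approx(np.std([2.4, 2.0], ddof=1))
        assert avg.loc[2, "length_mm_se"] == pytest.approx(
            np.std([2.4, 2.0], ddof=1) / np.sqrt(2))
        assert avg.loc[3, "branch_angle_deg_mean"] == pytest.approx(30.0)

    def test_invalid_diameter_uses_parent_value(self):
        avg = generation_averages(self.table()).set_index("generation")
        # label 111 is invalid: its parent 11 contributes 1.0 instead of 0.0
        assert avg.loc[3, "diameter_mm_mean"] == pytest.approx((1.0 + 0.6) / 2)

    def test_all_valid_is_plain_mean(self):
        t = self.table()
        t.loc[3, ["diameter_mm", "diameter_valid"]] = [0.7, True]
        avg = generation_averages(t).set_index("generation")
        assert avg.loc[3, "diameter_mm_mean"] == pytest.approx((0.7 + 0.6) / 2)
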