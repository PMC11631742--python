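import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarcogait.skeleton_processing import (
    DEFAULT_EDGES,
    DEFAULT_RAW32_TO_25,
    DegenerateFrameError,
    JointGraph,
    SELECTED25_JOINT_NAMES,
    SkeletonSequence,
    bone_vectors,
    joint_velocity,
    load_topology,
    multibranch_features,
    normalize_sequence,
    read_skeleton_csv,
    resample_sequence,
    save_topology,
    select_joints,
    trunk_distance,
    write_skeleton_csv,
)


def _raw32(rng, t=5):
    return SkeletonSequence(coords=rng.normal(size=(t, 32, 3)), joint_set="raw32")


def _sel25(coords, **kw):
    return SkeletonSequence(coords=coords, joint_set="selected25", **kw)


class TestSkeletonSequence:
    def test_joint_count_enforced(self, rng):
        with pytest.raises(ValueError, match="25 joints"):
            SkeletonSequence(coords=rng.normal(size=(4, 32, 3)), joint_set="selected25")

    def test_nonfinite_rejected(self):
        c = np.zeros((3, 32, 3))
        c[1, 5, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SkeletonSequence(coords=c, joint_set="raw32")


class TestSelectJoints:
    def test_output_has_25_joints(self, rng):
        out = select_joints(_raw32(rng))
        assert out.n_joints == 25
        assert out.joint_set == "selected25"

    def test_pure_projection(self, rng):
        seq = _raw32(rng)
        out = select_joints(seq)
        for sel_idx, raw_idx in enumerate(DEFAULT_RAW32_TO_25):
            np.testing.assert_array_equal(out.coords[:, sel_idx], seq.coords[:, raw_idx])

    def test_names_in_order(self):
        assert SELECTED25_JOINT_NAMES[0] == "sacrum"
        assert SELECTED25_JOINT_NAMES[1] == "spine_center"
        assert SELECTED25_JOINT_NAMES[2] == "neck"
        assert SELECTED25_JOINT_NAMES[3] == "head"
        assert SELECTED25_JOINT_NAMES[20] == "shoulder_center"
        assert SELECTED25_JOINT_NAMES[24] == "right_thumb"
        assert len(SELECTED25_JOINT_NAMES) == 25

    def test_wrong_joint_count_rejected(self, rng):
        seq = SkeletonSequence(coords=rng.normal(size=(4, 25, 3)), joint_set="selected25")
        with pytest.raises(ValueError, match="32"):
            select_joints(seq)

    def test_brute_force_index_scan(self, rng):
        # mark each raw joint with a unique constant; selection must retain
        # exactly the configured indices
        coords = np.zeros((3, 32, 3))
        coords[:, :, 0] = np.arange(32)
        out = select_joints(SkeletonSequence(coords=coords, joint_set="raw32"))
        retained = sorted(set(out.coords[0, :, 0].astype(int)))
        assert retained == sorted(DEFAULT_RAW32_TO_25)


class TestTrunkDistance:
    def test_unit_offset(self):
        frame = np.zeros((25, 3))
        frame[20] = [0, 1, 0]
        assert trunk_distance(frame) == pytest.approx(1.0)

    def test_hand_computed(self):
        frame = np.zeros((25, 3))
        frame[0] = [1, 2, 2]
        assert trunk_distance(frame) == pytest.approx(3.0)  # sqrt(1+4+4)

    def test_degenerate(self):
        frame = np.ones((25, 3))
        with pytest.raises(DegenerateFrameError):
            trunk_distance(frame)


class TestNormalizeSequence:
    def test_direct_division(self):
        coords = np.zeros((1, 25, 3))
        coords[0, 20] = [0, 2, 0]   # d = 2
        coords[0, 5] = [2, 4, 4]
        out, d = normalize_sequence(_sel25(coords))
        np.testing.assert_allclose(d, [2.0])
        np.testing.assert_allclose(out.coords[0, 5], [1, 2, 2])

    def test_trunk_distance_becomes_one(self, rng):
        coords = rng.normal(size=(8, 25, 3)) + 5.0
        out, _ = normalize_sequence(_sel25(coords))
        for t in range(8):
            assert trunk_distance(out.coords[t]) == pytest.approx(1.0, abs=1e-9)

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(4, 25, 3)) + 3.0
        a, _ = normalize_sequence(_sel25(coords))
        b, _ = normalize_sequence(_sel25(c * coords))
        np.testing.assert_allclose(a.coords, b.coords, rtol=1e-9, atol=1e-12)

    def test_idempotent(self, rng):
        coords = rng.normal(size=(6, 25, 3)) + 4.0
        once, _ = normalize_sequence(_sel25(coords))
        twice, _ = normalize_sequence(once)
        np.testing.assert_allclose(twice.coords, once.coords, rtol=1e-9)

    def test_degenerate_frames_listed(self, rng):
        coords = rng.normal(size=(5, 25, 3)) + 4.0
        coords[2] = 1.0  # joint0 == joint20
        with pytest.raises(DegenerateFrameError) as exc:
            normalize_sequence(_sel25(coords))
        assert exc.value.frame_indices == [2]

    def test_drop_degenerate_flag(self, rng):
        coords = rng.normal(size=(5, 25, 3)) + 4.0
        coords[2] = 1.0
        out, d = normalize_sequence(_sel25(coords), drop_degenerate=True)
        assert out.n_frames == 4 and len(d) == 4


class TestJointVelocity:
    def test_static_sequence(self):
        coords = np.tile(np.arange(75.0).reshape(1, 25, 3), (6, 1, 1))
        vel = joint_velocity(_sel25(coords))
        np.testing.assert_array_equal(vel, 0.0)

    def test_constant_slope(self):
        t = np.arange(10.0)[:, None, None]
        coords = np.broadcast_to(t * 0.5, (10, 25, 3)).copy()
        vel = joint_velocity(_sel25(coords))
        np.testing.assert_allclose(vel[0], 0.0)
        np.testing.assert_allclose(vel[1:], 0.5)

    def test_telescoping(self, rng):
        coords = rng.normal(size=(9, 25, 3))
        vel = joint_velocity(_sel25(coords))
        np.testing.assert_allclose(vel[1:].sum(axis=0), coords[-1] - coords[0],
                                   atol=1e-12)

    def test_too_short(self, rng):
        with pytest.raises(ValueError, match="2 frames"):
            joint_velocity(_sel25(rng.normal(size=(1, 25, 3))))


class TestBoneVectors:
    def test_normalized_trunk_chain(self, rng):
        # a graph with a direct sacrum -> shoulder-center edge: after
        # normalization that bone has length exactly 1
        # valid tree: replace edges (0,1) and (1,20) with (0,20) and (20,1)
        edges = tuple(e for e in DEFAULT_EDGES if e not in ((0, 1), (1, 20)))
        graph = JointGraph(edges=((0, 20), (20, 1)) + edges)
        coords = rng.normal(size=(4, 25, 3)) + 3.0
        seq, _ = normalize_sequence(_sel25(coords))
        bones = bone_vectors(seq, graph)
        np.testing.assert_allclose(np.linalg.norm(bones[:, 0, :], axis=1), 1.0,
                                   atol=1e-9)

    def test_translation_invariance(self, rng):
        coords = rng.normal(size=(4, 25, 3))
        shifted = coords + np.array([10.0, -3.0, 2.5])
        b1 = bone_vectors(_sel25(coords))
        b2 = bone_vectors(_sel25(shifted))
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_antisymmetry(self, rng):
        coords = rng.normal(size=(3, 25, 3))
        g_fwd = JointGraph()
        swapped = tuple((b, a) for a, b in DEFAULT_EDGES)
        g_rev = JointGraph(edges=swapped)
        np.testing.assert_allclose(bone_vectors(_sel25(coords), g_fwd),
                                   -bone_vectors(_sel25(coords), g_rev))

    def test_missing_joint_error(self, rng):
        seq = SkeletonSequence(coords=rng.normal(size=(3, 5, 3)), joint_set="other")
        with pytest.raises(ValueError, match="beyond"):
            bone_vectors(seq, JointGraph())


class TestResample:
    def test_identity(self, rng):
        seq = _sel25(rng.normal(size=(7, 25, 3)))
        out = resample_sequence(seq, 7)
        np.testing.assert_array_equal(out.coords, seq.coords)

    def test_constant(self):
        seq = _sel25(np.full((5, 25, 3), 3.3))
        out = resample_sequence(seq, 11)
        assert out.n_frames == 11
        np.testing.assert_allclose(out.coords, 3.3)

    def test_linear_exact(self):
        t = np.arange(6.0)
        coords = np.einsum("t,jc->tjc", t, np.ones((25, 3)))
        out = resample_sequence(_sel25(coords), 16)
        expected_t = np.linspace(0, 5, 16)
        np.testing.assert_allclose(out.coords[:, 0, 0], expected_t, atol=1e-12)
        # endpoints preserved
        np.testing.assert_allclose(out.coords[0], coords[0])
        np.testing.assert_allclose(out.coords[-1], coords[-1])

    def test_target_too_small(self, rng):
        with pytest.raises(ValueError):
            resample_sequence(_sel25(rng.normal(size=(5, 25, 3))), 1)


class TestJointGraph:
    def test_default_is_spanning_tree(self):
        g = JointGraph()
        assert g.node_count == 25
        assert len(g.edges) == 24

    def test_non_tree_rejected(self):
        with pytest.raises(ValueError, match="spanning tree"):
            JointGraph(node_names=("a", "b", "c"), edges=((0, 1),))

    def test_hop_distance(self, toy_graph):
        np.testing.assert_array_equal(toy_graph.hop_distance_to_root(), [0, 1, 2])


class TestMultibranchFeatures:
    def test_shape_and_order(self, rng):
        seq = _sel25(rng.normal(size=(6, 25, 3)))
        f = multibranch_features(seq)
        assert f.shape == (9, 6, 25)
        np.testing.assert_allclose(f[:3], np.transpose(seq.coords, (2, 0, 1)))

    def test_bone_assigned_to_child_root_zero(self, rng):
        seq = _sel25(rng.normal(size=(4, 25, 3)))
        f = multibranch_features(seq, branches=("bone",))
        np.testing.assert_array_equal(f[:, :, 0], 0.0)  # root keeps zero vector
        expected = seq.coords[:, 1] - seq.coords[:, 0]  # edge (0, 1) -> child 1
        np.testing.assert_allclose(f[:, :, 1].T, expected)

    def test_unknown_branch(self, rng):
        with pytest.raises(ValueError, match="branch"):
            multibranch_features(_sel25(rng.normal(size=(4, 25, 3))), branches=("x",))


class TestFileInterfaces:
    def test_csv_round_trip_6dp(self, tmp_path, rng):
        seq = SkeletonSequence(coords=rng.normal(size=(5, 32, 3)), fps=30.0,
                               joint_set="raw32", participant_id="p1",
                               sequence_id="s1")
        path = tmp_path / "seq.csv"
        write_skeleton_csv(seq, path)
        back = read_skeleton_csv(path)
        np.testing.assert_allclose(back.coords, seq.coords, atol=5e-7)
        assert back.participant_id == "p1"
        assert back.joint_set == "raw32"
        assert back.fps == 30.0

    def test_topology_round_trip(self, tmp_path):
        path = tmp_path / "topology.yaml"
        save_topology(path)
        graph, index_map = load_topology(path)
        assert graph.edges == DEFAULT_EDGES
        assert tuple(index_map) == DEFAULT_RAW32_TO_25
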