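import numpy as np
import pytest

from sarcogait.models import (
    CNNConfig,
    ResidualCNN,
    STGCN,
    STGCNConfig,
    build_adjacency,
    cnn_forward,
    stgcn_forward,
)
from sarcogait.models.checkpoint import load_checkpoint, save_checkpoint
from sarcogait.models.layers import log_softmax, softmax
from sarcogait.models.training import train_classifier
from sarcogait.skeleton_processing import JointGraph


class TestBuildAdjacency:
    def test_two_node_uniform_hand_normalized(self):
        g = JointGraph(node_names=("a", "b"), edges=((0, 1),))
        A = build_adjacency(g, "uniform")
        assert A.shape == (1, 2, 2)
        np.testing.assert_allclose(A[0], 0.5)  # A+I all-ones, degrees 2

    def test_uniform_row_sums_regular_graph(self):
        g = JointGraph(node_names=("a", "b"), edges=((0, 1),))
        A = build_adjacency(g, "uniform")
        np.testing.assert_allclose(A[0].sum(axis=1), 1.0)

    def test_sparsity_preserved(self):
        g = JointGraph()
        A = build_adjacency(g, "uniform")[0]
        mask = g.adjacency_matrix() + np.eye(25)
        assert (A[mask == 0] == 0).all()
        assert (A >= 0).all() and np.isfinite(A).all()

    def test_distance_strategy_subsets(self):
        g = JointGraph()
        A = build_adjacency(g, "distance")
        assert A.shape == (2, 25, 25)
        # subset 0 holds only self-loops
        assert (A[0][~np.eye(25, dtype=bool)] == 0).all()
        assert (np.diag(A[1]) == 0).all()

    def test_spatial_strategy_covers_all_links(self):
        g = JointGraph()
        A = build_adjacency(g, "spatial")
        assert A.shape == (3, 25, 25)
        support = (A.sum(axis=0) > 0)
        expected = (g.adjacency_matrix() + np.eye(25)) > 0
        np.testing.assert_array_equal(support, expected)

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="strategy"):
            build_adjacency(JointGraph(), "bogus")

    def test_disconnected_graph_rejected(self):
        class Fake:
            node_count = 4

            def adjacency_matrix(self):
                a = np.zeros((4, 4))
                a[0, 1] = a[1, 0] = 1.0
                return a

        with pytest.raises(ValueError, match="connected"):
            build_adjacency(Fake(), "uniform")


class TestSTGCNConfig:
    def test_requires_branch(self):
        with pytest.raises(ValueError, match="branch"):
            STGCNConfig(input_branches=())

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            STGCNConfig(temporal_kernel=4)

    def test_binary_only(self):
        with pytest.raises(ValueError, match="binary"):
            STGCNConfig(num_classes=3)


@pytest.fixture(scope="module")
def small_stgcn():
    A = build_adjacency(JointGraph(), "spatial")
    cfg = STGCNConfig(block_channels=(8, 8), temporal_kernel=3)
    return STGCN(cfg, A, seed=0)


class TestSTGCNForward:
    def test_rows_sum_to_one(self, small_stgcn, rng):
        x = rng.normal(size=(5, 9, 12, 25))
        p = stgcn_forward(x, small_stgcn)
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_batch_permutation_equivariance(self, small_stgcn, rng):
        x = rng.normal(size=(6, 9, 12, 25))
        perm = rng.permutation(6)
        p1 = small_stgcn.forward(x)
        p2 = small_stgcn.forward(x[perm])
        np.testing.assert_allclose(p2, p1[perm], atol=1e-12)

    def test_deterministic_forward(self, small_stgcn, rng):
        x = rng.normal(size=(3, 9, 12, 25))
        np.testing.assert_array_equal(small_stgcn.forward(x),
                                      small_stgcn.forward(x))

    def test_shape_errors_are_informative(self, small_stgcn, rng):
        with pytest.raises(ValueError, match="C=9"):
            small_stgcn.forward(rng.normal(size=(2, 6, 12, 25)))
        with pytest.raises(ValueError, match="V=25"):
            small_stgcn.forward(rng.normal(size=(2, 9, 12, 24)))
        with pytest.raises(ValueError, match="temporal kernel"):
            small_stgcn.forward(rng.normal(size=(2, 9, 2, 25)))

    def test_attention_weights_normalized(self, small_stgcn):
        w = small_stgcn.attention_weights()
        assert w.shape == (25,)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0)


class TestSTGCNMlpReductionOracle:
    """With identity adjacency, temporal kernel 1 and no normalization the
    network is a per-joint MLP; verify against explicit per-node loops."""

    def _build(self):
        cfg = STGCNConfig(input_branches=("position",), block_channels=(4, 4),
                          temporal_kernel=1, attention_enabled=False,
                          norm="none", partition_strategy="uniform")
        adjacency = np.eye(3)[None]  # single subset, no cross-node mixing
        return STGCN(cfg, adjacency, seed=3)

    def _brute_force(self, model, x):
        p = model.params
        n_, c_, t_, v_ = x.shape
        out = np.zeros((n_, 2))
        for n in range(n_):
            pooled = np.zeros(4)
            for t in range(t_):
                for v in range(v_):
                    h = x[n, :, t, v]
                    for blk in p["blocks"]:
                        z = h @ blk["spatial_w"][0] + blk["spatial_b"]
                        z = np.maximum(z, 0)
                        z = z @ blk["temporal_w"][:, :, 0, 0].T + blk["temporal_b"]
                        if "res_w" in blk:
                            res = h @ blk["res_w"][:, :, 0, 0].T
                        else:
                            res = h
                        h = np.maximum(z + res, 0)
                    pooled += h
            pooled /= t_ * v_
            logits = pooled @ p["fc"]["w"] + p["fc"]["b"]
            e = np.exp(logits - logits.max())
            out[n] = e / e.sum()
        return out

    def test_matches_brute_force(self, rng):
        model = self._build()
        x = rng.normal(size=(4, 3, 5, 3))
        np.testing.assert_allclose(model.forward(x), self._brute_force(model, x),
                                   atol=1e-10)


@pytest.fixture(scope="module")
def small_cnn():
    return ResidualCNN(CNNConfig(stage_channels=(4, 8, 8, 16)), seed=0)


class TestCNNForward:
    def test_rows_sum_to_one(self, small_cnn, rng):
        x = np.abs(rng.normal(size=(4, 1, 32, 32)))
        p = cnn_forward(x, small_cnn)
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_inputs_identical_outputs(self, small_cnn):
        x = np.zeros((2, 1, 32, 32))
        p = small_cnn.forward(x)
        np.testing.assert_array_equal(p[0], p[1])

    def test_channel_mismatch_rejected(self, small_cnn, rng):
        with pytest.raises(ValueError, match="channel"):
            small_cnn.forward(rng.normal(size=(2, 3, 32, 32)))

    def test_min_size_enforced(self, small_cnn, rng):
        with pytest.raises(ValueError, match="spatial size"):
            small_cnn.forward(rng.normal(size=(2, 1, 16, 16)))

    def test_skip_connections_change_outputs(self, rng):
        x = np.abs(rng.normal(size=(2, 1, 32, 32)))
        with_skips = ResidualCNN(CNNConfig(stage_channels=(4, 8, 8, 16)), seed=0)
        without = ResidualCNN(
            CNNConfig(stage_channels=(4, 8, 8, 16), skip_connections=False), seed=0)
        # identical initialization, different wiring
        assert not np.allclose(with_skips.forward(x), without.forward(x))

    def test_block_count_is_resnet18(self, small_cnn):
        assert len(small_cnn.params["stages"]) == 4
        assert all(len(s) == 2 for s in small_cnn.params["stages"])


class TestSoftmaxLayer:
    def test_log_softmax_stable(self):
        z = np.array([[1000.0, 1000.0]])
        np.testing.assert_allclose(softmax(z), [[0.5, 0.5]])

    def test_softmax_rows(self, rng):
        z = rng.normal(size=(7, 2)) * 10
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-12)


class TestTraining:
    def test_loss_decreases_tiny_model(self, rng):
        cfg = STGCNConfig(input_branches=("position",), block_channels=(4,),
                          temporal_kernel=3, norm="none")
        model = STGCN(cfg, np.eye(3)[None], seed=0)
        x = rng.normal(size=(8, 3, 6, 3))
        y = np.array([0, 1] * 4)
        hist = train_classifier(model, x, y, epochs=20, lr=0.05,
                                optimizer="adam", batch_size=8, seed=0)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_determinism_same_seed(self, rng):
        x = rng.normal(size=(8, 3, 6, 3))
        y = np.array([0, 1] * 4)
        outs = []
        for _ in range(2):
            cfg = STGCNConfig(input_branches=("position",), block_channels=(4,),
                              temporal_kernel=3, norm="none")
            model = STGCN(cfg, np.eye(3)[None], seed=1)
            train_classifier(model, x, y, epochs=5, lr=0.05, optimizer="adam",
                            batch_size=4, seed=2)
            outs.append(model.forward(x))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_nonfinite_loss_aborts(self, rng):
        cfg = STGCNConfig(input_branches=("position",), block_channels=(4,),
                          temporal_kernel=3, norm="none")
        model = STGCN(cfg, np.eye(3)[None], seed=0)
        x = rng.normal(size=(4, 3, 6, 3))
        x[0] = 1e300  # overflows to non-finite activations
        y = np.array([0, 1, 0, 1])
        with pytest.raises(FloatingPointError, match="non-finite"):
            with np.errstate(all="ignore"):
                train_classifier(model, x, y, epochs=5, lr=0.1, optimizer="sgd",
                                 batch_size=4, seed=0)

    def test_unknown_optimizer(self, small_stgcn, rng):
        with pytest.raises(ValueError, match="optimizer"):
            train_classifier(small_stgcn, rng.normal(size=(2, 9, 12, 25)),
                            np.array([0, 1]), epochs=1, optimizer="bogus")


class TestCheckpoint:
    def test_stgcn_round_trip(self, tmp_path, small_stgcn, rng):
        x = rng.normal(size=(2, 9, 12, 25))
        path = tmp_path / "model.npz"
        save_checkpoint(small_stgcn, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.forward(x), small_stgcn.forward(x),
                                   atol=1e-12)

    def test_cnn_round_trip(self, tmp_path, small_cnn, rng):
        x = np.abs(rng.normal(size=(2, 1, 32, 32)))
        path = tmp_path / "model.npz"
        save_checkpoint(small_cnn, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.forward(x), small_cnn.forward(x),
                                   atol=1e-12)
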