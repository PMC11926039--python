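"""Network building blocks: graph convolution, STGCN blocks, fusion, head,
loss, and the finite-difference gradient check."""

import numpy as np
import pytest

from cpraqa.model import (ITEM_NAMES, ModelConfig, MultiviewSTGCN, fuse_views,
                          mae_loss, small_model_config, spatial_graph_conv)
from cpraqa.nn import Adam
from cpraqa.skeleton import SkeletonGraph, normalized_adjacency

TINY = dict(channels=(4, 3, 3, 5, 5, 6), strides=(1, 1, 2, 1, 2),
            temporal_kernel=3, head_hidden=4)


@pytest.fixture(scope="module")
def graph2():
    return SkeletonGraph(("a", "b"), frozenset({(0, 1)}))


def tiny_model(graph, views=("1",), dtype="float64", seed=0, **kw):
    cfg = ModelConfig(views=views, dtype=dtype, **{**TINY, **kw})
    return MultiviewSTGCN(cfg, graph, seed=seed)


class TestSpatialGraphConv:
    def test_identity_adjacency_identity_weights_pass_through(self):
        x = np.random.default_rng(0).normal(size=(5, 3, 4))
        out = spatial_graph_conv(x, np.eye(3), np.eye(4))
        assert np.allclose(out, x)

    def test_two_nodes_equal_features_average_to_projection(self, graph2):
        ahat = normalized_adjacency(graph2)
        x = np.tile(np.array([1.0, -2.0, 0.5, 3.0]), (4, 2, 1))
        w = np.random.default_rng(1).normal(size=(4, 3))
        out = spatial_graph_conv(x, ahat, w)
        assert np.allclose(out, x @ w, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        g = SkeletonGraph(("a", "b", "c", "d"),
                          frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}))
        ahat = normalized_adjacency(g)
        x = rng.normal(size=(6, 4, 3))
        w = rng.normal(size=(3, 2))
        out = spatial_graph_conv(x, ahat, w)
        oracle = np.zeros((6, 4, 2))
        for t in range(6):
            for i in range(4):
                for j in range(4):
                    oracle[t, i] += ahat[i, j] * (x[t, j] @ w)
        assert np.max(np.abs(out - oracle)) < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spatial_graph_conv(np.zeros((2, 3, 4)), np.eye(3), np.zeros((5, 2)))


class TestBlocksAndEncoder:
    def test_temporal_stride_shape_contract(self, graph2):
        m = tiny_model(graph2)
        x = {"1": np.random.default_rng(0).normal(size=(2, 11, 2, 4))}
        # strides (1,1,2,1,2): 11 -> 11 -> 11 -> 6 -> 6 -> 3
        enc = m.encoders["1"]
        h = enc.inorm.forward(x["1"])
        for blk, t_expect in zip(enc.blocks, (11, 11, 6, 6, 3)):
            h = blk.forward(h)
            assert h.shape[1] == t_expect

    def test_encode_deterministic_and_joint_sensitive(self, graph2):
        m = tiny_model(graph2)
        x = np.random.default_rng(3).normal(size=(2, 12, 2, 4))
        f1 = m.encode_view("1", x)
        f2 = m.encode_view("1", x)
        assert np.array_equal(f1, f2)
        masked = x.copy()
        masked[:, :, 1, :] = 0.0
        assert not np.allclose(m.encode_view("1", masked), f1)

    def test_frame_repetition_invariance_with_unit_strides(self, graph2):
        m = tiny_model(graph2, strides=(1, 1, 1, 1, 1))
        x = np.random.default_rng(4).normal(size=(1, 10, 2, 4))
        rep = np.repeat(x, 2, axis=1)
        # temporal conv sees each frame twice: pooled averages agree when the
        # signal is piecewise constant at the kernel scale
        f1 = m.encode_view("1", np.repeat(x, 4, axis=1))
        f2 = m.encode_view("1", np.repeat(rep, 2, axis=1))
        assert np.allclose(f1, f2, atol=1e-9)

    def test_permutation_equivariance_of_loss(self):
        names = ("a", "b", "c")
        g1 = SkeletonGraph(names, frozenset({(0, 1), (1, 2)}))
        perm = [2, 0, 1]
        g2 = SkeletonGraph(tuple(names[p] for p in perm),
                           frozenset({(1, 2), (2, 0)}))  # same bones relabelled
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 3, 4))
        y = rng.uniform(0, 4, (2, 6))
        m1 = MultiviewSTGCN(ModelConfig(views=("1",), dtype="float64", **TINY), g1, seed=0)
        m2 = MultiviewSTGCN(ModelConfig(views=("1",), dtype="float64", **TINY), g2, seed=0)
        l1 = m1.loss_and_grad({"1": x}, y)
        l2 = m2.loss_and_grad({"1": x[:, :, perm, :]}, y)
        assert np.isclose(l1, l2, atol=1e-9)


class TestFusionAndHead:
    def test_single_view_passes_through(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(fuse_views({"1": v}, {"1": 0.7}), v)

    def test_equal_logits_identical_vectors_are_fixed_point(self):
        v = np.array([0.5, -1.0])
        out = fuse_views({"1": v, "4": v, "5": v}, {k: 0.3 for k in "145"})
        assert np.allclose(out, v)

    def test_softmax_saturation_picks_dominant_view(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        out = fuse_views({"1": a, "2": b}, {"1": 20.0, "2": -20.0})
        assert np.max(np.abs(out - a)) < 1e-6

    def test_no_views_rejected(self):
        with pytest.raises(ValueError):
            fuse_views({}, {})

    def test_zero_head_weights_output_equals_bias(self, graph2):
        m = tiny_model(graph2)
        m.head1.w.value[...] = 0; m.head1.b.value[...] = 0
        m.head2.w.value[...] = 0
        m.head2.b.value[...] = np.arange(6, dtype=float)
        x = {"1": np.random.default_rng(0).normal(size=(3, 8, 2, 4))}
        pred = m.forward(x)
        assert np.allclose(pred, np.arange(6))

    def test_inference_clamps_to_score_range(self, graph2):
        m = tiny_model(graph2)
        m.head1.w.value[...] = 0; m.head2.w.value[...] = 0
        m.head2.b.value[...] = [4.7, -0.3, 2.0, 0.0, 4.0, 1.0]
        pred = m.predict({"1": np.zeros((1, 8, 2, 4))})
        assert np.allclose(pred[0], [4.0, 0.0, 2.0, 0.0, 4.0, 1.0])

    def test_item_order_is_canonical(self):
        assert ITEM_NAMES == ("hand", "arm", "shoulder", "depth", "rate", "release")


class TestMAELoss:
    def test_exact_match_zero(self):
        y = np.arange(6, dtype=float)
        assert mae_loss(y, y) == 0.0

    def test_unit_error_per_item_sums_to_six(self):
        y = np.zeros(6)
        assert mae_loss(y + 1, y) == 6.0

    def test_hand_computed_example(self):
        pred = np.array([4, 4, 4, 4, 4, 4], dtype=float)
        y = np.array([2, 4, 4, 4, 3, 4], dtype=float)
        assert mae_loss(pred, y) == 3.0

    def test_batch_mean_and_length_mismatch(self):
        pred = np.array([[1.0] * 6, [2.0] * 6])
        y = np.zeros((2, 6))
        assert mae_loss(pred, y) == 9.0
        with pytest.raises(ValueError):
            mae_loss(np.zeros(5), np.zeros(6))


class TestGradientsAndTraining:
    def test_analytic_gradients_match_finite_differences(self, graph2):
        m = tiny_model(graph2, views=("1", "2"))
        rng = np.random.default_rng(1)
        xs = {v: rng.normal(size=(2, 8, 2, 4)) for v in ("1", "2")}
        y = rng.uniform(0, 4, (2, 6))
        m.loss_and_grad(xs, y)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for p in m.params():
            flat = p.value.reshape(-1)
            for s in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                orig = flat[s]
                flat[s] = orig + eps
                lp = mae_loss(m.forward(xs), y)
                flat[s] = orig - eps
                lm = mae_loss(m.forward(xs), y)
                flat[s] = orig
                fd = (lp - lm) / (2 * eps)
                an = p.grad.reshape(-1)[s]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd), abs(an))

    def test_overfits_single_sample_within_200_steps(self, graph17):
        from cpraqa.simulate import simulate_recording
        from cpraqa.train import prepare_features
        from conftest import clean_config, short_params
        rec, gt = simulate_recording(short_params(), clean_config(seed=40))
        feats = prepare_features(rec, graph17, ("1",), 64)
        y = np.array([[float(gt.item_totals[d]) for d in
                       ("hand", "arm", "shoulder", "depth", "rate", "release")]])
        m = MultiviewSTGCN(small_model_config(views=("1",)), graph17, seed=0)
        opt = Adam(m.params(), lr=0.01, weight_decay=0.0, lr_decay_tau=60.0)
        xs = {"1": feats["1"][None]}
        loss = np.inf
        for _ in range(200):
            opt.zero_grad()
            loss = m.loss_and_grad(xs, y)
            opt.step()
        assert loss < 0.1

    def test_checkpoint_roundtrip(self, graph2, tmp_path):
        m = tiny_model(graph2, dtype="float32")
        x = {"1": np.random.default_rng(0).normal(size=(2, 9, 2, 4)).astype(np.float32)}
        ref = m.predict(x)
        path = tmp_path / "model.ckpt"
        m.save(path)
        m2 = MultiviewSTGCN.load(path)
        assert np.allclose(m2.predict(x), ref, atol=1e-7)
        assert m2.config == m.config
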