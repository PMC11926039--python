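"""Folds, training loop, MAE evaluation, baseline and weighted kappa."""

import numpy as np
import pytest

from cpraqa.model import small_model_config
from cpraqa.skeleton import SkeletonGraph
from cpraqa.train import (TrainConfig, baseline_constant,
                          evaluate_mae, make_folds, train_model,
                          weighted_kappa)


class TestMakeFolds:
    def test_fifty_ids_five_equal_folds_cover_everything(self):
        ids = [f"r{i}" for i in range(50)]
        folds = make_folds(ids, k=5, seed=3)
        sizes = [len(f.test_ids) for f in folds]
        assert sizes == [10] * 5
        all_test = [i for f in folds for i in f.test_ids]
        assert sorted(all_test) == sorted(ids)
        for f in folds:
            assert not set(f.train_ids) & set(f.test_ids)
            assert sorted(f.train_ids + f.test_ids) == sorted(ids)

    def test_same_seed_reproduces_split(self):
        ids = list(range(23))
        assert make_folds(ids, seed=9) == make_folds(ids, seed=9)
        assert make_folds(ids, seed=9) != make_folds(ids, seed=10)

    def test_groups_never_straddle_folds(self):
        ids = [f"r{i}" for i in range(30)]
        groups = [f"p{i // 3}" for i in range(30)]  # 3 recordings per participant
        folds = make_folds(ids, k=5, seed=0, groups=groups)
        gmap = dict(zip(ids, groups))
        for f in folds:
            assert not {gmap[i] for i in f.train_ids} & {gmap[i] for i in f.test_ids}

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 2, 3], k=5)


def toy_dataset(n=12, T=20, seed=0):
    """Features whose mean level linearly encodes the labels."""
    rng = np.random.default_rng(seed)
    ds = []
    for _ in range(n):
        y = rng.integers(0, 5, size=6).astype(float)
        x = rng.normal(0, 0.1, (T, 2, 4)).astype(np.float32)
        x[..., 0] += y[0] / 4.0
        ds.append(({"1": x}, y))
    return ds


@pytest.fixture(scope="module")
def graph2():
    return SkeletonGraph(("left_hip", "right_hip"), frozenset({(0, 1)}))


TINY_MODEL = dict(channels=(4, 3, 3, 5, 5, 6), strides=(1, 1, 2, 1, 2),
                  temporal_kernel=3, head_hidden=4)


class TestTrainModel:
    def test_loss_decreases_on_learnable_data(self, graph2):
        cfg = TrainConfig(epochs=8, views=("1",), seed=0, batch_size=4)
        model, hist = train_model(toy_dataset(), graph2, cfg,
                                  small_model_config(views=("1",), **{}))
        assert hist[-1] < hist[0]

    def test_zero_learning_rate_leaves_parameters_and_history_flat(self, graph2):
        ds = toy_dataset()
        cfg = TrainConfig(learning_rate=0.0, weight_decay=0.0, epochs=3,
                          views=("1",), seed=0, batch_size=len(ds),
                          augment_noise_m=0.0)
        mc = small_model_config(views=("1",))
        model, hist = train_model(ds, graph2, cfg, mc)
        from cpraqa.model import MultiviewSTGCN
        fresh = MultiviewSTGCN(mc, graph2, seed=cfg.seed)
        med = np.median(np.stack([s[1] for s in ds]), axis=0)
        fresh.head2.b.value[...] = med.astype(np.float32)
        for p, q in zip(model.params(), fresh.params()):
            assert np.array_equal(p.value, q.value)
        # batch order varies per epoch; only float32 summation order differs
        assert np.ptp(hist) < 1e-6

    def test_same_seed_same_loss_curve(self, graph2):
        cfg = TrainConfig(epochs=3, views=("1",), seed=7)
        _, h1 = train_model(toy_dataset(), graph2, cfg,
                            small_model_config(views=("1",)))
        _, h2 = train_model(toy_dataset(), graph2, cfg,
                            small_model_config(views=("1",)))
        assert np.allclose(h1, h2, rtol=1e-5)

    def test_empty_dataset_rejected(self, graph2):
        with pytest.raises(ValueError):
            train_model([], graph2, TrainConfig(views=("1",)))


class TestEvaluateMAE:
    def test_perfect_predictions_all_zero(self):
        preds = {"a": np.full(6, 2.0), "b": np.full(6, 3.0)}
        rep = evaluate_mae(preds, preds)
        assert rep.total == 0.0
        assert all(v == 0.0 for v in rep.per_item.values())

    def test_constant_four_predictor_hand_computed(self):
        agreed = {"a": np.array([4, 4, 4, 4, 2, 4], float),
                  "b": np.array([0, 4, 4, 4, 4, 4], float)}
        preds = {k: np.full(6, 4.0) for k in agreed}
        rep = evaluate_mae(preds, agreed)
        assert [rep.per_item[k] for k in
                ("hand", "arm", "shoulder", "depth", "rate", "release")] == \
            [2.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        assert rep.total == 3.0

    def test_total_is_sum_of_items(self):
        rng = np.random.default_rng(0)
        preds = {i: rng.uniform(0, 4, 6) for i in range(9)}
        agreed = {i: rng.uniform(0, 4, 6) for i in range(9)}
        rep = evaluate_mae(preds, agreed)
        assert np.isclose(rep.total, sum(rep.per_item.values()))

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mae({"a": np.zeros(6)}, {"b": np.zeros(6)})


class TestBaselineConstant:
    def test_identical_labels_give_zero_mae(self):
        labels = [np.array([4, 0, 4, 2, 1, 3], float)] * 5
        med = baseline_constant(labels)
        assert np.allclose(med, labels[0])

    def test_invariant_to_duplication(self):
        labels = [np.arange(6, dtype=float), np.ones(6), np.full(6, 3.0)]
        assert np.allclose(baseline_constant(labels),
                           baseline_constant(labels * 3))

    def test_bimodal_zero_four_median_two(self):
        labels = [np.zeros(6)] * 3 + [np.full(6, 4.0)] * 3
        med = baseline_constant(labels)
        assert np.allclose(med, 2.0)
        mae = np.mean([np.abs(med - l) for l in labels], axis=0)
        assert np.allclose(mae, 2.0)


# two fixed 5x5 contingency tables; expected kappas frozen from an
# independent implementation (scikit-learn cohen_kappa_score)
T1 = np.array([[10, 2, 0, 0, 0],
               [3, 8, 2, 1, 0],
               [0, 2, 6, 2, 0],
               [0, 1, 2, 9, 1],
               [0, 0, 0, 2, 7]])
T2 = np.array([[1, 4, 2, 0, 3],
               [0, 2, 5, 1, 0],
               [2, 0, 1, 3, 1],
               [4, 1, 0, 2, 2],
               [1, 3, 2, 0, 4]])
FROZEN = {
    ("T1", "linear"): 0.7781178270849274,
    ("T1", "quadratic"): 0.8908235294117647,
    ("T2", "linear"): 0.04528301886792463,
    ("T2", "quadratic"): 0.043243243243243246,
}


def table_to_ratings(T):
    a, b = [], []
    for i in range(5):
        for j in range(5):
            a += [i] * T[i, j]
            b += [j] * T[i, j]
    return a, b


class TestWeightedKappa:
    def test_identical_ratings_kappa_one(self):
        r = ["Good", "Poor", "Excellent", "Borderline", "Good", "Unacceptable"]
        assert weighted_kappa(r, r) == pytest.approx(1.0)

    def test_reversed_balanced_two_category_design_is_minus_one(self):
        a = [0] * 10 + [1] * 10
        b = [1] * 10 + [0] * 10
        assert weighted_kappa(a, b, n_categories=2) == pytest.approx(-1.0)

    @pytest.mark.parametrize("name,T", [("T1", T1), ("T2", T2)])
    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    def test_matches_frozen_oracle_tables(self, name, T, weighting):
        a, b = table_to_ratings(T)
        got = weighted_kappa(a, b, weighting=weighting)
        assert got == pytest.approx(FROZEN[(name, weighting)], abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, 40)
        b = rng.integers(0, 5, 40)
        assert weighted_kappa(a, b) == pytest.approx(weighted_kappa(b, a))

    def test_cross_checked_against_sklearn_on_random_inputs(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        for trial in range(10):
            a = rng.integers(0, 5, 60)
            b = np.where(rng.random(60) < 0.6, a, rng.integers(0, 5, 60))
            for w in ("linear", "quadratic"):
                ref = sklearn.cohen_kappa_score(a, b, labels=[0, 1, 2, 3, 4],
                                                weights=w)
                assert weighted_kappa(a, b, weighting=w) == pytest.approx(ref, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([], [])
        with pytest.raises(ValueError):
            weighted_kappa([0, 1], [0])
        with pytest.raises(ValueError):
            weighted_kappa(["Superb"], ["Good"])
        with pytest.raises(ValueError):
            weighted_kappa([0, 7], [0, 1])
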