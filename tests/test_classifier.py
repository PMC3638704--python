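"""Training-set construction, network training and thresholding."""

import numpy as np
import pytest

from dcetex import (
    ClassifierConfig,
    NNModel,
    TrainingSet,
    build_training_and_verification_sets,
    predict_scores,
    threshold_scores,
    train_nn,
)


def _masks_and_features(rng, shape=(20, 20, 6), n_lesion=100):
    body = np.zeros(shape, bool)
    body[2:18, 2:18, 1:5] = True
    lesion = np.zeros(shape, bool)
    coords = np.argwhere(body)
    sel = coords[rng.choice(len(coords), n_lesion, replace=False)]
    lesion[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    valid = np.ones(shape, bool)
    features = rng.normal(size=shape + (12,))
    return lesion, body, valid, features


class TestSetConstruction:
    def test_even_split_counts(self, rng):
        lesion, body, valid, feats = _masks_and_features(rng, n_lesion=100)
        tr, ver = build_training_and_verification_sets(lesion, body, valid, feats, seed=0)
        assert len(tr) == 50 and len(ver) == 50
        assert tr.labels.sum() == 25 and ver.labels.sum() == 25

    @pytest.mark.parametrize("n_lesion", [99, 100, 101, 17])
    def test_balanced_disjoint_and_size_gap_at_most_one(self, rng, n_lesion):
        lesion, body, valid, feats = _masks_and_features(rng, n_lesion=n_lesion)
        tr, ver = build_training_and_verification_sets(lesion, body, valid, feats, seed=3)
        assert abs(len(tr) - len(ver)) <= 1
        for s in (tr, ver):
            assert abs(2 * s.labels.sum() - len(s)) <= 1
        tr_set = {tuple(c) for c in tr.coords}
        ver_set = {tuple(c) for c in ver.coords}
        assert not tr_set & ver_set
        assert len(tr_set) == len(tr) and len(ver_set) == len(ver)

    def test_coords_inside_masks(self, rng):
        lesion, body, valid, feats = _masks_and_features(rng)
        valid[:, :, 0] = False
        tr, ver = build_training_and_verification_sets(lesion, body, valid, feats, seed=1)
        for s in (tr, ver):
            assert np.all(body[s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]])
            assert np.all(valid[s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]])

    def test_deterministic_per_seed(self, rng):
        lesion, body, valid, feats = _masks_and_features(rng)
        a = build_training_and_verification_sets(lesion, body, valid, feats, seed=5)
        b = build_training_and_verification_sets(lesion, body, valid, feats, seed=5)
        c = build_training_and_verification_sets(lesion, body, valid, feats, seed=6)
        assert np.array_equal(a[0].coords, b[0].coords)
        assert not np.array_equal(a[0].coords, c[0].coords)

    def test_benign_voxels_enter_negatives(self, rng):
        lesion, body, valid, feats = _masks_and_features(rng, n_lesion=60)
        benign = np.zeros(lesion.shape, bool)
        benign[3:6, 3:6, 2] = True  # 9 voxels, disjoint from most lesions
        benign &= ~lesion
        tr, ver = build_training_and_verification_sets(
            lesion, body, valid, feats, seed=2, benign_mask=benign
        )
        all_neg = np.concatenate(
            [tr.coords[tr.labels == 0], ver.coords[ver.labels == 0]]
        )
        n_benign_sampled = sum(bool(benign[tuple(c)]) for c in all_neg)
        assert n_benign_sampled == (benign.sum() + 1) // 2
        for s in (tr, ver):
            assert abs(2 * s.labels.sum() - len(s)) <= 1

    def test_empty_lesion_mask_raises(self, rng):
        _, body, valid, feats = _masks_and_features(rng)
        with pytest.raises(ValueError):
            build_training_and_verification_sets(
                np.zeros(body.shape, bool), body, valid, feats, seed=0
            )

    def test_insufficient_body_voxels_raises(self, rng):
        lesion, body, valid, feats = _masks_and_features(rng, n_lesion=100)
        with pytest.raises(ValueError):
            build_training_and_verification_sets(lesion, lesion, valid, feats, seed=0)


def _gaussian_sets(rng, n=200, sep=3.0, dim=10, shuffle=False):
    """Two well-separated Gaussian clouds, split into balanced train/verify."""
    half, quarter = n // 2, n // 4
    X0 = rng.normal(-sep / 2, 1, (half, dim))
    X1 = rng.normal(sep / 2, 1, (half, dim))

    def mk(X0p, X1p):
        X = np.concatenate([X0p, X1p])
        y = np.concatenate([np.zeros(len(X0p)), np.ones(len(X1p))])
        if shuffle:
            y = rng.permutation(y)
        perm = rng.permutation(len(y))
        return TrainingSet(np.zeros((len(y), 3), int), X[perm], y[perm], 0)

    return mk(X0[:quarter], X1[:quarter]), mk(X0[quarter:], X1[quarter:])


class TestTraining:
    def test_separable_data_learned(self, rng):
        tr, ver = _gaussian_sets(rng)
        model = train_nn(tr, ver, ClassifierConfig(seed=0, max_epochs=800))
        assert model.history["train_mse"][-1] < 0.05
        acc = np.mean((model.forward(ver.features) >= 0.5) == (ver.labels == 1))
        assert acc == 1.0

    def test_shuffled_labels_unlearnable(self, rng):
        tr, ver = _gaussian_sets(rng, shuffle=True)
        model = train_nn(tr, ver, ClassifierConfig(seed=0, max_epochs=800))
        assert min(model.history["verify_mse"]) >= 0.2

    def test_deterministic_per_seed(self, rng):
        tr, ver = _gaussian_sets(rng)
        m1 = train_nn(tr, ver, ClassifierConfig(seed=4))
        m2 = train_nn(tr, ver, ClassifierConfig(seed=4))
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)

    def test_early_stopping_restores_best_weights(self, rng):
        tr, ver = _gaussian_sets(rng)
        model = train_nn(tr, ver, ClassifierConfig(seed=0, max_epochs=600, patience=30))
        best = min(model.history["verify_mse"])
        # recomputing the verification MSE with the returned weights gives the best epoch
        pred = np.tanh(
            ((ver.features[:, model.kept_features] - model.mean[model.kept_features])
             / model.sd[model.kept_features]) @ model.W1 + model.b1
        ) @ model.W2 + model.b2
        mse = np.mean((pred[:, 0] - ver.labels) ** 2)
        assert mse == pytest.approx(best, rel=1e-9)

    def test_zero_variance_feature_dropped(self, rng):
        tr, ver = _gaussian_sets(rng)
        tr.features[:, 3] = 1.0
        model = train_nn(tr, ver, ClassifierConfig(seed=0, max_epochs=50))
        assert 3 in model.dropped_features

    def test_nan_feature_named(self, rng):
        tr, ver = _gaussian_sets(rng)
        tr.features[5, 2] = np.nan
        with pytest.raises(ValueError, match="f2"):
            train_nn(tr, ver, feature_names=[f"f{i}" for i in range(10)])

    def test_model_json_roundtrip(self, rng):
        tr, ver = _gaussian_sets(rng)
        model = train_nn(tr, ver, ClassifierConfig(seed=0, max_epochs=50))
        clone = NNModel.from_json(model.to_json())
        x = rng.normal(size=(20, 10))
        assert np.allclose(model.forward(x), clone.forward(x))


class TestPredictAndThreshold:
    def test_zero_weight_forward_pass_closed_form(self):
        model = NNModel(
            W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 1)), b2=np.array([0.5]),
            mean=np.zeros(4), sd=np.ones(4),
            kept_features=np.arange(4), dropped_features=np.array([], int),
        )
        scores = model.forward(np.random.default_rng(0).normal(size=(10, 4)))
        assert np.all(scores == 0.5)

    def test_scores_clipped_to_unit_interval(self, rng):
        model = NNModel(
            W1=rng.normal(size=(4, 3)) * 10, b1=rng.normal(size=3),
            W2=rng.normal(size=(3, 1)) * 10, b2=np.array([0.0]),
            mean=np.zeros(4), sd=np.ones(4),
            kept_features=np.arange(4), dropped_features=np.array([], int),
        )
        scores = model.forward(rng.normal(size=(10000, 4)))
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_masked_voxels_score_zero(self, rng):
        model = NNModel(
            W1=np.zeros((2, 2)), b1=np.zeros(2), W2=np.zeros((2, 1)), b2=np.array([0.9]),
            mean=np.zeros(2), sd=np.ones(2),
            kept_features=np.arange(2), dropped_features=np.array([], int),
        )
        body = np.zeros((4, 4, 2), bool)
        body[1:3, 1:3, :] = True
        stack = rng.normal(size=(4, 4, 2, 2))
        scores = predict_scores(model, stack, body, np.ones(body.shape, bool))
        assert np.all(scores[body] == 0.9)
        assert not scores[~body].any()

    def test_feature_dimension_mismatch_raises(self, rng):
        model = NNModel(
            W1=np.zeros((4, 3)), b1=np.zeros(3), W2=np.zeros((3, 1)), b2=np.zeros(1),
            mean=np.zeros(4), sd=np.ones(4),
            kept_features=np.arange(4), dropped_features=np.array([], int),
        )
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(5, 7)))

    def test_threshold_boundary_semantics(self):
        scores = np.array([0.38, 0.39, 0.40])
        assert threshold_scores(scores, 0.39).tolist() == [False, True, True]

    def test_threshold_monotonic_nesting(self, rng):
        scores = rng.random((8, 8, 4))
        prev = None
        for t in (0.39, 0.49, 0.59, 0.69, 0.78, 0.88, 0.98):
            mask = threshold_scores(scores, t)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask
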