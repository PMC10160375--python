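"""The PCA-fused CNN: elementary operations against hand-computed values,
the backprop gradient against finite differences, the plain-CNN ablation
identity, the learning-rate rule and training behavior."""

import numpy as np
import pytest

from eegsa.cnn import (
    CNNConfig,
    PCAFusedCNN,
    conv_block,
    cross_entropy,
    max_pool,
    pca_fuse,
    sgd_step,
    softmax,
    update_learning_rate,
)


class TestConvBlock:
    def test_zero_weights_zero_map(self):
        out = conv_block(np.ones((4, 4)), np.zeros((2, 2)), np.zeros(1))
        assert np.all(out == 0.0)

    def test_hand_convolution(self):
        out = conv_block(np.ones((3, 3)), np.ones((2, 2)), np.zeros(1))
        assert np.allclose(out, 4.0)
        assert out.shape == (2, 2)

    def test_identity_kernel_reproduces_subwindow(self, rng):
        x = rng.random((5, 5))
        k = np.zeros((2, 2))
        k[0, 0] = 1.0
        out = conv_block(x, k, np.zeros(1))
        assert np.allclose(out, np.maximum(x[:4, :4], 0.0))

    def test_negative_sums_clipped(self):
        out = conv_block(np.ones((3, 3)), -np.ones((2, 2)), np.zeros(1))
        assert np.all(out == 0.0)

    def test_kernel_too_large_rejected(self):
        with pytest.raises(ValueError):
            conv_block(np.ones((2, 2)), np.ones((3, 3)), np.zeros(1))


class TestMaxPool:
    def test_constant_map(self):
        out = max_pool(np.full((6, 6), 2.5))
        assert np.all(out == 2.5)
        assert out.shape == (6, 6)  # stride-1 same padding keeps the shape

    def test_hand_valid_pooling(self):
        x = np.arange(1, 17, dtype=float).reshape(4, 4)
        out = max_pool(x, pool=2, stride=2, same=False)
        assert np.array_equal(out, [[6.0, 8.0], [14.0, 16.0]])

    def test_never_exceeds_global_max(self, rng):
        x = rng.normal(size=(8, 9))
        assert max_pool(x).max() <= x.max() + 1e-12


class TestPCAFuse:
    def test_zero_basis_is_identity(self, rng):
        conv = rng.random((2, 2))
        pooled = rng.random((2, 2))
        fused = pca_fuse(conv, pooled, np.zeros((4, 2)))
        assert np.array_equal(fused, pooled)

    def test_hand_built_rank_one_basis(self):
        conv = np.array([[1.0, 0.0], [0.0, 0.0]])
        pooled = np.array([[0.5, 0.5], [0.5, 0.5]])
        v = np.array([[1.0], [0.0], [0.0], [0.0]])  # projects onto cell (0,0)
        fused = pca_fuse(conv, pooled, v)
        expected = pooled + np.array([[1.0, 0.0], [0.0, 0.0]])
        assert np.allclose(fused, expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fuse(rng.random((2, 2)), rng.random((2, 2)), np.zeros((5, 1)))


class TestHead:
    def test_equal_logits_uniform(self):
        p = softmax(np.zeros(4))
        assert np.allclose(p, 0.25)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_pair(self):
        assert softmax(np.array([0.0, np.log(3)])) == pytest.approx([0.25, 0.75])

    def test_cross_entropy_closed_form(self):
        assert cross_entropy([1, 0], [0.75, 0.25]) == pytest.approx(-np.log(0.75))

    def test_loss_nonnegative(self, rng):
        q = softmax(rng.normal(size=3))
        assert cross_entropy([0, 1, 0], q) >= 0.0

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0.0]))


class TestSGD:
    def test_zero_gradient_no_change(self):
        assert sgd_step(np.array(1.0), np.array(0.0), 0.1) == 1.0

    def test_hand_step(self):
        assert sgd_step(np.array(1.0), np.array(0.5), 0.1) == pytest.approx(0.95)

    def test_lr_halved_after_loss_jump(self):
        assert update_learning_rate(0.1, prev_loss=1.0, new_loss=1.3) == pytest.approx(0.05)

    def test_lr_kept_below_threshold(self):
        assert update_learning_rate(0.1, prev_loss=1.0, new_loss=1.2) == 0.1


@pytest.fixture(scope="module")
def tiny_model_and_batch():
    cfg = CNNConfig(input_shape=(13, 20), n_filters=(2, 2), batch_size=4,
                    fusion_components=2, seed=0)
    model = PCAFusedCNN(cfg)
    rng = np.random.default_rng(0)
    x = rng.random((6, 13, 20))
    y = np.array([0, 1, 0, 1, 1, 0])
    model.fit_fusion(x)
    return model, x, y


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_model_and_batch):
        from eegsa.cnn import gradient_check

        model, x, y = tiny_model_and_batch
        worst, checked = gradient_check(model, x, y, n_coords=50, seed=1)
        assert checked >= 40  # the vast majority of coordinates are smooth
        assert worst < 1e-4

    @pytest.mark.parametrize("seed", [3, 7])
    def test_gradient_check_stable_across_seeds(self, seed):
        from eegsa.cnn import gradient_check

        cfg = CNNConfig(n_filters=(2, 2), fusion_components=2, seed=seed)
        model = PCAFusedCNN(cfg)
        rng = np.random.default_rng(seed)
        x = rng.random((5, 13, 20))
        y = rng.integers(0, 2, 5)
        y[:2] = [0, 1]
        model.fit_fusion(x)
        worst, checked = gradient_check(model, x, y, n_coords=30, seed=seed)
        assert checked >= 20
        assert worst < 1e-4


class TestAblation:
    def test_zero_fusion_equals_plain_cnn(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 13, 20))
        plain = PCAFusedCNN(CNNConfig(n_filters=(2, 2), fusion_components=0, seed=7))
        plain.fit_fusion(x)
        fused = PCAFusedCNN(CNNConfig(n_filters=(2, 2), fusion_components=2, seed=7))
        fused.V1[:] = 0.0
        fused.V2[:] = 0.0
        fused.fusion_frozen = True
        assert np.array_equal(plain.predict(x)[1], fused.predict(x)[1])


def separable_maps(seed, n=80):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, (n, 13, 20))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, 2:5, 3:8] += 1.5
    return X, y


class TestTraining:
    def test_separable_data_learned(self):
        wins = 0
        for s in range(3):
            X, y = separable_maps(s)
            cfg = CNNConfig(batch_size=20, max_iterations=300, seed=s)
            res = PCAFusedCNN(cfg).train(X, y)
            tr = res.train_indices
            acc = float(np.mean(res.model.predict(X[tr])[0] == y[tr]))
            wins += acc >= 0.95
        assert wins >= 2

    def test_same_seed_identical_trajectories(self):
        X, y = separable_maps(1, n=40)
        cfg = CNNConfig(batch_size=10, max_iterations=30, seed=5)
        h1 = PCAFusedCNN(cfg).train(X, y).history
        h2 = PCAFusedCNN(cfg).train(X, y).history
        assert np.array_equal(h1["loss"].to_numpy(), h2["loss"].to_numpy())

    def test_scores_are_probabilities(self):
        X, y = separable_maps(0, n=24)
        cfg = CNNConfig(batch_size=8, max_iterations=10, seed=0)
        res = PCAFusedCNN(cfg).train(X, y)
        labels, scores = res.model.predict(X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.array_equal(labels, (scores > 0.5).astype(int))

    def test_batch_larger_than_training_set_rejected(self):
        X, y = separable_maps(0, n=12)
        cfg = CNNConfig(batch_size=50, max_iterations=5, seed=0)
        with pytest.raises(ValueError, match="batch"):
            PCAFusedCNN(cfg).train(X, y)

    def test_wrong_input_shape_rejected(self):
        cfg = CNNConfig(n_filters=(2, 2), seed=0)
        model = PCAFusedCNN(cfg)
        with pytest.raises(ValueError, match="shape"):
            model.predict(np.zeros((2, 9, 9)))
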