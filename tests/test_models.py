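import numpy as np
import pytest

from injurycast import encoders, models
from injurycast.models import (
    AutoencoderSpec,
    ClassifierSpec,
    FocalLossParams,
    compute_alpha,
    focal_loss,
)


class TestFocalLoss:
    def test_hand_evaluated_single_point(self):
        got = focal_loss(np.array([0.9]), np.array([1]),
                         FocalLossParams(alpha=0.25, gamma=2.0))
        expected = -0.25 * 0.1**2 * np.log(0.9)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert round(expected, 7) == 2.634e-4

    def test_reduces_to_half_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=200)
        y = rng.integers(0, 2, size=200)
        got = focal_loss(p, y, FocalLossParams(alpha=0.5, gamma=0.0))
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        np.testing.assert_allclose(got, 0.5 * bce, atol=1e-12)

    def test_strictly_decreasing_in_probability_for_positives(self):
        p = np.linspace(0.05, 0.95, 50)
        losses = [focal_loss(np.array([v]), np.array([1]), FocalLossParams())
                  for v in p]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_vanishes_for_confident_correct_predictions(self):
        assert focal_loss(np.array([1.0]), np.array([1]), FocalLossParams()) < 1e-5
        assert focal_loss(np.array([0.0]), np.array([0]), FocalLossParams()) < 1e-5

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5]), np.array([2]), FocalLossParams())

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FocalLossParams(alpha=1.0)
        with pytest.raises(ValueError):
            FocalLossParams(gamma=-1.0)


class TestComputeAlpha:
    def test_reference_class_counts(self):
        # 1 - 533/39722 = 0.98658..., i.e. approximately 0.986
        assert abs(compute_alpha(533, 39722) - 0.986) < 1e-3

    def test_even_split_gives_half(self):
        assert compute_alpha(1, 2) == 0.5

    @pytest.mark.parametrize("k", [1, 10, 1000])
    def test_scale_invariance(self, k):
        np.testing.assert_allclose(compute_alpha(k, 10 * k), 0.9)

    def test_invalid_counts_rejected(self):
        for args in [(0, 10), (10, 10), (5, 0)]:
            with pytest.raises(ValueError):
                compute_alpha(*args)


@pytest.fixture(scope="module")
def toy_stacks():
    rng = np.random.default_rng(3)
    mats = rng.uniform(size=(96, 8, 10))
    return encoders.encode_dataset(mats, "gasf")


class TestDCAE:
    def test_loss_history_length_and_decrease(self, toy_stacks):
        # small batches so adadelta gets enough updates on a small dataset
        spec = AutoencoderSpec(conv_channels=(8, 16), epochs=12, batch_size=16)
        model = models.dcae_fit(toy_stacks, spec, seed=0)
        assert len(model.loss_history) == 12
        assert model.loss_history[-1] <= 0.5 * model.loss_history[0]

    def test_constant_dataset_reaches_near_zero_loss(self):
        stacks = np.full((40, 8, 8, 10), 0.3)
        spec = AutoencoderSpec(conv_channels=(4, 8), epochs=40, batch_size=8,
                               dropout_rate=0.0)
        model = models.dcae_fit(stacks, spec, seed=1)
        assert model.loss_history[-1] < 0.01

    def test_reconstruction_shape_matches_input(self, toy_stacks):
        spec = AutoencoderSpec(conv_channels=(4, 8), epochs=2)
        model = models.dcae_fit(toy_stacks[:32], spec, seed=2)
        out = model.reconstruct(toy_stacks[:5])
        assert out.shape == (5, 8, 8, 10)

    def test_encode_is_deterministic_at_inference(self, toy_stacks):
        spec = AutoencoderSpec(conv_channels=(4, 8), epochs=2)
        model = models.dcae_fit(toy_stacks[:32], spec, seed=3)
        z1 = model.encode(toy_stacks[:8])
        z2 = model.encode(toy_stacks[:8])
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (8, 5)  # default latent dimension is 5

    def test_same_seed_reproduces_training(self, toy_stacks):
        spec = AutoencoderSpec(conv_channels=(4, 8), epochs=3)
        m1 = models.dcae_fit(toy_stacks[:40], spec, seed=4)
        m2 = models.dcae_fit(toy_stacks[:40], spec, seed=4)
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)
        np.testing.assert_array_equal(m1.encode(toy_stacks[:4]), m2.encode(toy_stacks[:4]))

    def test_untrained_encode_rejected(self):
        model = models.DCAE(AutoencoderSpec(), seed=0)
        with pytest.raises(RuntimeError, match="not trained"):
            model.encode(np.zeros((2, 8, 8, 10)))

    def test_shape_mismatch_rejected_before_training(self):
        with pytest.raises(ValueError, match="8, 8, 10"):
            models.dcae_fit(np.zeros((4, 7, 10)), AutoencoderSpec(), seed=0)

    def test_weight_round_trip(self, toy_stacks, tmp_path):
        spec = AutoencoderSpec(conv_channels=(4, 8), epochs=2)
        m1 = models.dcae_fit(toy_stacks[:32], spec, seed=5)
        path = tmp_path / "w.npz"
        np.savez(path, *m1.get_weights())
        m2 = models.DCAE(spec, seed=99)
        with np.load(path) as archive:
            m2.set_weights([archive[k] for k in archive.files])
        np.testing.assert_array_equal(m1.encode(toy_stacks[:4]), m2.encode(toy_stacks[:4]))


class TestDNNClassifier:
    def test_separable_latents_learned(self):
        rng = np.random.default_rng(6)
        Z = np.concatenate([rng.normal(-2, 1, (250, 5)), rng.normal(2, 1, (250, 5))])
        y = np.array([0] * 250 + [1] * 250)
        spec = ClassifierSpec(epochs=40, focal=FocalLossParams(alpha=0.5, gamma=0.0))
        clf = models.dnn_fit(Z, y, spec, seed=6)
        pred = (clf.predict_proba(Z) >= 0.5).astype(int)
        sens = pred[y == 1].mean()
        spec_ = 1 - pred[y == 0].mean()
        assert sens >= 0.95 and spec_ >= 0.95

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        clf = models.dnn_fit(Z, y, ClassifierSpec(epochs=3), seed=7)
        p = clf.predict_proba(rng.normal(size=(30, 5)) * 10)
        assert ((p > 0) & (p < 1)).all()

    def test_permuted_labels_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        Z = np.concatenate([rng.normal(-1, 1, (300, 5)), rng.normal(1, 1, (300, 5))])
        y = rng.permutation(np.array([0] * 300 + [1] * 300))  # labels decoupled
        spec = ClassifierSpec(epochs=25, focal=FocalLossParams(alpha=0.5, gamma=0.0))
        clf = models.dnn_fit(Z[:400], y[:400], spec, seed=8)
        auc = roc_auc_score(y[400:], clf.predict_proba(Z[400:]))
        assert 0.4 <= auc <= 0.6

    def test_nan_inputs_rejected(self):
        Z = np.zeros((10, 5))
        Z[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            models.dnn_fit(Z, np.zeros(10, dtype=int), ClassifierSpec(epochs=1), seed=0)


class TestScaleStack:
    def test_unit_interval_methods_mapped_to_tanh_range(self):
        x = np.array([[0.0, 0.5, 1.0]])
        np.testing.assert_allclose(models.scale_stack(x, "mtf"), [[-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(models.scale_stack(x, "rp"), [[-1.0, 0.0, 1.0]])

    def test_angular_fields_pass_through(self):
        x = np.array([[-0.5, 0.5]])
        np.testing.assert_array_equal(models.scale_stack(x, "gasf"), x)
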