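"""Network and loss contracts: closed-form loss values, distribution
invariants, weight sharing, attention fusion properties."""

import itertools

import numpy as np
import pytest

from mammoage.autodiff import Tensor, concat
from mammoage.model import (BACKBONES, LossBundle, MammoAgeModel, ModelConfig,
                            MultiHeadAttention, ViewFeatureSet, ce_age_loss,
                            density_ce_loss, expected_age, mean_variance_loss,
                            poe_loss, total_loss)


# ---------------------------------------------------------------------------
# losses — hand-derived values
# ---------------------------------------------------------------------------

def _onehot(k, n=100):
    v = np.zeros(n)
    v[k - 1] = 1.0
    return v


class TestExpectedAge:
    def test_point_mass(self):
        assert expected_age(_onehot(40)) == 40.0

    def test_uniform(self):
        assert np.isclose(expected_age(np.full(100, 0.01)), 50.5)

    def test_symmetric_mixture(self):
        d = np.zeros(100)
        d[39] = d[59] = 0.5
        assert expected_age(d) == 50.0

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            expected_age(np.full(100, 0.02))


class TestMeanVarianceLoss:
    def test_exact_point_prediction_is_zero(self):
        assert mean_variance_loss(_onehot(50), 50) == (0.0, 0.0)

    def test_symmetric_mixture_values(self):
        d = np.zeros(100)
        d[39] = d[59] = 0.5
        m, v = mean_variance_loss(d, 50)
        assert abs(m) < 1e-9 and abs(v - 100.0) < 1e-9

    def test_offset_point_mass(self):
        m, v = mean_variance_loss(_onehot(45), 50)
        assert abs(m - 12.5) < 1e-9 and abs(v) < 1e-9


class TestCrossEntropyAge:
    def test_onehot_at_truth_is_zero(self):
        assert abs(ce_age_loss(_onehot(30), 30)) < 1e-9

    def test_uniform_is_log_100(self):
        assert abs(ce_age_loss(np.full(100, 0.01), 7) - np.log(100)) < 1e-9

    def test_half_probability_is_log_2(self):
        d = np.full(100, 0.5 / 99)
        d[49] = 0.5
        assert abs(ce_age_loss(d, 50) - np.log(2)) < 1e-9

    def test_zero_probability_floored_not_infinite(self):
        d = _onehot(10)
        assert np.isfinite(ce_age_loss(d, 90))


class TestPoeLoss:
    def test_kl_of_standard_normal_is_zero(self):
        _, kl = poe_loss(np.zeros((3, 2)), np.ones((3, 2)), np.array([30, 50, 70]))
        assert abs(kl) < 1e-9

    def test_kl_unit_mean_is_half(self):
        _, kl = poe_loss(np.ones((3, 1)), np.ones((3, 1)), np.array([30, 50, 70]))
        assert abs(kl - 0.5) < 1e-9

    def test_wellordered_embeddings_have_zero_hinge(self):
        mu = np.array([[30.0], [50.0], [70.0]])  # distances mirror age gaps
        ordinal, _ = poe_loss(mu, np.ones((3, 1)), np.array([30, 50, 70]),
                              margin=0.1)
        assert ordinal == 0.0

    def test_small_batch_has_no_ordinal_term(self):
        ordinal, _ = poe_loss(np.zeros((2, 2)), np.ones((2, 2)), np.array([30, 50]))
        assert ordinal == 0.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            poe_loss(np.zeros((3, 1)), np.zeros((3, 1)), np.array([1, 2, 3]))


class TestDensityCE:
    def test_correct_onehot_is_zero(self):
        p = np.array([[1.0, 0, 0, 0]])
        loss, n = density_ce_loss(p, ["A"])
        assert loss < 1e-9 and n == 1

    def test_uniform_is_log_4(self):
        loss, _ = density_ce_loss(np.full((1, 4), 0.25), ["C"])
        assert abs(loss - np.log(4)) < 1e-9

    def test_all_unknown_batch_is_zero_weight(self):
        loss, n = density_ce_loss(np.full((3, 4), 0.25),
                                  ["unknown", "unknown", "unknown"])
        assert loss == 0.0 and n == 0


class TestTotalLoss:
    def test_zero_weights_zero_total(self):
        terms = {"a": 1.0, "b": 2.0}
        assert total_loss(terms, {"a": 0.0, "b": 0.0}).total == 0.0

    def test_single_weighted_term(self):
        assert total_loss({"a": 3.0}, {"a": 2.0}).total == 6.0

    def test_default_weights_sum(self):
        terms = dict(zip("abcdef", (1, 2, 3, 0.5, 0.5, 1)))
        assert total_loss(terms).total == 8.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss({"a": 1.0}, {"a": -1.0})


def test_loss_gradients_match_finite_differences(rng):
    """Backward gradients of the distributional losses w.r.t. logits agree
    with central differences to 1e-4 relative error."""
    logits0 = rng.normal(size=100)
    y = 42

    def losses(logits):
        d = Tensor(logits, requires_grad=True).softmax()
        m, v = mean_variance_loss(d, y)
        ce = ce_age_loss(d, y)
        return d, m + v * 0.5 + ce

    d, out = losses(logits0)
    out.backward()

    def scalar(logits):
        _, o = losses(logits)
        return float(o.data)

    num = np.zeros(100)
    eps = 1e-6
    for i in range(100):
        up, dn = logits0.copy(), logits0.copy()
        up[i] += eps
        dn[i] -= eps
        num[i] = (scalar(up) - scalar(dn)) / (2 * eps)
    # find the logits tensor gradient
    t = d
    while t._parents:
        t = t._parents[0]
    denom = np.maximum(np.abs(num), 1e-3)
    assert (np.abs(t.grad - num) / denom).max() < 1e-4


# ---------------------------------------------------------------------------
# network structure
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def model():
    return MammoAgeModel(ModelConfig(backbone_id="tiny_cnn"), seed=1)


class TestForwardViews:
    def test_weight_sharing_identical_views(self, model, rng):
        img = rng.random((64, 32))
        images = np.stack([img, img, rng.random((64, 32)), img])[None]
        feats = model.forward_views(images)
        t = feats.tokens.data
        assert np.array_equal(t[0, 0], t[0, 1])
        assert np.array_equal(t[0, 0], t[0, 3])
        assert not np.array_equal(t[0, 0], t[0, 2])

    def test_token_grid_from_stride_arithmetic(self, model, rng):
        feats = model.forward_views(rng.random((1, 4, 256, 128)))
        assert feats.grid == (8, 4)
        assert feats.tokens.shape == (1, 4, 32, 32)

    def test_registry_contract(self):
        assert set(BACKBONES) == {"tiny_cnn", "resnet18", "resnet50",
                                  "convnext_tiny", "densenet121",
                                  "efficientnet_b0"}
        with pytest.raises(ValueError, match="unknown backbone"):
            MammoAgeModel(ModelConfig(backbone_id="vgg16"))

    @pytest.mark.parametrize("backbone", sorted(BACKBONES))
    def test_every_backbone_runs(self, backbone, rng):
        net = MammoAgeModel(ModelConfig(backbone_id=backbone), seed=0)
        out = net.forward(rng.random((1, 4, 64, 32)))
        assert out["age_probs"].shape == (1, 4, 100)


class TestInstanceBagFusion:
    def test_shape_preserving(self, model, rng):
        feats = model.forward_views(rng.random((2, 4, 64, 32)))
        fused = model.instance_bag_fuse(feats)
        assert fused.tokens.shape == feats.tokens.shape

    def test_duplicated_keys_make_cross_equal_self(self, rng):
        attn = MultiHeadAttention(32, 8, rng)
        x = Tensor(rng.normal(size=(1, 6, 32)))
        self_out = attn(x, x)
        cross_out = attn(x, concat([x, x, x, x], axis=1))
        assert np.allclose(self_out.data, cross_out.data, atol=1e-12)

    def test_identical_views_fuse_identically(self, model, rng):
        img = rng.random((64, 32))
        images = np.broadcast_to(img, (1, 4, 64, 32)).copy()
        fused = model.instance_bag_fuse(model.forward_views(images))
        t = fused.tokens.data[0]
        for v in range(1, 4):
            assert np.allclose(t[0], t[v], atol=1e-12)

    def test_permutation_equivariance_without_view_embeddings(self, model, rng):
        tokens = rng.normal(size=(1, 4, 3, 32))
        base = model.instance_bag_fuse(
            ViewFeatureSet(Tensor(tokens), grid=(3, 1))).tokens.data
        for perm in itertools.permutations(range(4)):
            out = model.instance_bag_fuse(
                ViewFeatureSet(Tensor(tokens[:, perm]), grid=(3, 1))).tokens.data
            assert np.allclose(out, base[:, perm], atol=1e-10)

    def test_head_count_must_divide_channels(self, rng):
        with pytest.raises(ValueError, match="divide"):
            MultiHeadAttention(30, 8, rng)


class TestAgeHead:
    def test_inference_deterministic_and_normalized(self, model, rng):
        images = rng.random((2, 4, 64, 32))
        a = model.forward(images)
        b = model.forward(images)
        assert np.array_equal(a["age_probs"].data, b["age_probs"].data)
        assert np.allclose(a["age_probs"].data.sum(-1), 1.0, atol=1e-6)
        assert np.all(a["sigma2"].data > 0)

    def test_training_with_zero_noise_equals_inference(self, rng):
        # dropout disabled so only the POE sampling distinguishes the modes
        net = MammoAgeModel(ModelConfig(backbone_id="tiny_cnn", dropout=0.0), seed=2)
        images = rng.random((1, 4, 64, 32))
        feats = net.instance_bag_fuse(net.forward_views(images))

        class ZeroNoise:
            def standard_normal(self, shape):
                return np.zeros(shape)

        train_probs, _, _ = net.age_head(feats, training=True, rng=ZeroNoise())
        eval_probs, _, _ = net.age_head(feats, training=False)
        assert np.allclose(train_probs.data, eval_probs.data)

    def test_exam_age_is_mean_of_view_ages(self, model, rng):
        out = model.forward(rng.random((3, 4, 64, 32)))
        assert np.allclose(out["exam_age"], out["view_ages"].mean(axis=1))
        assert np.all((out["exam_age"] >= 1) & (out["exam_age"] <= 100))


def test_checkpoint_roundtrip(tmp_path, model, rng):
    from mammoage.model import load_checkpoint, save_checkpoint
    images = rng.random((1, 4, 64, 32))
    before = model.forward(images)["exam_age"]
    path = str(tmp_path / "m.npz")
    save_checkpoint(model, path, seed=1)
    restored = load_checkpoint(path)
    after = restored.forward(images)["exam_age"]
    assert np.allclose(before, after)
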