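import numpy as np
import pytest

from metacam.cams import (
    CAM_METHODS,
    channel_weights,
    compute_cam,
    eigen_cam,
    eigen_projection,
    elementwise_map,
    fullgrad_map,
    random_cam,
)
from metacam.errors import ParameterError
from metacam.models import ActivationBundle

from _oracles import naive_ablation_weights, naive_scorecam_weights


def bundle(a, g, cls=0):
    return ActivationBundle(
        feature_maps=np.asarray(a, dtype=float),
        gradients=np.asarray(g, dtype=float),
        class_index=cls,
    )


class TestChannelWeights:
    def test_gradcam_is_spatial_mean(self):
        g = np.stack([np.full((2, 2), 0.5), np.full((2, 2), -1.0)])
        a = np.ones_like(g)
        np.testing.assert_allclose(
            channel_weights("gradcam", bundle(a, g)), [0.5, -1.0]
        )

    def test_xgradcam_zero_activation_channel_guarded(self):
        a = np.stack([np.zeros((2, 2)), np.ones((2, 2))])
        g = np.ones_like(a)
        w = channel_weights("xgradcam", bundle(a, g))
        assert w[0] == pytest.approx(0.0)
        assert w[1] == pytest.approx(1.0, rel=1e-6)

    def test_gradcampp_positive_gradients_uniform(self):
        """Constant positive gradients with constant activations reduce
        GradCAM++ to equal per-channel weights."""
        a = np.ones((2, 3, 3))
        g = np.full((2, 3, 3), 0.2)
        w = channel_weights("gradcampp", bundle(a, g))
        assert w[0] == pytest.approx(w[1])
        assert (w > 0).all()


class TestElementwiseMaps:
    def test_hirescam_hand_example(self):
        a = [[[1.0, -1.0], [0.0, 2.0]]]
        out = elementwise_map("hirescam", bundle(a, a))
        np.testing.assert_allclose(out.values, [[1.0, 1.0], [0.0, 4.0]])

    def test_gradcam_elementwise_same_on_single_channel(self):
        a = [[[1.0, -1.0], [0.0, 2.0]]]
        out = elementwise_map("gradcam_elementwise", bundle(a, a))
        np.testing.assert_allclose(out.values, [[1.0, 1.0], [0.0, 4.0]])

    def test_hirescam_and_elementwise_differ_on_cancellation(self):
        """Negative products in one channel cancel positives in another for
        HiResCAM (sum before ReLU) but not GradCAMElementwise."""
        a = np.stack([np.ones((1, 1)), np.ones((1, 1))])
        g = np.stack([np.full((1, 1), 2.0), np.full((1, 1), -2.0)])
        b = bundle(a, g)
        hi = elementwise_map("hirescam", b).values
        el = elementwise_map("gradcam_elementwise", b).values
        assert hi[0, 0] == pytest.approx(0.0)
        assert el[0, 0] == pytest.approx(2.0)

    def test_layercam_all_negative_gradients_zero(self):
        a = np.ones((2, 2, 2))
        g = -np.ones((2, 2, 2))
        out = elementwise_map("layercam", bundle(a, g))
        np.testing.assert_array_equal(out.values, np.zeros((2, 2)))


class TestAssembleCam:
    def test_hand_arithmetic_through_weighting(self):
        """GradCAM weights (0.5, -1) applied to disjoint single-pixel
        channels: post-ReLU [[0.5,0],[0,0]], normalized [[1,0],[0,0]]."""

        class Stub:
            class_count = 2
            layer_names = ("L",)
            input_shape = (2, 2, 1)

            def logits(self, image):
                return np.array([1.0, 0.0])

            def capture(self, image, layer_name, class_index):
                a = np.stack(
                    [[[1.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 1.0]]]
                )
                g = np.stack([np.full((2, 2), 0.5), np.full((2, 2), -1.0)])
                return ActivationBundle(a, g, class_index)

        res = compute_cam("gradcam", Stub(), np.zeros((2, 2, 1)), layer="L", class_index=0)
        assert res.valid
        np.testing.assert_allclose(res.map.values, [[1.0, 0.0], [0.0, 0.0]])

    def test_zero_gradients_flagged_invalid(self, toy_model, toy_image):
        toy_model.fc.W[:] = 0.0  # head ignores the layer -> zero gradients
        res = compute_cam("gradcam", toy_model, toy_image, class_index=0)
        assert not res.valid
        assert res.reason

    def test_gradcam_equals_hirescam_for_constant_gradients(self, toy_model, toy_image):
        """With a GAP head, per-channel gradients are spatially constant,
        so GradCAM and HiResCAM coincide after normalization."""
        g1 = compute_cam("gradcam", toy_model, toy_image, class_index=0)
        h1 = compute_cam("hirescam", toy_model, toy_image, class_index=0)
        assert g1.valid and h1.valid
        np.testing.assert_allclose(g1.map.values, h1.map.values, atol=1e-10)


class TestPerturbationCams:
    def test_scorecam_matches_naive_loop(self, fixture_model, scene):
        model, _ = fixture_model
        res = compute_cam(
            "scorecam", model, scene.image, class_index=scene.class_label
        )
        w = naive_scorecam_weights(model, scene.image, "conv3", scene.class_label)
        bundle_ = model.capture(scene.image, "conv3", scene.class_label)
        raw = np.maximum((w[:, None, None] * bundle_.feature_maps).sum(axis=0), 0.0)
        from metacam.saliency import SaliencyMap, normalize_unit, upsample_bilinear

        expected = normalize_unit(upsample_bilinear(SaliencyMap(raw), 64, 64))
        assert res.valid
        np.testing.assert_allclose(res.map.values, expected.values, atol=1e-5)

    def test_ablationcam_matches_naive_loop(self, fixture_model, scene):
        model, _ = fixture_model
        res = compute_cam(
            "ablationcam", model, scene.image, class_index=scene.class_label
        )
        w = naive_ablation_weights(model, scene.image, "conv3", scene.class_label)
        bundle_ = model.capture(scene.image, "conv3", scene.class_label)
        raw = np.maximum((w[:, None, None] * bundle_.feature_maps).sum(axis=0), 0.0)
        from metacam.saliency import SaliencyMap, normalize_unit, upsample_bilinear

        expected = normalize_unit(upsample_bilinear(SaliencyMap(raw), 64, 64))
        assert res.valid
        np.testing.assert_allclose(res.map.values, expected.values, atol=1e-5)

    def test_ablating_irrelevant_channel_gets_zero_weight(self, toy_model, toy_image):
        toy_model.fc.W[:, 4] = 0.0
        w = naive_ablation_weights(toy_model, toy_image, "conv3", 0)
        assert w[4] == pytest.approx(0.0, abs=1e-12)


class TestEigenCams:
    def test_single_channel_proportional_to_it(self):
        a = np.abs(np.random.default_rng(0).normal(size=(1, 3, 3))) + 0.1
        res = eigen_cam("eigencam", bundle(a, np.ones_like(a)), (3, 3))
        assert res.valid
        flat_in = (a[0] - a[0].min()) / (a[0].max() - a[0].min())
        np.testing.assert_allclose(res.map.values, flat_in, atol=1e-10)

    def test_duplicated_channels_match_single(self):
        a1 = np.abs(np.random.default_rng(1).normal(size=(1, 4, 4))) + 0.1
        a2 = np.concatenate([a1, a1])
        r1 = eigen_cam("eigencam", bundle(a1, np.ones_like(a1)), (4, 4))
        r2 = eigen_cam("eigencam", bundle(a2, np.ones_like(a2)), (4, 4))
        np.testing.assert_allclose(r1.map.values, r2.map.values, atol=1e-10)

    def test_projection_matches_dense_eig_oracle(self):
        """First-component projection agrees with an eigendecomposition of
        the Gram matrix (independent of the SVD route)."""
        rng = np.random.default_rng(2)
        stack = rng.normal(size=(3, 4, 5))
        proj = eigen_projection(stack)
        mat = stack.reshape(3, -1)
        evals, evecs = np.linalg.eigh(mat.T @ mat)
        v = evecs[:, -1] * np.sqrt(evals[-1])
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        np.testing.assert_allclose(proj.ravel(), v, atol=1e-6)

    def test_rank_zero_invalid(self):
        res = eigen_cam("eigencam", bundle(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))), (2, 2))
        assert not res.valid


class TestFullGrad:
    def test_bias_free_model_reduces_to_input_gradient_term(self, toy_model, toy_image):
        for layer in (toy_model.conv1, toy_model.conv2, toy_model.conv3):
            layer.b[:] = 0.0
        res = fullgrad_map(toy_model, toy_image, class_index=0)
        grad, _ = toy_model.full_gradients(toy_image, 0)
        term = np.abs(grad * toy_image).sum(axis=2)
        expected = (term - term.min()) / (term.max() - term.min())
        assert res.valid
        np.testing.assert_allclose(res.map.values, expected, atol=1e-10)

    def test_model_without_bias_gradients_invalid(self):
        class NoBias:
            class_count = 2
            layer_names = ("L",)
            input_shape = (2, 2, 1)

            def logits(self, image):
                return np.zeros(2)

            def capture(self, image, layer_name, class_index):
                raise NotImplementedError

        res = fullgrad_map(NoBias(), np.zeros((2, 2, 1)), class_index=0)
        assert not res.valid


class TestRandomCam:
    def test_seeded_determinism(self):
        a = random_cam(8, 8, seed=5)
        b = random_cam(8, 8, seed=5)
        np.testing.assert_array_equal(a.map.values, b.map.values)

    def test_mean_near_zero_at_large_n(self):
        rng = np.random.default_rng(11)
        raw = rng.uniform(-1.0, 1.0, size=(100, 100))
        assert abs(raw.mean()) < 0.05  # CLT bound at 10^4 pixels

    def test_rejects_bad_dims(self):
        with pytest.raises(ParameterError):
            random_cam(0, 5, seed=0)


class TestRegistry:
    def test_exactly_twelve_methods(self):
        assert len(CAM_METHODS) == 12
        assert "randomcam" in CAM_METHODS

    def test_unknown_method_rejected(self, toy_model, toy_image):
        with pytest.raises(ParameterError):
            compute_cam("nope", toy_model, toy_image)

    def test_all_outputs_normalized_or_invalid(self, fixture_model, scene):
        model, _ = fixture_model
        for m in CAM_METHODS:
            res = compute_cam(m, model, scene.image, class_index=scene.class_label, seed=1)
            v = res.map.values
            assert res.map.shape == (64, 64)
            assert np.isfinite(v).all()
            assert v.min() >= 0.0 and v.max() <= 1.0
            if not res.valid:
                assert res.reason
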