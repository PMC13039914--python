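import numpy as np
import pytest

from metacam.cams import CamResult
from metacam.ensemble import (
    AdaptiveResult,
    EnsembleConfig,
    adaptive_threshold_search,
    consensus_metacam,
    drop_invalid,
    mean_ensemble,
    weight_transform,
    weighted_ensemble,
)
from metacam.errors import EnsembleError, ParameterError
from metacam.road import RoadConfig
from metacam.saliency import SaliencyMap, normalize_unit


def smap(values):
    return SaliencyMap(np.asarray(values, dtype=float))


def cam_result(values, valid=True, method="m", reason=None):
    return CamResult(
        method=method,
        map=smap(values),
        valid=valid,
        reason=reason,
    )


class TestDropInvalid:
    def test_filters_flagged_and_degenerate(self):
        good1 = cam_result([[0.0, 1.0]], method="a")
        flagged = cam_result([[0.0, 1.0]], valid=False, method="b", reason="x")
        zero = cam_result([[0.0, 0.0]], method="c")
        good2 = cam_result([[1.0, 0.5]], method="d")
        kept = drop_invalid([good1, flagged, zero, good2])
        assert [r.method for r in kept] == ["a", "d"]

    def test_all_invalid_raises_with_reasons(self):
        bad = cam_result([[0.0, 1.0]], valid=False, method="b", reason="boom")
        with pytest.raises(EnsembleError, match="boom"):
            drop_invalid([bad])

    def test_all_valid_unchanged(self):
        results = [cam_result([[0.0, 1.0]], method=str(i)) for i in range(3)]
        assert drop_invalid(results) == results


class TestMeanEnsemble:
    def test_identical_maps_returned(self):
        m = normalize_unit(smap([[0.2, 0.8], [0.4, 1.0]]))
        out = mean_ensemble([m, m, m])
        np.testing.assert_allclose(out.values, m.values)

    def test_hand_example_disjoint_supports(self):
        a = smap([[1.0, 0.0], [0.0, 0.0]])
        b = smap([[0.0, 0.0], [0.0, 1.0]])
        out = mean_ensemble([a, b])
        np.testing.assert_allclose(out.values, [[1.0, 0.0], [0.0, 1.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            mean_ensemble([smap([[1.0]]), smap([[1.0, 2.0]])])


class TestWeightTransform:
    def test_minmax_affine(self):
        np.testing.assert_allclose(weight_transform([0.1, 0.2], "minmax"), [0.0, 1.0])

    def test_equal_values_uniform_any_mode(self):
        for mode in ("minmax", "softmax_amplified", "exponential"):
            w = weight_transform([0.3, 0.3, 0.3], mode)
            np.testing.assert_allclose(w, np.full(3, w[0]))

    def test_softmax_amplification_rule(self):
        """[0.01, 0.02]: smallest power of 10 with max|s*v| >= 10 is
        s=1000, so the result is softmax([10, 20])."""
        got = weight_transform([0.01, 0.02], "softmax_amplified")
        e = np.exp([10.0 - 20.0, 0.0])
        np.testing.assert_allclose(got, e / e.sum())

    def test_none_shifts_negatives(self):
        got = weight_transform([-0.2, 0.3], "none")
        np.testing.assert_allclose(got, [0.0, 0.5])
        assert (got >= 0).all()


class TestWeightedEnsemble:
    def test_uniform_weights_equal_mean_bitwise(self):
        rng = np.random.default_rng(0)
        maps = [normalize_unit(smap(rng.random((4, 4)))) for _ in range(3)]
        a = weighted_ensemble(maps, [1.0, 1.0, 1.0])
        b = mean_ensemble(maps)
        np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_selection(self):
        m1 = normalize_unit(smap([[0.0, 1.0], [0.5, 0.25]]))
        m2 = normalize_unit(smap([[1.0, 0.0], [0.0, 0.0]]))
        out = weighted_ensemble([m1, m2], [1.0, 0.0])
        np.testing.assert_allclose(out.values, m1.values)

    def test_hand_convex_combination(self):
        m1 = smap([[0.0, 1.0]])
        m2 = smap([[1.0, 0.0]])
        out = weighted_ensemble([m1, m2], [1.0, 3.0])
        expected = np.array([[0.75, 0.25]])
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        np.testing.assert_allclose(out.values, expected)

    def test_zero_weights_rejected(self):
        with pytest.raises(EnsembleError):
            weighted_ensemble([smap([[1.0, 0.0]])], [0.0])


class TestConsensus:
    def test_single_map_k100_identity(self):
        m = normalize_unit(smap([[0.1, 0.9], [0.4, 0.6]]))
        out = consensus_metacam([m], 100)
        np.testing.assert_allclose(out.values, m.values)

    def test_agreement_pixel_survives_small_k(self):
        """Two maps that agree only on one pixel: at small k only the
        agreed pixel survives the summed threshold."""
        a = smap([[1.0, 0.9, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        b = smap([[1.0, 0.0, 0.9], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        out = consensus_metacam([a, b], 12)  # keep top ~1 of 9 pixels
        nonzero = np.nonzero(out.values)
        assert list(zip(*nonzero)) == [(0, 0)]

    def test_constant_map_does_not_change_support(self):
        rng = np.random.default_rng(1)
        maps = [normalize_unit(smap(rng.random((5, 5)))) for _ in range(2)]
        const = smap(np.full((5, 5), 0.5))
        base = consensus_metacam(maps, 40)
        shifted = consensus_metacam(maps + [const], 40)
        np.testing.assert_array_equal(base.values != 0, shifted.values != 0)

    def test_support_shrinks_with_k(self):
        rng = np.random.default_rng(2)
        maps = [normalize_unit(smap(rng.random((8, 8)))) for _ in range(4)]
        sizes = [
            (consensus_metacam(maps, k).values != 0).sum()
            for k in (80, 60, 40, 20, 10)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestAdaptiveSearch:
    class BumpModel:
        """Confidence favors maps concentrated on the image center."""

        class_count = 2
        layer_names = ("L",)
        input_shape = (6, 6, 1)

        def logits(self, image):
            img = np.asarray(image)
            s = 20.0 * (img[2:4, 2:4].mean() - img.mean())
            return np.array([s, -s])

        def capture(self, image, layer_name, class_index):
            raise NotImplementedError

    def test_singleton_grid_returned(self):
        m = normalize_unit(smap(np.random.default_rng(0).random((6, 6))))
        res = adaptive_threshold_search(
            m,
            self.BumpModel(),
            np.random.default_rng(1).random((6, 6, 1)),
            0,
            k_grid=(30,),
            road_config=RoadConfig(noise_std=0.0),
        )
        assert res.best_k == 30
        assert set(res.scores_by_k) == {30}

    def test_best_k_attains_table_maximum(self):
        rng = np.random.default_rng(3)
        maps = [normalize_unit(smap(rng.random((6, 6)))) for _ in range(3)]
        res = adaptive_threshold_search(
            maps,
            self.BumpModel(),
            rng.random((6, 6, 1)),
            0,
            k_grid=(10, 25, 50, 75, 100),
            road_config=RoadConfig(noise_std=0.0),
        )
        assert res.scores_by_k[res.best_k] == max(res.scores_by_k.values())
        assert isinstance(res, AdaptiveResult)

    def test_constant_model_ties_break_to_smallest_k(self):
        class Flat:
            class_count = 2
            layer_names = ("L",)
            input_shape = (6, 6, 1)

            def logits(self, image):
                return np.array([0.0, 0.0])

            def capture(self, image, layer_name, class_index):
                raise NotImplementedError

        m = normalize_unit(smap(np.random.default_rng(4).random((6, 6))))
        res = adaptive_threshold_search(
            m,
            Flat(),
            np.random.default_rng(5).random((6, 6, 1)),
            0,
            k_grid=(40, 20, 60),
            road_config=RoadConfig(noise_std=0.0),
        )
        assert set(res.scores_by_k.values()) == {0.0}
        assert res.best_k == 20

    def test_empty_grid_rejected(self):
        m = normalize_unit(smap(np.random.default_rng(6).random((6, 6))))
        with pytest.raises(ParameterError):
            adaptive_threshold_search(
                m, self.BumpModel(), np.zeros((6, 6, 1)), 0, k_grid=()
            )


class TestEnsembleConfig:
    def test_validation(self):
        with pytest.raises(ParameterError):
            EnsembleConfig(mode="bogus")
        with pytest.raises(ParameterError):
            EnsembleConfig(k_grid=(0.0,))
        cfg = EnsembleConfig()
        assert cfg.mode == "consensus"
        assert cfg.k_grid[0] == 5
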