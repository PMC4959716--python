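"""Kernel malignancy model: scoring arithmetic, calibration, training."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promai.mai import (
    FEATURE_NAMES,
    KernelMalignancyModel,
    assemble_features,
    calibrate_to_mai,
    gleason_anchor,
    raw_malignancy_score,
    train_mai_model,
)
from promai.parametric_maps import FLAG_TOFTS, ParametricMaps


def _hand_model(projection=(2.0, -1.0)) -> KernelMalignancyModel:
    """A fully specified 2-kernel model in a 2D feature space."""
    m = KernelMalignancyModel()
    m.feature_mean_ = np.zeros(2)
    m.feature_scale_ = np.ones(2)
    m.centers_ = np.array([[0.0, 0.0], [1.0, 1.0]])
    m.widths_ = np.array([1.0, 0.5])
    m.projection_weights_ = np.asarray(projection, dtype=float)
    m.linear_weights_ = np.ones(2)
    m.bias_ = 0.5
    m.calibration_raw_ = np.array([0.0, 1.0, 2.0])
    m.calibration_mai_ = np.array([0.3, 0.6, 1.0])
    m.classes_ = np.array([0, 6, 10])
    m.n_features_in_ = 2
    m.validation_ranking_error_ = 0.0
    m.train_ranking_error_ = 0.0
    return m


class TestRawScore:
    def test_hand_computed_two_kernel_table(self):
        """Scores match the kernel/linear arithmetic written out by hand."""
        m = _hand_model()

        def oracle(x):
            phi1 = math.exp(-((x[0] - 0) ** 2 + (x[1] - 0) ** 2) / (2 * 1.0**2))
            phi2 = math.exp(-((x[0] - 1) ** 2 + (x[1] - 1) ** 2) / (2 * 0.5**2))
            return 2.0 * phi1 - 1.0 * phi2 + 0.5

        inputs = [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5)]
        expected = [oracle(x) for x in inputs]
        got = raw_malignancy_score(np.array(inputs), m)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        # frozen values of the same arithmetic
        np.testing.assert_allclose(
            expected, [2.4816844, 0.2357589, 1.6897221], atol=1e-7
        )

    def test_zero_weights_give_bias(self):
        m = _hand_model(projection=(0.0, 0.0))
        got = raw_malignancy_score(np.array([[3.0, -2.0], [0.1, 0.2]]), m)
        np.testing.assert_allclose(got, 0.5)

    def test_single_kernel_activation_at_width_distance(self):
        m = _hand_model(projection=(1.0, 0.0))
        m.bias_ = 0.0
        at_center = raw_malignancy_score(np.array([[0.0, 0.0]]), m)[0]
        at_width = raw_malignancy_score(np.array([[1.0, 0.0]]), m)[0]
        # activation 1 at the centre, e^(-1/2) one width away (minus the
        # negligible second-kernel term, removed by zero projection)
        assert at_center == pytest.approx(1.0)
        assert at_width == pytest.approx(math.exp(-0.5))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            raw_malignancy_score(np.ones((2, 3)), _hand_model())


class TestCalibration:
    def test_interpolation_and_clamping(self):
        m = _hand_model()
        assert calibrate_to_mai(0.5, m) == pytest.approx(0.45)
        assert calibrate_to_mai(-5.0, m) == pytest.approx(0.3)  # below lowest node
        assert calibrate_to_mai(9.0, m) == pytest.approx(1.0)

    def test_gleason_anchor_policy(self):
        assert gleason_anchor(6) == pytest.approx(0.6)
        assert gleason_anchor(10) == pytest.approx(1.0)
        assert gleason_anchor(0) == pytest.approx(0.3)
        for g in (6, 7, 8, 9, 10):
            assert gleason_anchor(g) == pytest.approx(0.6 + 0.1 * (g - 6))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=50))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_over_any_raw_grid(self, raws):
        m = _hand_model()
        out = m.calibrate(np.sort(np.asarray(raws)))
        assert np.all(np.diff(out) >= -1e-12)
        assert np.all((out >= 0) & (out <= 1))

    def test_non_monotone_nodes_rejected_at_load(self):
        m = _hand_model()
        d = m.to_json_dict()
        d["calibration_raw"] = [0.0, 2.0, 1.0]
        with pytest.raises(ValueError):
            KernelMalignancyModel.from_json_dict(d)


class TestAssembleFeatures:
    def _maps(self, n=3):
        shape = (n, n, n)
        arr = {k: np.random.default_rng(1).normal(size=shape)
               for k in ("adc", "s0", "ktrans", "ve", "kep", "t2w_norm")}
        flags = np.zeros(shape, dtype=int)
        return ParametricMaps(**arr, flags=flags, affine=np.eye(4))

    def test_component_order_and_shape(self):
        maps = self._maps()
        mask = np.ones(maps.shape, dtype=bool)
        X, used = assemble_features(maps, mask)
        assert X.shape == (mask.sum(), len(FEATURE_NAMES))
        np.testing.assert_array_equal(X[:, 1], maps.adc[used])
        np.testing.assert_array_equal(X[:, 0], maps.t2w_norm[used])

    def test_flagged_voxels_excluded(self):
        maps = self._maps()
        maps.flags[0, 0, 0] = FLAG_TOFTS
        mask = np.ones(maps.shape, dtype=bool)
        X, used = assemble_features(maps, mask)
        assert not used[0, 0, 0]
        assert X.shape[0] == mask.sum() - 1

    def test_empty_and_all_flagged_masks_rejected(self):
        maps = self._maps()
        with pytest.raises(ValueError):
            assemble_features(maps, np.zeros(maps.shape, dtype=bool))
        maps.flags[:] = FLAG_TOFTS
        with pytest.raises(ValueError):
            assemble_features(maps, np.ones(maps.shape, dtype=bool))


def _synthetic_classes(rng, n_per_class=120, classes=(0, 6, 7, 8)):
    """Gaussian class clouds along a malignancy direction in 5D."""
    X, y = [], []
    for i, c in enumerate(classes):
        mu = np.zeros(5)
        mu[:2] = i  # separation along two features
        X.append(rng.normal(mu, 0.35, size=(n_per_class, 5)))
        y.append(np.full(n_per_class, c, dtype=int))
    return np.vstack(X), np.concatenate(y)


class TestTraining:
    def test_separable_two_class_reaches_zero_ranking_error(self):
        rng = np.random.default_rng(0)
        X0 = rng.normal(0.0, 0.2, size=(150, 5))
        X1 = rng.normal(3.0, 0.2, size=(150, 5))
        X = np.vstack([X0, X1])
        y = np.array([0] * 150 + [7] * 150)
        model = train_mai_model(X, y, seed=1)
        assert model.train_ranking_error_ == 0.0

    def test_class_median_ordering_after_training(self):
        rng = np.random.default_rng(3)
        X, y = _synthetic_classes(rng)
        model = train_mai_model(X, y, seed=2)
        mai = model.predict(X)
        med = {c: np.median(mai[y == c]) for c in (0, 6, 8)}
        assert med[0] < med[6] < med[8]

    def test_gleason6_median_lands_on_its_anchor(self):
        rng = np.random.default_rng(4)
        X, y = _synthetic_classes(rng)
        model = train_mai_model(X, y, seed=5)
        mai = model.predict(X)
        assert np.median(mai[y == 6]) == pytest.approx(0.6, abs=0.05)

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(6)
        X, y = _synthetic_classes(rng, n_per_class=80)
        m1 = train_mai_model(X, y, seed=9)
        m2 = train_mai_model(X, y, seed=9)
        assert json.dumps(m1.to_json_dict(), sort_keys=True) == json.dumps(
            m2.to_json_dict(), sort_keys=True
        )

    def test_single_class_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            train_mai_model(X, np.zeros(10, dtype=int), seed=0)

    def test_serialization_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        X, y = _synthetic_classes(rng, n_per_class=60, classes=(0, 7))
        model = train_mai_model(X, y, seed=3)
        p = model.save(tmp_path / "model.json")
        back = KernelMalignancyModel.load(p)
        np.testing.assert_array_equal(back.centers_, model.centers_)
        np.testing.assert_array_equal(back.projection_weights_,
                                      model.projection_weights_)
        np.testing.assert_array_equal(back.calibration_raw_, model.calibration_raw_)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))

    def test_sklearn_params_round_trip(self):
        model = KernelMalignancyModel(max_kernels=12, patience=3)
        params = model.get_params()
        clone = KernelMalignancyModel(**params)
        assert clone.get_params() == params
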