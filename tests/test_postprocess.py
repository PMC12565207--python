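import math
from collections import deque

import numpy as np
import pytest

from lesionseg.io import BinaryMask, MultiModalVolume
from lesionseg.networks import NetworkSpec, build_network
from lesionseg.postprocess import (
    UncertaintyMap,
    binary_entropy,
    ensemble_predict,
    expected_calibration_error,
    mc_dropout_predict,
    remove_small_blobs,
    uncertainty_error_summary,
)


def flood_fill_filter(mask: np.ndarray, min_voxels: int, connectivity: int) -> np.ndarray:
    """Brute-force BFS connected-component filter; the independent oracle."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    visited = np.zeros_like(mask, dtype=bool)
    out = np.zeros_like(mask)
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        component = [start]
        visited[start] = True
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2] \
                        and mask[nz, ny, nx] and not visited[nz, ny, nx]:
                    visited[nz, ny, nx] = True
                    component.append((nz, ny, nx))
                    queue.append((nz, ny, nx))
        if len(component) >= min_voxels:
            for voxel in component:
                out[voxel] = 1
    return out


def _mask(data):
    return BinaryMask(np.asarray(data, dtype=np.uint8), (1, 1, 1))


class TestRemoveSmallBlobs:
    def test_two_voxel_component_below_threshold_removed(self):
        data = np.zeros((5, 5, 5))
        data[1, 1, 1] = data[1, 1, 2] = 1
        out = remove_small_blobs(_mask(data), min_voxels=3)
        assert out.data.sum() == 0

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        data = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
        out = remove_small_blobs(_mask(data), min_voxels=0)
        np.testing.assert_array_equal(out.data, data)

    def test_mixed_component_sizes(self):
        data = np.zeros((10, 10, 10))
        data[0, 0, 0:2] = 1                  # size 2
        data[4, 4, 2:7] = 1                  # size 5
        data[8, 0:3, 0:3] = 1                # size 9
        out = remove_small_blobs(_mask(data), min_voxels=5)
        assert out.data.sum() == 14

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(50):
            data = (rng.random((12, 12, 12)) < 0.25).astype(np.uint8)
            min_voxels = int(rng.integers(0, 8))
            ours = remove_small_blobs(_mask(data), min_voxels, connectivity).data
            oracle = flood_fill_filter(data, min_voxels, connectivity)
            np.testing.assert_array_equal(ours, oracle)

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(1)
        data = (rng.random((10, 10, 10)) < 0.25).astype(np.uint8)
        once = remove_small_blobs(_mask(data), 4)
        twice = remove_small_blobs(once, 4)
        np.testing.assert_array_equal(once.data, twice.data)
        stricter = remove_small_blobs(_mask(data), 8)
        assert np.all(stricter.data <= once.data)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            remove_small_blobs(_mask(np.zeros((3, 3, 3))), -1)


class TestBinaryEntropy:
    def test_maximum_at_half(self):
        assert binary_entropy(0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_zero_at_certainty(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0

    def test_hand_value_at_quarter(self):
        assert binary_entropy(0.25) == pytest.approx(0.562335, abs=1e-6)

    def test_vectorized_bounded_by_ln2(self):
        p = np.linspace(0, 1, 101)
        h = binary_entropy(p)
        assert np.all((h >= 0) & (h <= math.log(2) + 1e-12))


@pytest.fixture(scope="module")
def tiny_volume():
    rng = np.random.default_rng(0)
    return MultiModalVolume(rng.standard_normal((3, 16, 16, 16)).astype(np.float32),
                            (1, 1, 1))


class TestMCDropout:
    def test_requires_dropout_layers(self, tiny_volume):
        spec = NetworkSpec.tiny()
        import dataclasses

        no_dropout = build_network(dataclasses.replace(spec, dropout_rate=0.0))
        with pytest.raises(ValueError, match="dropout"):
            mc_dropout_predict(no_dropout, tiny_volume, n_passes=2, patch_size=16)

    def test_mean_and_entropy_consistent(self, tiny_volume):
        model = build_network(NetworkSpec.tiny(), seed=1)
        unc = mc_dropout_predict(model, tiny_volume, n_passes=4, seed=0, patch_size=16)
        assert unc.method == "mc_dropout"
        assert unc.n_samples == 4
        np.testing.assert_allclose(unc.uncertainty, binary_entropy(unc.mean_prob),
                                   atol=1e-12)
        assert unc.uncertainty.max() <= math.log(2) + 1e-12

    def test_seeded_reproducibility(self, tiny_volume):
        model = build_network(NetworkSpec.tiny(), seed=1)
        a = mc_dropout_predict(model, tiny_volume, n_passes=3, seed=5, patch_size=16)
        b = mc_dropout_predict(model, tiny_volume, n_passes=3, seed=5, patch_size=16)
        np.testing.assert_array_equal(a.mean_prob, b.mean_prob)


class _ConstantModel:
    def __init__(self, value, spec):
        self.value = value
        self.spec = spec

    def forward(self, x, mode=None):
        return np.full((x.shape[0], 1) + x.shape[2:], self.value)


class TestEnsemblePredict:
    def test_identical_members_zero_variance(self, tiny_volume):
        member = build_network(NetworkSpec.tiny(), seed=2)
        clone = build_network(NetworkSpec.tiny(), seed=2)
        unc = ensemble_predict([member, clone], tiny_volume, patch_size=16)
        np.testing.assert_allclose(unc.uncertainty, 0.0, atol=1e-12)

    def test_two_point_variance(self, tiny_volume):
        spec = NetworkSpec.tiny()
        members = [_ConstantModel(0.0, spec), _ConstantModel(1.0, spec)]
        unc = ensemble_predict(members, tiny_volume, patch_size=16)
        np.testing.assert_allclose(unc.mean_prob, 0.5)
        np.testing.assert_allclose(unc.uncertainty, 0.25)

    def test_differently_seeded_members_disagree(self, tiny_volume):
        members = [build_network(NetworkSpec.tiny(), seed=s) for s in (0, 1)]
        unc = ensemble_predict(members, tiny_volume, patch_size=16)
        assert unc.uncertainty.mean() > 0
        assert unc.uncertainty.max() <= 0.25 + 1e-12

    def test_single_member_rejected(self, tiny_volume):
        with pytest.raises(ValueError):
            ensemble_predict([build_network(NetworkSpec.tiny())], tiny_volume)


class TestCalibration:
    def test_confident_correct_predictions_zero_ece(self):
        probs = np.array([0.9999, 0.0001, 0.9999, 0.0001])
        labels = np.array([1, 0, 1, 0])
        report = expected_calibration_error(probs, labels)
        assert report.ece == pytest.approx(0.0, abs=1e-3)

    def test_single_bin_hand_value(self):
        probs = np.full(1000, 0.9)
        labels = np.ones(1000)
        report = expected_calibration_error(probs, labels)
        assert report.ece == pytest.approx(0.1, abs=1e-9)

    def test_bin_counts_partition_voxels(self):
        rng = np.random.default_rng(3)
        probs = rng.random(5000)
        labels = (rng.random(5000) < 0.5).astype(int)
        report = expected_calibration_error(probs, labels)
        assert report.bin_counts.sum() == 5000

    def test_calibrated_by_construction_low_ece(self):
        rng = np.random.default_rng(4)
        probs = rng.random(20000)
        labels = (rng.random(20000) < probs).astype(int)
        report = expected_calibration_error(probs, labels)
        assert report.ece <= 0.05

    def test_uncertainty_error_correlation_positive_when_errors_are_uncertain(self):
        rng = np.random.default_rng(5)
        probs = np.concatenate([rng.uniform(0.9, 1.0, 500),    # confident correct
                                rng.uniform(0.45, 0.55, 100)])  # uncertain wrong-ish
        labels = np.concatenate([np.ones(500), np.zeros(100)])
        report = expected_calibration_error(probs, labels)
        assert report.unc_error_correlation > 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([]), np.array([]))


def test_uncertainty_error_summary_directional():
    mean_prob = np.array([[[0.95, 0.55], [0.05, 0.45]]])
    target = BinaryMask(np.array([[[1, 0], [0, 1]]], dtype=np.uint8), (1, 1, 1))
    unc = UncertaintyMap(mean_prob=mean_prob, uncertainty=binary_entropy(mean_prob),
                         method="ensemble", n_samples=2)
    summary = uncertainty_error_summary(unc, target)
    assert summary["mean_uncertainty_errors"] > summary["mean_uncertainty_correct"]
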