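"""Dataset assembly: tensor layout, labels, determinism, splits."""

import numpy as np
import pytest

from hotspotmon import (
    AntennaArray,
    FrequencyGrid,
    ScatterData,
    build_input,
    build_label,
    load_dataset,
    save_dataset,
)
from hotspotmon.dataset import DatasetConfig, _split_indices
from hotspotmon.thermal import TemperatureField
from hotspotmon.geometry import GridSpec


def _sdata(data):
    freqs = FrequencyGrid(1e9, 2e9, data.shape[-1])
    return ScatterData(data, freqs, AntennaArray(data.shape[0], 0.04))


def test_input_layout_interleaves_real_imag_per_frequency(rng):
    hot = _sdata(rng.standard_normal((4, 4, 3)) + 1j * rng.standard_normal((4, 4, 3)))
    cold = _sdata(rng.standard_normal((4, 4, 3)) + 1j * rng.standard_normal((4, 4, 3)))
    tensor = build_input(hot, cold)
    assert tensor.shape == (4, 4, 6)
    diff = hot.data - cold.data
    for k in range(3):
        np.testing.assert_array_equal(tensor[..., 2 * k], diff[..., k].real)
        np.testing.assert_array_equal(tensor[..., 2 * k + 1], diff[..., k].imag)


def test_identical_hot_cold_gives_zero_tensor(rng):
    data = rng.standard_normal((4, 4, 2)) + 1j * rng.standard_normal((4, 4, 2))
    tensor = build_input(_sdata(data), _sdata(data.copy()))
    np.testing.assert_array_equal(tensor, 0.0)


def test_full_scale_geometry_tensor_shape(rng):
    data = rng.standard_normal((16, 16, 16)) + 1j * rng.standard_normal((16, 16, 16))
    freqs = FrequencyGrid(0.5e9, 2e9, 16)
    hot = ScatterData(data, freqs, AntennaArray(16, 0.075))
    cold = ScatterData(0.5 * data, freqs, AntennaArray(16, 0.075))
    assert build_input(hot, cold).shape == (16, 16, 32)


def test_label_threshold_is_strict():
    grid = GridSpec(4, 0.002)
    T = np.full((4, 4), 37.0)
    T[1, 2] = 41.0
    T[2, 2] = 40.0  # exactly at the threshold: not a hotspot
    label = build_label(TemperatureField(grid, T))
    assert label.sum() == 1
    assert label[1, 2] == 1 and label[2, 2] == 0


def test_all_baseline_temperatures_give_empty_label():
    grid = GridSpec(4, 0.002)
    label = build_label(TemperatureField(grid, np.full((4, 4), 37.0)))
    assert label.sum() == 0


def test_splits_disjoint_and_exhaustive():
    splits = _split_indices(50_000, (0.70, 0.15, 0.15), np.random.default_rng(0))
    assert len(splits["train"]) == 35_000
    assert len(splits["val"]) == 7_500
    assert len(splits["test"]) == 7_500
    merged = np.concatenate(list(splits.values()))
    assert len(np.unique(merged)) == 50_000


def test_generation_deterministic(fixture_cfg):
    from hotspotmon import run_generate

    a = run_generate(fixture_cfg)
    b = run_generate(fixture_cfg)
    np.testing.assert_array_equal(a.tensors, b.tensors)
    np.testing.assert_array_equal(a.labels, b.labels)
    for k in a.splits:
        np.testing.assert_array_equal(a.splits[k], b.splits[k])


def test_fixture_dataset_is_learnable(fixture_dataset):
    ds = fixture_dataset
    frac = ds.labels.mean()
    assert 0.0 < frac < 1.0
    # at least one scenario is danger-positive (hotspot outside the tumor)
    dangers = [
        bool(np.any((lab > 0) & ~ds.tumor_mask)) for lab in ds.labels
    ]
    assert any(dangers)


def test_dataset_container_round_trip(tmp_path, fixture_dataset):
    path = tmp_path / "ds.npz"
    save_dataset(path, fixture_dataset)
    loaded = load_dataset(path)
    np.testing.assert_array_equal(loaded.tensors, fixture_dataset.tensors)
    np.testing.assert_array_equal(loaded.labels, fixture_dataset.labels)
    np.testing.assert_array_equal(loaded.clean_cold, fixture_dataset.clean_cold)
    assert loaded.manifest["norm_factor"] == fixture_dataset.manifest["norm_factor"]


def test_renoised_inputs_match_training_distribution(fixture_dataset, rng):
    ds = fixture_dataset
    idx = ds.splits["test"][:4]
    x = ds.renoised_inputs(idx, ds.manifest["snr_train_db"], rng)
    assert x.shape == (4, ds.n_channels, *ds.tensors.shape[1:3])
    stored = ds.network_inputs(idx)
    # same scenarios, fresh noise: close in scale, not identical
    assert not np.allclose(x, stored)
    assert np.linalg.norm(x) == pytest.approx(np.linalg.norm(stored), rel=0.5)


def test_split_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        DatasetConfig(split_fractions=(0.75, 0.15, 0.15))
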