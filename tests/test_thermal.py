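"""Heating-scenario generator: profiles, bounds, smoothness, I/O."""

import numpy as np
import pytest

from hotspotmon import (
    HeatingRegion,
    ScenarioConfig,
    export_temperature_map,
    import_temperature_map,
    sample_scenario,
)
from hotspotmon.config import make_preset
from hotspotmon.phantom import build_phantom
from hotspotmon.thermal import layered_profile


@pytest.fixture(scope="module")
def small_phantom():
    return build_phantom(make_preset("fixture").phantom)[0]


def test_no_regions_gives_uniform_baseline(small_phantom, rng):
    cfg = ScenarioConfig(region_count_choices=(0,))
    field = sample_scenario(rng, small_phantom, cfg)
    np.testing.assert_array_equal(field.T, 37.0)


def test_temperature_rise_never_exceeds_bound(small_phantom):
    cfg = ScenarioConfig()
    for seed in range(50):
        field = sample_scenario(np.random.default_rng(seed), small_phantom, cfg)
        assert field.T.min() >= cfg.baseline_T - 1e-12
        assert (field.T - cfg.baseline_T).max() <= cfg.delta_T_max + 1e-9


def test_layered_profile_peak_and_extent(small_phantom):
    grid = small_phantom.grid
    region = HeatingRegion((0.004, 0.002), np.array([0.003, 0.006, 0.009]), np.array([10.0, 6.0, 2.0]))
    dT = layered_profile(grid, region)
    x, y = grid.cell_centers()
    r = np.hypot(x - 0.004, y - 0.002)
    assert dT[np.unravel_index(np.argmin(r), r.shape)] == pytest.approx(10.0)
    assert np.all(dT[r > 0.009] == 0.0)
    # piecewise values match the annulus the cell falls in
    assert np.all(dT[(r > 0.003) & (r <= 0.006)] == 6.0)


def test_single_region_radially_non_increasing_before_smoothing(small_phantom, rng):
    cfg = ScenarioConfig(region_count_choices=(1,), smoothing_sigma_cells=0.0,
                         tumor_heat_probability=1.0)
    field = sample_scenario(rng, small_phantom, cfg)
    region = field.regions[0]
    x, y = field.grid.cell_centers()
    r = np.hypot(x - region.center[0], y - region.center[1])
    order = np.argsort(r.ravel())
    dts = field.delta_T.ravel()[order]
    # along increasing radius the profile never increases
    assert np.all(np.diff(dts) <= 1e-12)


def test_smoothing_bounds_discrete_laplacian(small_phantom):
    cfg = ScenarioConfig(smoothing_sigma_cells=1.0)
    rough_cfg = ScenarioConfig(smoothing_sigma_cells=0.0)

    def max_laplacian(T):
        lap = T[1:-1, 2:] + T[1:-1, :-2] + T[2:, 1:-1] + T[:-2, 1:-1] - 4 * T[1:-1, 1:-1]
        return np.abs(lap).max()

    worst_smooth = max(
        max_laplacian(sample_scenario(np.random.default_rng(s), small_phantom, cfg).T)
        for s in range(20)
    )
    worst_rough = max(
        max_laplacian(sample_scenario(np.random.default_rng(s), small_phantom, rough_cfg).T)
        for s in range(20)
    )
    assert worst_smooth < worst_rough
    assert worst_smooth < 10.0  # °C per cell^2: smooth variation on the grid scale


def test_tumor_heating_frequency_matches_probability(small_phantom):
    cfg = ScenarioConfig(tumor_heat_probability=0.5)
    n = 1000
    heated = sum(
        sample_scenario(np.random.default_rng(s), small_phantom, cfg).tumor_heated
        for s in range(n)
    )
    sigma = np.sqrt(n * 0.5 * 0.5)
    assert abs(heated - 0.5 * n) < 3 * sigma


def test_scenario_reproducible_from_seed(small_phantom):
    a = sample_scenario(np.random.default_rng(42), small_phantom)
    b = sample_scenario(np.random.default_rng(42), small_phantom)
    np.testing.assert_array_equal(a.T, b.T)
    assert a.tumor_heated == b.tumor_heated


def test_temperature_map_round_trip(tmp_path, small_phantom, rng):
    field = sample_scenario(rng, small_phantom)
    path = tmp_path / "T.txt"
    export_temperature_map(path, field)
    loaded = import_temperature_map(path, field.grid)
    np.testing.assert_allclose(loaded.T, field.T, rtol=1e-7)


def test_constant_37_yields_no_hotspots(tmp_path, small_phantom):
    from hotspotmon import build_label

    path = tmp_path / "flat.txt"
    np.savetxt(path, np.full((24, 24), 37.0))
    field = import_temperature_map(path, small_phantom.grid)
    assert build_label(field).sum() == 0


def test_nearest_neighbor_resampling_matches_oracle(tmp_path, small_phantom):
    grid = small_phantom.grid  # 24 x 24
    src_n = 72  # 3x the target resolution; unique nearest neighbors
    rng = np.random.default_rng(0)
    src = 37.0 + 5.0 * rng.random((src_n, src_n))
    path = tmp_path / "hi.txt"
    np.savetxt(path, src)
    field = import_temperature_map(path, grid)

    # brute-force oracle: nearest source cell center per target cell center
    extent = grid.extent
    src_centers = -extent / 2 + extent / src_n * (np.arange(src_n) + 0.5)
    tgt_centers = -extent / 2 + extent / 24 * (np.arange(24) + 0.5)
    expected = np.empty((24, 24))
    for i in range(24):
        for j in range(24):
            si = np.argmin(np.abs(src_centers - tgt_centers[i]))
            sj = np.argmin(np.abs(src_centers - tgt_centers[j]))
            expected[i, j] = src[si, sj]
    np.testing.assert_array_equal(field.T, expected)


def test_import_rejects_invalid_maps(tmp_path, small_phantom):
    bad = tmp_path / "bad.txt"
    np.savetxt(bad, np.full((24, 24), 150.0))
    with pytest.raises(ValueError, match="0-100"):
        import_temperature_map(bad, small_phantom.grid)
    nan = tmp_path / "nan.txt"
    np.savetxt(nan, np.full((24, 24), np.nan))
    with pytest.raises(ValueError, match="non-finite"):
        import_temperature_map(nan, small_phantom.grid)
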