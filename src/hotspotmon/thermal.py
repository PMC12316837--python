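"""Random heating-scenario generator for hyperthermia monitoring.

Real treatment temperature maps would come from an electromagnetic-thermal
co-simulation or from solving the bioheat equation; training a detector needs
tens of thousands of scenarios, so instead we sample synthetic fields that
reproduce the qualitative behavior of published hyperthermia heating studies:

* smooth spatial variation,
* layered heating regions whose temperature decreases away from the center,
* a random number of simultaneous regions,
* a configurable probability that the tumor itself is (or is not) the
  heating focus, emulating focusing errors.

A scenario is built as concentric-annulus step profiles (one per region,
combined cell-wise by maximum so the peak stays bounded), then smoothed with
a Gaussian kernel and clamped to ``baseline + delta_T_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import GridSpec
from .phantom import TissueMap

__all__ = [
    "HeatingRegion",
    "TemperatureField",
    "ScenarioConfig",
    "sample_scenario",
    "layered_profile",
    "import_temperature_map",
    "export_temperature_map",
]


@dataclass(frozen=True)
class HeatingRegion:
    """One layered heating region: constant delta-T annuli around a center."""

    center: tuple[float, float]  # m
    layer_radii: np.ndarray  # outer radius of each layer, m, strictly increasing
    layer_delta_T: np.ndarray  # °C per layer, non-increasing outward

    def __post_init__(self) -> None:
        radii = np.asarray(self.layer_radii, dtype=float)
        dts = np.asarray(self.layer_delta_T, dtype=float)
        if radii.ndim != 1 or radii.size == 0 or radii.size != dts.size:
            raise ValueError("layer_radii and layer_delta_T must be 1-D, same length")
        if (radii <= 0).any() or (np.diff(radii) <= 0).any():
            raise ValueError("layer radii must be positive and strictly increasing")
        if (np.diff(dts) > 0).any():
            raise ValueError("layer delta-T must be non-increasing outward")
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "layer_delta_T", dts)

    @property
    def peak_delta_T(self) -> float:
        return float(self.layer_delta_T[0])


@dataclass(frozen=True)
class TemperatureField:
    """Per-cell temperature (°C) for one heating scenario."""

    grid: GridSpec
    T: np.ndarray  # (n, n) °C
    baseline_T: float = 37.0
    regions: tuple[HeatingRegion, ...] = ()
    tumor_heated: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T.shape != self.grid.shape:
            raise ValueError("temperature array shape does not match grid")
        if not np.isfinite(self.T).all():
            raise ValueError("non-finite temperatures")

    @property
    def delta_T(self) -> np.ndarray:
        return self.T - self.baseline_T


@dataclass(frozen=True)
class ScenarioConfig:
    """Sampling distributions for the heating-scenario generator.

    The behavior being emulated is only qualitatively constrained, so every
    distribution is exposed here.  Defaults: 1-3 regions (uniform), peak temperature rise
    uniform on [0, 24] °C, 2-5 layers of 2-6 mm width, tumor heated with
    probability 0.5, Gaussian smoothing of 1 cell.
    """

    region_count_choices: tuple[int, ...] = (1, 2, 3)
    peak_delta_T_range: tuple[float, float] = (0.0, 24.0)
    n_layers_range: tuple[int, int] = (2, 5)
    layer_width_range: tuple[float, float] = (0.002, 0.006)  # m
    tumor_heat_probability: float = 0.5
    smoothing_sigma_cells: float = 1.0
    delta_T_max: float = 24.0
    baseline_T: float = 37.0

    def __post_init__(self) -> None:
        if self.delta_T_max <= 0:
            raise ValueError("delta_T_max must be positive")
        if not 0.0 <= self.tumor_heat_probability <= 1.0:
            raise ValueError("tumor_heat_probability must be in [0, 1]")


def layered_profile(grid: GridSpec, region: HeatingRegion) -> np.ndarray:
    """Evaluate one region's piecewise-constant delta-T profile on the grid."""
    x, y = grid.cell_centers()
    r = np.hypot(x - region.center[0], y - region.center[1])
    # searchsorted maps distance to its annulus; beyond the last radius -> 0.
    idx = np.searchsorted(region.layer_radii, r, side="left")
    dts = np.append(region.layer_delta_T, 0.0)
    return dts[idx]


def sample_scenario(
    rng: np.random.Generator, tissue: TissueMap, config: ScenarioConfig | None = None
) -> TemperatureField:
    """Draw one random heating scenario on the phantom grid.

    Region centers are restricted to breast-interior cells (heating the
    coupling medium is meaningless); when the tumor is drawn as heated, the
    first region is centered on the tumor.
    """
    cfg = config or ScenarioConfig()
    grid = tissue.grid
    interior = np.argwhere(tissue.interior_mask)
    if interior.size == 0:
        raise ValueError("phantom has no breast-interior cells")

    n_regions = int(rng.choice(cfg.region_count_choices))
    tumor_heated = bool(rng.uniform() < cfg.tumor_heat_probability) and n_regions > 0

    x, y = grid.cell_centers()
    regions: list[HeatingRegion] = []
    for i in range(n_regions):
        if i == 0 and tumor_heated:
            center = tissue.tumor_center
        else:
            row, col = interior[rng.integers(len(interior))]
            center = (float(x[row, col]), float(y[row, col]))
        peak = float(rng.uniform(*cfg.peak_delta_T_range))
        n_layers = int(rng.integers(cfg.n_layers_range[0], cfg.n_layers_range[1] + 1))
        widths = rng.uniform(*cfg.layer_width_range, size=n_layers)
        radii = np.cumsum(widths)
        # Linear ramp from the peak to (almost) zero at the outermost layer.
        dts = peak * (1.0 - np.arange(n_layers) / n_layers)
        regions.append(HeatingRegion(center, radii, dts))

    dT = np.zeros(grid.shape)
    for region in regions:
        dT = np.maximum(dT, layered_profile(grid, region))
    if cfg.smoothing_sigma_cells > 0:
        dT = gaussian_filter(dT, sigma=cfg.smoothing_sigma_cells, mode="nearest")
    dT = np.clip(dT, 0.0, cfg.delta_T_max)

    return TemperatureField(
        grid,
        cfg.baseline_T + dT,
        baseline_T=cfg.baseline_T,
        regions=tuple(regions),
        tumor_heated=tumor_heated,
    )


# ---------------------------------------------------------------------------
# Import/export of externally computed temperature maps

def export_temperature_map(path, field: TemperatureField) -> None:
    """Write the temperature matrix as whitespace-delimited text (°C)."""
    np.savetxt(path, field.T, fmt="%.8g")


def import_temperature_map(
    path, grid: GridSpec, baseline_T: float = 37.0
) -> TemperatureField:
    """Load an externally computed temperature map (plain text matrix, °C).

    Emulates testing against a temperature field produced by an external
    electromagnetic-thermal simulator.  A square source matrix of different
    resolution is resampled onto ``grid`` by nearest neighbor (both grids are
    assumed to cover the same physical extent).
    """
    T = np.atleast_2d(np.loadtxt(path, dtype=float))
    if not np.isfinite(T).all():
        raise ValueError("temperature map contains non-finite entries")
    if (T < 0.0).any() or (T > 100.0).any():
        raise ValueError("temperatures outside the plausible 0-100 °C range")
    if T.shape[0] != T.shape[1]:
        raise ValueError("temperature map must be square")

    n = grid.n_cells_per_axis
    if T.shape[0] != n:
        src = T.shape[0]
        # Nearest source cell center for each target cell center.
        idx = np.clip(np.floor((np.arange(n) + 0.5) * src / n).astype(int), 0, src - 1)
        T = T[np.ix_(idx, idx)]
    return TemperatureField(grid, T, baseline_T=baseline_T)
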