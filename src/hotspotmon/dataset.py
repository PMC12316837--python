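"""Labeled dataset assembly for the hotspot detector.

Each sample couples one random heating scenario with the differential
multi-static measurement it produces:

* the forward problem is solved once for the cold breast per frequency and
  the cold fields are cached;
* per scenario, the hot dielectric map is solved, AWGN is applied to the
  hot and cold measurements independently, and the network input is the
  difference hot - cold with real and imaginary parts concatenated per
  frequency along the channel axis (n_ant x n_ant x 2*n_freq);
* the label is the binary image of cells whose temperature exceeds the
  40 °C danger threshold (strictly greater; exactly 40 °C is not a
  hotspot).

Clean (pre-noise) fields are retained so evaluation can re-noise the same
scenarios at any test SNR without re-solving the physics.  Input tensors
are optionally normalized by the global standard deviation of the training
split (differential fields are tiny; the factor is stored in the manifest
and applied consistently at evaluation time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .forward import MoMSolver, ScatterData
from .geometry import AntennaArray, FrequencyGrid
from .noise import NoiseSpec, add_awgn
from .phantom import DielectricMap, TissueMap
from .thermal import ScenarioConfig, TemperatureField, sample_scenario
from .thermo_dielectric import ThermoModel, heated_dielectric_map

__all__ = [
    "HOTSPOT_THRESHOLD_C",
    "DatasetConfig",
    "Dataset",
    "build_input",
    "build_label",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

HOTSPOT_THRESHOLD_C = 40.0


def build_input(hot: ScatterData, cold: ScatterData) -> np.ndarray:
    """Differential input tensor (n_rx, n_tx, 2*n_freq).

    Channel 2k holds the real part and channel 2k+1 the imaginary part of
    (hot - cold) at frequency k.
    """
    diff = (hot - cold).data
    n_rx, n_tx, n_freq = diff.shape
    out = np.empty((n_rx, n_tx, 2 * n_freq))
    out[..., 0::2] = diff.real
    out[..., 1::2] = diff.imag
    return out


def build_label(
    temperature: TemperatureField, threshold: float = HOTSPOT_THRESHOLD_C
) -> np.ndarray:
    """Binary hotspot image: 1 where T strictly exceeds the threshold."""
    return (temperature.T > threshold).astype(np.uint8)


@dataclass(frozen=True)
class DatasetConfig:
    n_scenarios: int = 50_000
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    snr_train_db: float = 40.0
    noise_scope: str = "per_frequency"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    thermo: ThermoModel = field(default_factory=ThermoModel)
    normalize: bool = True
    threshold_C: float = HOTSPOT_THRESHOLD_C
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scenarios < 1:
            raise ValueError("n_scenarios must be >= 1")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass
class Dataset:
    """In-memory dataset of differential tensors and hotspot labels."""

    tensors: np.ndarray  # (N, n_rx, n_tx, 2*n_freq) float32, normalized
    labels: np.ndarray  # (N, n, n) uint8
    temperatures: np.ndarray  # (N, n, n) float32, °C
    clean_hot: np.ndarray  # (N, n_rx, n_tx, n_freq) complex64
    clean_cold: np.ndarray  # (n_rx, n_tx, n_freq) complex128
    splits: dict[str, np.ndarray]
    tumor_mask: np.ndarray  # (n, n) bool
    norm_factor: float
    manifest: dict

    def __post_init__(self) -> None:
        counts = sum(len(v) for v in self.splits.values())
        if counts != len(self.tensors):
            raise ValueError("split sizes do not cover the dataset")
        all_idx = np.concatenate(list(self.splits.values()))
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("splits overlap")

    def __len__(self) -> int:
        return len(self.tensors)

    @property
    def n_channels(self) -> int:
        return self.tensors.shape[-1]

    @property
    def frequencies(self) -> FrequencyGrid:
        m = self.manifest
        return FrequencyGrid(m["f_min"], m["f_max"], m["n_frequencies"])

    @property
    def antennas(self) -> AntennaArray:
        m = self.manifest
        return AntennaArray(m["n_antennas"], m["antenna_radius"])

    def network_inputs(self, indices: np.ndarray) -> np.ndarray:
        """Tensors as NCHW batches for the network."""
        return np.moveaxis(self.tensors[indices], -1, 1)

    def renoised_inputs(
        self, indices: np.ndarray, snr_db: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Re-noise the stored clean fields at ``snr_db`` and rebuild tensors.

        Reproduces the measurement pipeline (independent AWGN on hot and
        cold, differencing, channel layout, normalization) at an arbitrary
        test SNR without re-solving the forward problem.
        """
        freqs, ant = self.frequencies, self.antennas
        spec = NoiseSpec(snr_db, self.manifest["noise_scope"])
        cold_clean = ScatterData(self.clean_cold, freqs, ant)
        out = np.empty(
            (len(indices), *self.tensors.shape[1:3], self.n_channels), dtype=np.float32
        )
        for j, i in enumerate(indices):
            hot = ScatterData(self.clean_hot[i].astype(complex), freqs, ant)
            noisy_hot = add_awgn(hot, spec, rng)
            noisy_cold = add_awgn(cold_clean, spec, rng)
            out[j] = build_input(noisy_hot, noisy_cold) / self.norm_factor
        return np.moveaxis(out, -1, 1)


def _split_indices(n: int, fractions, rng: np.random.Generator) -> dict[str, np.ndarray]:
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train : n_train + n_val]),
        "test": np.sort(order[n_train + n_val :]),
    }


def generate_dataset(
    tissue: TissueMap,
    cold_map: DielectricMap,
    config: DatasetConfig,
    antennas: AntennaArray | None = None,
    solver: MoMSolver | None = None,
    progress: bool = False,
) -> Dataset:
    """Run the full data-acquisition pipeline.

    Deterministic given ``config.seed``; the cold forward problem is solved
    once and reused for every scenario.
    """
    cfg = config
    ant = antennas or (solver.antennas if solver else AntennaArray())
    solver = solver or MoMSolver(cold_map.grid, ant, cold_map.frequencies)
    rng = np.random.default_rng(cfg.seed)

    cold_clean = solver.simulate(cold_map)
    spec = NoiseSpec(cfg.snr_train_db, cfg.noise_scope)

    n = cfg.n_scenarios
    n_ant, n_freq = ant.n_antennas, len(cold_map.frequencies)
    grid_n = cold_map.grid.n_cells_per_axis
    tensors = np.empty((n, n_ant, n_ant, 2 * n_freq), dtype=np.float32)
    labels = np.empty((n, grid_n, grid_n), dtype=np.uint8)
    temperatures = np.empty((n, grid_n, grid_n), dtype=np.float32)
    clean_hot = np.empty((n, n_ant, n_ant, n_freq), dtype=np.complex64)

    for i in range(n):
        scenario = sample_scenario(rng, tissue, cfg.scenario)
        hot_map = heated_dielectric_map(cold_map, scenario, cfg.thermo, tissue)
        hot_clean = solver.simulate(hot_map)
        clean_hot[i] = hot_clean.data
        noisy_hot = add_awgn(hot_clean, spec, rng)
        noisy_cold = add_awgn(cold_clean, spec, rng)
        tensors[i] = build_input(noisy_hot, noisy_cold)
        labels[i] = build_label(scenario, cfg.threshold_C)
        temperatures[i] = scenario.T
        if progress and (i + 1) % 200 == 0:
            print(f"  generated {i + 1}/{n} scenarios")

    splits = _split_indices(n, cfg.split_fractions, rng)
    if cfg.normalize:
        norm = float(tensors[splits["train"]].std())
        if norm == 0.0:
            norm = 1.0
    else:
        norm = 1.0
    tensors /= norm

    manifest = {
        "n_scenarios": n,
        "split_counts": {k: int(len(v)) for k, v in splits.items()},
        "snr_train_db": cfg.snr_train_db,
        "noise_scope": cfg.noise_scope,
        "seed": cfg.seed,
        "norm_factor": norm,
        "threshold_C": cfg.threshold_C,
        "n_antennas": ant.n_antennas,
        "antenna_radius": ant.radius,
        "f_min": cold_map.frequencies.f_min,
        "f_max": cold_map.frequencies.f_max,
        "n_frequencies": cold_map.frequencies.n_frequencies,
        "grid_n": grid_n,
        "cell_size": cold_map.grid.cell_size,
        "thermo_kind": cfg.thermo.kind,
        "thermo_degree": cfg.thermo.nonlinearity_degree,
    }
    return Dataset(
        tensors,
        labels,
        temperatures,
        clean_hot,
        cold_clean.data,
        splits,
        tissue.tumor_mask,
        norm,
        manifest,
    )


def save_dataset(path, ds: Dataset) -> None:
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(ds.manifest).encode(), dtype=np.uint8),
        tensors=ds.tensors,
        labels=ds.labels,
        temperatures=ds.temperatures,
        clean_hot=ds.clean_hot,
        clean_cold=ds.clean_cold,
        tumor_mask=ds.tumor_mask,
        **{f"split_{k}": v for k, v in ds.splits.items()},
    )


def load_dataset(path) -> Dataset:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["meta"]).decode())
        splits = {
            k[len("split_") :]: data[k] for k in data.files if k.startswith("split_")
        }
        return Dataset(
            data["tensors"],
            data["labels"],
            data["temperatures"],
            data["clean_hot"],
            data["clean_cold"],
            splits,
            data["tumor_mask"].astype(bool),
            manifest["norm_factor"],
            manifest,
        )
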