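"""Scale presets and run configuration.

Three presets resolve every module default:

* ``full`` — the full-scale conditions: 50x50 grid (2 mm cells), 16
  antennas on a 75 mm circle, 16 frequencies 0.5-2 GHz, 50,000 scenarios,
  40 epochs.  Multi-day on one CPU; provided for completeness.
* ``desk`` — a scaled-down end-to-end configuration that preserves every
  pipeline stage: 24x24 grid, 4 antennas, 4 frequencies, 2,000 scenarios,
  15 epochs.  Runs on one CPU in tens of minutes.
* ``fixture`` — a seconds-scale configuration for tests and examples.

All randomness derives from the single ``seed``; the configuration hash is
embedded in generated artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

from .dataset import DatasetConfig
from .geometry import AntennaArray, FrequencyGrid, GridSpec
from .phantom import PhantomConfig
from .thermal import ScenarioConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "make_preset", "PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    preset: str
    seed: int
    phantom: PhantomConfig
    antennas: AntennaArray
    dataset: DatasetConfig
    train: TrainConfig
    arch_width: int
    alpha_dec: float = 0.5

    @property
    def grid(self) -> GridSpec:
        return self.phantom.grid

    @property
    def frequencies(self) -> FrequencyGrid:
        return self.phantom.frequencies

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items() if not k.startswith("_")}
            if hasattr(o, "tolist"):
                return o.tolist()
            return str(o)

        payload = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _full(seed: int) -> RunConfig:
    phantom = PhantomConfig(seed=seed)
    return RunConfig(
        preset="full",
        seed=seed,
        phantom=phantom,
        antennas=AntennaArray(16, 0.075),
        dataset=DatasetConfig(n_scenarios=50_000, seed=seed),
        train=TrainConfig(epochs=40, seed=seed),
        arch_width=64,
    )


def _desk(seed: int) -> RunConfig:
    grid = GridSpec(24, 0.002)
    freqs = FrequencyGrid(0.5e9, 2.0e9, 4)
    phantom = PhantomConfig(
        grid=grid,
        frequencies=freqs,
        breast_radius=0.020,
        skin_thickness=0.002,
        tumor_center=(0.008, 0.0),
        tumor_radius=0.004,
        n_fibro_blobs=4,
        fibro_blob_radius=0.005,
        seed=seed,
    )
    scenario = ScenarioConfig(
        n_layers_range=(2, 4),
        layer_width_range=(0.0015, 0.004),
    )
    return RunConfig(
        preset="desk",
        seed=seed,
        phantom=phantom,
        antennas=AntennaArray(4, 0.040),
        dataset=DatasetConfig(n_scenarios=2_000, scenario=scenario, seed=seed),
        train=TrainConfig(epochs=15, seed=seed),
        arch_width=24,
    )


def _fixture(seed: int) -> RunConfig:
    desk = _desk(seed)
    phantom = replace(
        desk.phantom, frequencies=FrequencyGrid(1.0e9, 2.0e9, 2), n_fibro_blobs=2
    )
    return replace(
        desk,
        preset="fixture",
        phantom=phantom,
        dataset=replace(desk.dataset, n_scenarios=50, seed=seed),
        train=replace(desk.train, epochs=3),
        arch_width=4,
    )


PRESETS = {"full": _full, "desk": _desk, "fixture": _fixture}


def make_preset(name: str, seed: int = 0, **overrides) -> RunConfig:
    """Resolve a named preset; keyword overrides replace RunConfig fields."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name](seed)
    return replace(cfg, **overrides) if overrides else cfg


def _apply_nested(obj, overrides: dict):
    """Recursively replace dataclass fields from a plain dict."""
    import dataclasses

    kwargs = {}
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown config field {key!r} for {type(obj).__name__}")
        current = getattr(obj, key)
        if isinstance(value, dict) and dataclasses.is_dataclass(current):
            kwargs[key] = _apply_nested(current, value)
        else:
            kwargs[key] = value
    return replace(obj, **kwargs)


def load_config(path, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file of overrides.

    The file names a ``preset`` (default "desk") and may override any nested
    field, e.g.::

        preset: desk
        arch_width: 16
        dataset: {n_scenarios: 500, snr_train_db: 30}
        train: {epochs: 5}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    preset = raw.pop("preset", "desk")
    cfg = make_preset(preset, seed=raw.pop("seed", 0) if seed is None else seed)
    return _apply_nested(cfg, raw)
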