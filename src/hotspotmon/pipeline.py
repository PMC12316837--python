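"""End-to-end orchestration of the monitoring pipeline.

Thin glue binding the modules together for scripts, the CLI and the
examples: phantom -> scenario generator -> forward solver -> dataset ->
detector training -> evaluation, plus the Born-iterative comparison on the
same test scenarios.
"""

from __future__ import annotations

import numpy as np

from .bim import InverseConfig, bim_invert
from .config import RunConfig
from .dataset import Dataset, generate_dataset
from .forward import MoMSolver, ScatterData
from .hotspot_net import Network, build_model, default_architecture
from .metrics import MetricsReport, evaluate_images
from .phantom import DielectricMap, TissueMap, build_phantom
from .trainer import TrainHistory, train

__all__ = [
    "build_pipeline",
    "run_generate",
    "make_network",
    "run_train",
    "run_baseline",
    "sweep_nonlinearity",
    "REGULARIZERS",
]

REGULARIZERS = ("tr", "tsvd", "cgls", "fista")


def build_pipeline(cfg: RunConfig) -> tuple[TissueMap, DielectricMap, MoMSolver]:
    tissue, cold_map = build_phantom(cfg.phantom)
    solver = MoMSolver(cfg.grid, cfg.antennas, cfg.frequencies)
    return tissue, cold_map, solver


def run_generate(cfg: RunConfig, progress: bool = False) -> Dataset:
    tissue, cold_map, solver = build_pipeline(cfg)
    ds = generate_dataset(tissue, cold_map, cfg.dataset, solver=solver, progress=progress)
    ds.manifest["config_hash"] = cfg.config_hash()
    ds.manifest["preset"] = cfg.preset
    return ds


def make_network(cfg: RunConfig, seed: int | None = None) -> Network:
    spec = default_architecture(
        in_channels=2 * cfg.frequencies.n_frequencies,
        in_size=cfg.antennas.n_antennas,
        out_size=cfg.grid.n_cells_per_axis,
        width=cfg.arch_width,
    )
    return build_model(spec, seed=cfg.seed if seed is None else seed)


def run_train(
    cfg: RunConfig, dataset: Dataset, verbose: bool = False
) -> tuple[Network, TrainHistory]:
    model = make_network(cfg)
    history = train(model, dataset, cfg.train, verbose=verbose)
    return model, history


def run_baseline(
    cfg: RunConfig,
    dataset: Dataset,
    indices: np.ndarray,
    regularizers=REGULARIZERS,
    inverse: InverseConfig | None = None,
    rng: np.random.Generator | None = None,
    snr_db: float | None = None,
) -> dict[str, MetricsReport]:
    """Born-iterative inversion of ``indices`` test scenarios, per regularizer.

    The differential data are rebuilt from the stored clean fields with
    fresh noise at ``snr_db`` (default: the dataset's training SNR), exactly
    as a measurement would be, then inverted and scored against the true
    hotspot images.
    """
    tissue, cold_map, solver = build_pipeline(cfg)
    rng = rng or np.random.default_rng(cfg.seed)
    snr = dataset.manifest["snr_train_db"] if snr_db is None else snr_db

    from .noise import NoiseSpec, add_awgn

    spec = NoiseSpec(snr, dataset.manifest["noise_scope"])
    freqs, ant = dataset.frequencies, dataset.antennas
    cold_clean = ScatterData(dataset.clean_cold, freqs, ant)

    diffs = []
    for i in indices:
        hot = ScatterData(dataset.clean_hot[i].astype(complex), freqs, ant)
        diffs.append(add_awgn(hot, spec, rng) - add_awgn(cold_clean, spec, rng))

    from dataclasses import replace

    noise_norm = _expected_noise_norm(dataset, snr)
    reports: dict[str, MetricsReport] = {}
    for reg in regularizers:
        icfg = replace(
            inverse or InverseConfig(), regularizer=reg, noise_norm=noise_norm
        )
        preds = np.stack(
            [bim_invert(d, cold_map, tissue, icfg, solver).hotspots for d in diffs]
        )
        truths = dataset.labels[indices] > 0
        reports[reg] = evaluate_images(preds, truths, dataset.tumor_mask)
    return reports


def sweep_nonlinearity(
    cfg: RunConfig,
    dataset: Dataset,
    model: Network,
    degrees,
    n_scenarios: int = 20,
    snr_db: float | None = None,
    alpha_dec: float = 0.5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Model-mismatch study: a linearly trained detector on nonlinear truth.

    For each nonlinearity degree ``a`` the stored test-scenario temperature
    fields are re-coupled to the dielectric maps through the quadratic
    thermo-dielectric law, the forward problem is re-solved, fresh noise is
    applied, and the linear-trained ``model`` is scored.  Degree 0 is the
    linear model itself and reproduces the ordinary evaluation exactly for
    the same seed.
    """
    from .dataset import build_input
    from .noise import NoiseSpec, add_awgn
    from .thermal import TemperatureField
    from .thermo_dielectric import ThermoModel, heated_dielectric_map
    from .trainer import _forward_batched

    tissue, cold_map, solver = build_pipeline(cfg)
    snr = dataset.manifest["snr_train_db"] if snr_db is None else snr_db
    spec = NoiseSpec(snr, dataset.manifest["noise_scope"])
    idx = dataset.splits["test"][:n_scenarios]
    cold_clean = solver.simulate(cold_map)

    rows = {"degree": [], "mean_accuracy": [], "mean_dice": []}
    for a in degrees:
        thermo = ThermoModel() if a == 0 else ThermoModel(kind="quadratic", nonlinearity_degree=float(a))
        rng = np.random.default_rng(seed)
        tensors = []
        for i in idx:
            field = TemperatureField(cold_map.grid, dataset.temperatures[i].astype(float))
            hot_map = heated_dielectric_map(cold_map, field, thermo, tissue)
            hot_clean = solver.simulate(hot_map)
            noisy_hot = add_awgn(hot_clean, spec, rng)
            noisy_cold = add_awgn(cold_clean, spec, rng)
            tensors.append(build_input(noisy_hot, noisy_cold) / dataset.norm_factor)
        x = np.moveaxis(np.stack(tensors).astype(np.float32), -1, 1)
        probs = _forward_batched(model, x)
        report = evaluate_images(probs > alpha_dec, dataset.labels[idx] > 0, dataset.tumor_mask)
        rows["degree"].append(float(a))
        rows["mean_accuracy"].append(report.mean_accuracy)
        rows["mean_dice"].append(np.nan if report.mean_dice is None else report.mean_dice)
    return {k: np.asarray(v) for k, v in rows.items()}


def _expected_noise_norm(dataset: Dataset, snr_db: float) -> float:
    """Expected noise norm of a differential measurement.

    Hot and cold are noised independently at the same SNR against nearly
    identical signal powers, so the differential noise power is twice the
    single-measurement noise power.
    """
    if np.isinf(snr_db):
        return 0.0
    p_cold = np.mean(np.abs(dataset.clean_cold) ** 2, axis=(0, 1))
    per_entry = 2.0 * p_cold * 10.0 ** (-snr_db / 10.0)
    n_entries = dataset.clean_cold.shape[0] * dataset.clean_cold.shape[1]
    return float(np.sqrt(np.sum(per_entry) * n_entries))
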