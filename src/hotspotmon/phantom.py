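"""Synthetic 2-D breast phantom and its frequency-dependent dielectric maps.

The phantom is parametric: a skin ring around a circular breast region,
adipose (fat) bulk, smooth random fibroglandular blobs, and a circular tumor
inclusion (default radius 7.5 mm at (20, 0) mm).  It stands in for a
patient-specific MRI-derived model: per-class dielectric properties are
single-pole Debye fits of literature magnitude and are configurable; they are
substitutes, not measured breast data.

Complex relative permittivity follows the e^{-j omega t} convention:
eps_c = eps_r + j * sigma / (omega * eps_0), so the loss term has a
non-negative imaginary part for passive media.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import FrequencyGrid, GridSpec

__all__ = [
    "EPS0",
    "TissueClass",
    "DebyeParams",
    "PhantomConfig",
    "TissueMap",
    "DielectricMap",
    "build_phantom",
    "dp_at_frequency",
    "complex_permittivity",
    "save_phantom",
    "load_phantom",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class TissueClass:
    """Integer labels for the tissue-class grid."""

    BACKGROUND = 0  # coupling medium
    SKIN = 1
    FAT = 2
    FIBROGLANDULAR = 3
    TUMOR = 4

    NAMES = {0: "background", 1: "skin", 2: "fat", 3: "fibroglandular", 4: "tumor"}


@dataclass(frozen=True)
class DebyeParams:
    """Single-pole Debye dispersion: eps_c(w) = eps_inf + d_eps/(1 - j w tau) + j sigma_s/(w eps_0).

    With the e^{-jwt} convention the real part (eps_r) is non-increasing in
    frequency and the effective conductivity sigma = w eps_0 Im(eps_c) is
    non-decreasing, as expected of biological tissue over 0.5-2 GHz.
    """

    eps_inf: float
    d_eps: float
    tau: float  # relaxation time, s
    sigma_s: float  # static ionic conductivity, S/m

    def evaluate(self, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (eps_r, sigma) at angular frequencies ``omega``."""
        omega = np.asarray(omega, dtype=float)
        denom = 1.0 + (omega * self.tau) ** 2
        eps_r = self.eps_inf + self.d_eps / denom
        sigma = self.sigma_s + EPS0 * self.d_eps * self.tau * omega ** 2 / denom
        return eps_r, sigma


#: Literature-magnitude substitute parameters per tissue class (the study's
#: MRI-derived values are not public).  Background (coupling medium) is
#: non-dispersive by construction: eps_r = 20, sigma = 0.6 S/m.
DEFAULT_DEBYE: dict[int, DebyeParams] = {
    TissueClass.BACKGROUND: DebyeParams(eps_inf=20.0, d_eps=0.0, tau=0.0, sigma_s=0.6),
    TissueClass.SKIN: DebyeParams(eps_inf=16.0, d_eps=23.0, tau=13.0e-12, sigma_s=0.50),
    TissueClass.FAT: DebyeParams(eps_inf=3.0, d_eps=2.5, tau=13.0e-12, sigma_s=0.05),
    TissueClass.FIBROGLANDULAR: DebyeParams(eps_inf=14.0, d_eps=36.0, tau=13.0e-12, sigma_s=0.60),
    TissueClass.TUMOR: DebyeParams(eps_inf=18.0, d_eps=39.0, tau=13.0e-12, sigma_s=0.80),
}


@dataclass(frozen=True)
class PhantomConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    frequencies: FrequencyGrid = field(default_factory=FrequencyGrid)
    breast_radius: float = 0.045
    skin_thickness: float = 0.002
    tumor_center: tuple[float, float] = (0.020, 0.0)
    tumor_radius: float = 0.0075
    n_fibro_blobs: int = 6
    fibro_blob_radius: float = 0.008
    seed: int = 0
    #: "debye" uses per-class dispersion; "constant" evaluates each class's
    #: Debye model at the grid's center frequency and holds it flat (handy in
    #: tests where frequency-flat maps simplify oracles).
    dispersion: str = "debye"
    debye: dict[int, DebyeParams] = field(default_factory=lambda: dict(DEFAULT_DEBYE))


@dataclass(frozen=True)
class TissueMap:
    """Per-cell tissue-class labels plus the tumor geometry."""

    grid: GridSpec
    class_id: np.ndarray  # (n, n) int
    tumor_center: tuple[float, float]
    tumor_radius: float

    def __post_init__(self) -> None:
        if self.class_id.shape != self.grid.shape:
            raise ValueError("class_id shape does not match grid")

    def mask(self, tissue_class: int) -> np.ndarray:
        return self.class_id == tissue_class

    @property
    def interior_mask(self) -> np.ndarray:
        """Cells inside the breast (everything that is not coupling medium)."""
        return self.class_id != TissueClass.BACKGROUND

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.class_id == TissueClass.TUMOR


@dataclass(frozen=True)
class DielectricMap:
    """Per-cell, per-frequency relative permittivity and conductivity.

    ``eps_r`` and ``sigma`` have shape (n, n, n_freq); the background
    (coupling-medium) values are scalars because the matching liquid is
    non-dispersive here.
    """

    grid: GridSpec
    frequencies: FrequencyGrid
    eps_r: np.ndarray
    sigma: np.ndarray
    eps_rb: float = 20.0
    sigma_b: float = 0.6

    def __post_init__(self) -> None:
        expected = (*self.grid.shape, len(self.frequencies))
        if self.eps_r.shape != expected or self.sigma.shape != expected:
            raise ValueError(
                f"eps_r/sigma must have shape {expected}, got "
                f"{self.eps_r.shape} and {self.sigma.shape}"
            )
        if not (np.isfinite(self.eps_r).all() and np.isfinite(self.sigma).all()):
            raise ValueError("non-finite dielectric values")
        if (self.eps_r < 1.0).any():
            raise ValueError("relative permittivity below 1")
        if (self.sigma < 0.0).any():
            raise ValueError("negative conductivity")

    def with_values(self, eps_r: np.ndarray, sigma: np.ndarray) -> "DielectricMap":
        return replace(self, eps_r=eps_r, sigma=sigma)


def complex_permittivity(eps_r: np.ndarray, sigma: np.ndarray, f: float) -> np.ndarray:
    """eps_c = eps_r + j sigma/(omega eps_0) for the e^{-jwt} convention."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    return np.asarray(eps_r) + 1j * np.asarray(sigma) / (omega * EPS0)


def dp_at_frequency(dmap: DielectricMap, f: float) -> np.ndarray:
    """Complex relative permittivity grid of ``dmap`` at grid frequency ``f``."""
    k = dmap.frequencies.index_of(f)
    return complex_permittivity(dmap.eps_r[..., k], dmap.sigma[..., k], f)


def contrast(dmap: DielectricMap, f: float) -> np.ndarray:
    """Contrast chi = eps_c - eps_cb against the coupling medium at ``f``."""
    eps_cb = complex_permittivity(dmap.eps_rb, dmap.sigma_b, f)
    return dp_at_frequency(dmap, f) - eps_cb


def _disc_mask(grid: GridSpec, center: tuple[float, float], radius: float) -> np.ndarray:
    x, y = grid.cell_centers()
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2


def build_phantom(config: PhantomConfig | None = None) -> tuple[TissueMap, DielectricMap]:
    """Build the parametric breast phantom and its cold dielectric maps.

    Deterministic given the config (fibroglandular blob placement is driven
    by ``config.seed``).  Raises if the tumor disc extends outside the breast
    interior.
    """
    cfg = config or PhantomConfig()
    grid, freqs = cfg.grid, cfg.frequencies
    rng = np.random.default_rng(cfg.seed)

    cx, cy = cfg.tumor_center
    if np.hypot(cx, cy) + cfg.tumor_radius > cfg.breast_radius - cfg.skin_thickness:
        raise ValueError(
            "tumor disc extends outside the breast interior: "
            f"center {cfg.tumor_center}, radius {cfg.tumor_radius}"
        )

    class_id = np.full(grid.shape, TissueClass.BACKGROUND, dtype=np.int64)
    breast = _disc_mask(grid, (0.0, 0.0), cfg.breast_radius)
    inner = _disc_mask(grid, (0.0, 0.0), cfg.breast_radius - cfg.skin_thickness)
    class_id[breast] = TissueClass.SKIN
    class_id[inner] = TissueClass.FAT

    # Smooth fibroglandular blobs inside the fat bulk, away from the skin.
    blob_zone = cfg.breast_radius - cfg.skin_thickness - cfg.fibro_blob_radius
    for _ in range(cfg.n_fibro_blobs):
        r = blob_zone * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        radius = cfg.fibro_blob_radius * rng.uniform(0.5, 1.0)
        blob = _disc_mask(grid, (r * np.cos(phi), r * np.sin(phi)), radius)
        class_id[blob & inner] = TissueClass.FIBROGLANDULAR

    if cfg.tumor_radius > 0:
        tumor = _disc_mask(grid, cfg.tumor_center, cfg.tumor_radius)
        class_id[tumor] = TissueClass.TUMOR

    tmap = TissueMap(grid, class_id, cfg.tumor_center, cfg.tumor_radius)
    dmap = _dielectric_from_classes(tmap, freqs, cfg)
    return tmap, dmap


def _dielectric_from_classes(
    tmap: TissueMap, freqs: FrequencyGrid, cfg: PhantomConfig
) -> DielectricMap:
    omega = freqs.angular_frequencies
    if cfg.dispersion == "constant":
        omega_eval = np.full_like(omega, 2.0 * np.pi * float(np.mean(freqs.frequencies)))
    elif cfg.dispersion == "debye":
        omega_eval = omega
    else:
        raise ValueError(f"unknown dispersion mode {cfg.dispersion!r}")

    n = tmap.grid.n_cells_per_axis
    eps_r = np.empty((n, n, len(freqs)))
    sigma = np.empty((n, n, len(freqs)))
    bg = cfg.debye[TissueClass.BACKGROUND]
    for cls in np.unique(tmap.class_id):
        if cls not in cfg.debye:
            raise ValueError(f"no dielectric parameters for tissue class {cls}")
        er, sg = cfg.debye[cls].evaluate(omega_eval)
        m = tmap.class_id == cls
        eps_r[m] = er
        sigma[m] = sg
    return DielectricMap(
        tmap.grid, freqs, eps_r, sigma, eps_rb=bg.eps_inf, sigma_b=bg.sigma_s
    )


# ---------------------------------------------------------------------------
# Container I/O (NPZ payload + JSON-encoded metadata)

_FORMAT = "hotspotmon-phantom-v1"


def save_phantom(path, tmap: TissueMap, dmap: DielectricMap) -> None:
    meta = {
        "format": _FORMAT,
        "n_cells_per_axis": tmap.grid.n_cells_per_axis,
        "cell_size": tmap.grid.cell_size,
        "f_min": dmap.frequencies.f_min,
        "f_max": dmap.frequencies.f_max,
        "n_frequencies": dmap.frequencies.n_frequencies,
        "tumor_center": list(tmap.tumor_center),
        "tumor_radius": tmap.tumor_radius,
        "eps_rb": dmap.eps_rb,
        "sigma_b": dmap.sigma_b,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        class_id=tmap.class_id,
        eps_r=dmap.eps_r,
        sigma=dmap.sigma,
    )


def load_phantom(path) -> tuple[TissueMap, DielectricMap]:
    """Load a phantom container; validates invariants on load.

    The grid need not be 50x50 — downstream label grids follow the phantom
    grid, which is how user-supplied (e.g. MRI-derived) models plug in.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != _FORMAT:
            raise ValueError(f"not a phantom container: {path}")
        grid = GridSpec(meta["n_cells_per_axis"], meta["cell_size"])
        freqs = FrequencyGrid(meta["f_min"], meta["f_max"], meta["n_frequencies"])
        tmap = TissueMap(
            grid,
            data["class_id"].astype(np.int64),
            tuple(meta["tumor_center"]),
            meta["tumor_radius"],
        )
        dmap = DielectricMap(
            grid,
            freqs,
            data["eps_r"].astype(float),
            data["sigma"].astype(float),
            eps_rb=meta["eps_rb"],
            sigma_b=meta["sigma_b"],
        )
    return tmap, dmap
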