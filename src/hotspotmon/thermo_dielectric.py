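"""Temperature dependence of tissue dielectric properties.

Around hyperthermia temperatures the relative permittivity of tissue drops
by about 0.25% per °C while the effective conductivity rises by about 1.25%
per °C, both proportionally to the reference (cold) values:

    d_eps_r = -eps_r * (0.0025 * dT)
    d_sigma = +sigma * (0.0125 * dT)

The coefficients are global (not tissue-specific) and frequency-independent;
frequency enters only through the reference properties.  A quadratic variant
models mild nonlinearity of the true tissue response: an effective
temperature rise

    dT_eff = (1 - a) * dT + a * dT^2 / dT_max

is substituted into the linear law, with degree ``a`` in [0, 1].  By
construction the quadratic family agrees with the linear law at dT = 0 and
at dT = dT_max (24 °C), the range covered by the scenario generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import DielectricMap, TissueMap
from .thermal import TemperatureField

__all__ = [
    "ALPHA_EPS",
    "ALPHA_SIGMA",
    "ThermoModel",
    "delta_dp",
    "heated_dielectric_map",
    "temperature_from_dp",
]

ALPHA_EPS = 0.0025  # fractional permittivity decrease per °C
ALPHA_SIGMA = 0.0125  # fractional conductivity increase per °C


@dataclass(frozen=True)
class ThermoModel:
    kind: str = "linear"  # "linear" | "quadratic"
    alpha_eps: float = ALPHA_EPS
    alpha_sigma: float = ALPHA_SIGMA
    nonlinearity_degree: float = 0.0  # a in [0, 1]; 0 reproduces the linear law
    delta_T_max: float = 24.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "quadratic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.nonlinearity_degree <= 1.0:
            raise ValueError("nonlinearity_degree must be in [0, 1]")
        if self.kind == "linear" and self.nonlinearity_degree != 0.0:
            raise ValueError("linear model requires nonlinearity_degree == 0")

    def effective_delta_T(self, dT: np.ndarray) -> np.ndarray:
        dT = np.asarray(dT, dtype=float)
        if self.kind == "linear":
            return dT
        a = self.nonlinearity_degree
        return (1.0 - a) * dT + a * dT ** 2 / self.delta_T_max


def _clamped(dT, lo, hi):
    dT = np.asarray(dT, dtype=float)
    if (dT < lo).any() or (dT > hi).any():
        warnings.warn(
            f"delta-T outside [{lo}, {hi}] °C clamped before dielectric update",
            stacklevel=3,
        )
        dT = np.clip(dT, lo, hi)
    return dT


def delta_dp(model: ThermoModel, eps_r, sigma, delta_T):
    """Dielectric-property changes for a temperature rise ``delta_T`` (°C).

    Returns ``(d_eps_r, d_sigma)`` with the same shape as the inputs.
    Temperature rises outside [0, delta_T_max] are clamped with a warning.
    """
    eps_r = np.asarray(eps_r, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (eps_r < 0).any() or (sigma < 0).any():
        raise ValueError("reference dielectric properties must be non-negative")
    dT_eff = model.effective_delta_T(_clamped(delta_T, 0.0, model.delta_T_max))
    d_eps = -eps_r * (model.alpha_eps * dT_eff)
    d_sigma = sigma * (model.alpha_sigma * dT_eff)
    return d_eps, d_sigma


def heated_dielectric_map(
    cold: DielectricMap,
    field: TemperatureField,
    model: ThermoModel | None = None,
    tissue: TissueMap | None = None,
) -> DielectricMap:
    """Hot-state dielectric map for one heating scenario.

    The temperature rise is applied per cell at every frequency.  Cells of
    the coupling medium are never modified; if ``tissue`` is omitted, the
    background is identified as cells matching the background properties at
    every frequency.
    """
    model = model or ThermoModel()
    if field.grid.shape != cold.grid.shape:
        raise ValueError("temperature and dielectric grids do not match")
    if tissue is not None:
        tissue_mask = tissue.interior_mask
    else:
        tissue_mask = ~(
            np.all(cold.eps_r == cold.eps_rb, axis=-1)
            & np.all(cold.sigma == cold.sigma_b, axis=-1)
        )
    dT = np.where(tissue_mask, field.delta_T, 0.0)[..., None]
    d_eps, d_sigma = delta_dp(model, cold.eps_r, cold.sigma, np.broadcast_to(dT, cold.eps_r.shape))
    return cold.with_values(cold.eps_r + d_eps, cold.sigma + d_sigma)


def temperature_from_dp(
    delta: np.ndarray,
    reference: np.ndarray,
    model: ThermoModel | None = None,
    channel: str = "sigma",
    min_reference: float = 1e-6,
):
    """Invert the linear law: temperature rise from a dielectric change.

    Parameters
    ----------
    delta, reference:
        Observed property change and the cold reference values (same shape);
        the permittivity channel uses ``d_eps_r``/``eps_r``, the conductivity
        channel ``d_sigma``/``sigma``.
    channel:
        "sigma" (default; the stronger effect, +1.25%/°C) or "eps".
    min_reference:
        Cells whose |reference| falls below this are flagged invalid rather
        than divided through.

    Returns
    -------
    (delta_T, valid):
        Temperature-rise estimate (0 where invalid) and a boolean validity
        mask.
    """
    model = model or ThermoModel()
    if model.kind != "linear":
        raise ValueError("only the linear model is invertible in closed form")
    delta = np.asarray(delta, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if delta.shape != reference.shape:
        raise ValueError("delta and reference shapes differ")
    valid = np.abs(reference) > min_reference
    safe_ref = np.where(valid, reference, 1.0)
    if channel == "sigma":
        dT = delta / (model.alpha_sigma * safe_ref)
    elif channel == "eps":
        dT = -delta / (model.alpha_eps * safe_ref)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return np.where(valid, dT, 0.0), valid
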