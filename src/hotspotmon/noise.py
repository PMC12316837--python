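"""Additive white Gaussian noise on scattered-field arrays.

Measurement noise is modeled as circularly symmetric complex Gaussian noise
at a prescribed signal-to-noise ratio SNR = 10 log10(P_signal / P_noise),
where the powers are mean squared magnitudes.  Hot and cold measurements are
noised independently (they are separate acquisitions).  The default scope
computes the signal power per frequency, since the scattered power varies
strongly over 0.5-2 GHz; a global scope is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ScatterData

__all__ = ["NoiseSpec", "add_awgn", "measure_snr"]


@dataclass(frozen=True)
class NoiseSpec:
    snr_db: float = 40.0  # np.inf leaves the data untouched
    scope: str = "per_frequency"  # or "global"

    def __post_init__(self) -> None:
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")
        if self.scope not in ("per_frequency", "global"):
            raise ValueError(f"unknown noise scope {self.scope!r}")


def _signal_power(data: np.ndarray, scope: str) -> np.ndarray:
    if scope == "global":
        return np.full(data.shape[-1], np.mean(np.abs(data) ** 2))
    return np.mean(np.abs(data) ** 2, axis=(0, 1))


def add_awgn(
    sdata: ScatterData, spec: NoiseSpec, rng: np.random.Generator
) -> ScatterData:
    """Return a noisy copy of ``sdata`` at the specified SNR.

    Noise power is split equally between the real and imaginary parts.
    ``snr_db = inf`` is the noiseless sentinel.  Zero signal power in any
    scope makes the SNR undefined and raises.
    """
    if np.isinf(spec.snr_db) and spec.snr_db > 0:
        return sdata
    power = _signal_power(sdata.data, spec.scope)
    if np.any(power == 0.0):
        raise ValueError("zero signal power in scope: SNR is undefined")
    noise_power = power * 10.0 ** (-spec.snr_db / 10.0)
    std = np.sqrt(noise_power / 2.0)
    shape = sdata.data.shape
    noise = std[None, None, :] * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    return ScatterData(sdata.data + noise, sdata.frequencies, sdata.antennas)


def measure_snr(clean: ScatterData, noisy: ScatterData, scope: str = "per_frequency") -> np.ndarray:
    """Empirical SNR (dB) of ``noisy`` against ``clean``, per scope.

    Returns one value per frequency (or a single-element array for the
    global scope); identical arrays give the +inf sentinel.
    """
    if clean.data.shape != noisy.data.shape:
        raise ValueError("shape mismatch between clean and noisy data")
    diff = noisy.data - clean.data
    if scope == "global":
        ps = np.array([np.mean(np.abs(clean.data) ** 2)])
        pn = np.array([np.mean(np.abs(diff) ** 2)])
    elif scope == "per_frequency":
        ps = np.mean(np.abs(clean.data) ** 2, axis=(0, 1))
        pn = np.mean(np.abs(diff) ** 2, axis=(0, 1))
    else:
        raise ValueError(f"unknown noise scope {scope!r}")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(ps / pn)
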