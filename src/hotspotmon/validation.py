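"""Closed-form electromagnetic references for solver validation.

The only 2-D TM scattering geometry with a convenient exact solution is a
homogeneous circular cylinder in a homogeneous (possibly lossy) background,
illuminated by a line source: expanding the incident Hankel field in
cylindrical harmonics and matching E and dE/dr at the cylinder boundary
yields the scattered and interior fields as Bessel series.  This is a
closed-form route entirely independent of the method-of-moments
discretization, which makes it the reference in solver-accuracy checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp

__all__ = ["cylinder_series_coefficients", "cylinder_scattered_field", "cylinder_total_field"]


def _truncation_order(kb: complex, k1: complex, radius: float, rho_max: float) -> int:
    x = max(abs(kb) * rho_max, abs(k1) * radius)
    return int(np.ceil(x + 12 + 4 * x ** (1 / 3)))


def cylinder_series_coefficients(
    radius: float, kb: complex, k1: complex, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic coefficients (a_n, c_n) for orders 0..n_max.

    a_n multiplies the scattered H_n^{(1)}(k_b r) terms outside the cylinder,
    c_n the interior J_n(k_1 r) terms; both are symmetric in n -> -n.  With
    zero contrast (k_1 == k_b) every a_n vanishes.
    """
    n = np.arange(n_max + 1)
    jb, jbp = jv(n, kb * radius), jvp(n, kb * radius)
    j1, j1p = jv(n, k1 * radius), jvp(n, k1 * radius)
    hb, hbp = hankel1(n, kb * radius), h1vp(n, kb * radius)
    denom = kb * j1 * hbp - k1 * j1p * hb
    a = (k1 * j1p * jb - kb * j1 * jbp) / denom
    c = (jb + a * hb) / j1
    return a, c


def _polar(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return np.hypot(points[:, 0], points[:, 1]), np.arctan2(points[:, 1], points[:, 0])


def cylinder_scattered_field(
    points: np.ndarray,
    tx_position: np.ndarray,
    radius: float,
    kb: complex,
    k1: complex,
) -> np.ndarray:
    """Exact scattered field at exterior points for a line source at tx.

    The source normalization matches the solver's unit-amplitude line source
    (i/4) H_0^{(1)}(k_b |r - r_t|).
    """
    rho, phi = _polar(points)
    rho_t, phi_t = _polar(np.asarray(tx_position)[None, :])
    if np.any(rho <= radius):
        raise ValueError("scattered-field series is for exterior points only")
    n_max = _truncation_order(kb, kb, radius, float(max(rho.max(), rho_t[0])))
    a, _ = cylinder_series_coefficients(radius, kb, k1, n_max)
    n = np.arange(n_max + 1)
    h_r = hankel1(n[None, :], kb * rho[:, None])
    h_t = hankel1(n, kb * rho_t[0])
    cosd = np.cos(n[None, :] * (phi[:, None] - phi_t[0]))
    weight = np.where(n == 0, 1.0, 2.0)
    return 0.25j * np.sum(weight * a * h_t * h_r * cosd, axis=1)


def cylinder_total_field(
    points: np.ndarray,
    tx_position: np.ndarray,
    radius: float,
    kb: complex,
    k1: complex,
) -> np.ndarray:
    """Exact total field at interior points (rho < radius)."""
    rho, phi = _polar(points)
    rho_t, phi_t = _polar(np.asarray(tx_position)[None, :])
    if np.any(rho >= radius):
        raise ValueError("total-field series is for interior points only")
    n_max = _truncation_order(kb, k1, radius, float(rho_t[0]))
    _, c = cylinder_series_coefficients(radius, kb, k1, n_max)
    n = np.arange(n_max + 1)
    j_r = jv(n[None, :], k1 * rho[:, None])
    h_t = hankel1(n, kb * rho_t[0])
    cosd = np.cos(n[None, :] * (phi[:, None] - phi_t[0]))
    weight = np.where(n == 0, 1.0, 2.0)
    return 0.25j * np.sum(weight * c * h_t * j_r * cosd, axis=1)
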