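"""Born-iterative temperature estimation: the conventional comparator.

The classical route to hotspot detection inverts the differential scattered
data for the dielectric change and converts it to temperature.  Because the
permittivity and conductivity changes are both proportional to the local
temperature rise (linear thermo-dielectric law), the frequency-dependent
contrast change can be written as

    d_chi(r, w) = [ -a_eps * eps_r(r, w) + j a_sigma * sigma(r, w)/(w eps0) ] * dT(r),

so the natural unknown for a multi-frequency inversion is the real,
frequency-independent temperature-rise map dT itself; the per-frequency
thermo-dielectric factors are folded into the Born operator.  The Born
iterative method (BIM) alternates (i) solving the forward problem for the
current temperature estimate, (ii) linearizing the data equation about it
with the background Green's function and the current internal fields, and
(iii) a regularized linear solve for the update.

Four textbook regularizers are provided for step (iii): Tikhonov (TR),
truncated SVD (TSVD), conjugate-gradient least squares stopped early
(CGLS), and FISTA (L1 proximal gradient).  When the measurement noise norm
is known, TR/TSVD/CGLS pick their parameter by the discrepancy principle;
otherwise spectral-fraction defaults apply.  The unknown is restricted to
breast-interior cells (the coupling medium is never heated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import MoMSolver, ScatterData
from .phantom import EPS0, DielectricMap, TissueMap
from .thermal import TemperatureField
from .thermo_dielectric import ThermoModel, heated_dielectric_map

__all__ = ["InverseConfig", "BimResult", "born_operator", "regularized_solve", "bim_invert"]


@dataclass(frozen=True)
class InverseConfig:
    regularizer: str = "tr"  # "tr" | "tsvd" | "cgls" | "fista"
    reg_param: float | None = None  # method-specific; None -> default policy
    noise_norm: float | None = None  # ||noise|| estimate for the discrepancy rule
    outer_iterations: int = 5
    tolerance: float = 1e-3  # relative-residual stop
    delta_T_max: float = 24.0
    baseline_T: float = 37.0
    threshold_C: float = 40.0
    cgls_max_iter: int = 50
    fista_iterations: int = 200

    def __post_init__(self) -> None:
        if self.regularizer not in ("tr", "tsvd", "cgls", "fista"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.outer_iterations < 1:
            raise ValueError("outer_iterations must be >= 1")


@dataclass
class BimResult:
    delta_T: np.ndarray  # (n, n) °C
    hotspots: np.ndarray  # (n, n) bool
    residual_history: list
    converged: bool


def born_operator(
    solver: MoMSolver,
    reference: DielectricMap,
    fields_per_freq: list[np.ndarray],
    support: np.ndarray,
    thermo: ThermoModel | None = None,
    current: DielectricMap | None = None,
) -> np.ndarray:
    """Linear map from the per-cell temperature rise to the stacked data.

    ``fields_per_freq[k]`` is the (n_cells, n_tx) total field solved in the
    current medium estimate at frequency k; ``current`` is that estimate
    (defaults to the cold reference) and supplies the distorted-wave
    receiver operator, without which the linearization error would not
    vanish for weak perturbations.  Rows are ordered (freq, tx, rx) with the
    complex rows split into real on top of imaginary.  Columns are the
    support cells in row-major order; cells where the field vanishes produce
    zero columns.
    """
    thermo = thermo or ThermoModel()
    current = current or reference
    sup_idx = np.flatnonzero(np.asarray(support).ravel())
    blocks = []
    for k, f in enumerate(solver.frequencies.frequencies):
        omega = 2.0 * np.pi * f
        eps_r = reference.eps_r[..., k].ravel()[sup_idx]
        sigma = reference.sigma[..., k].ravel()[sup_idx]
        # d_chi/d_dT on the support at this frequency
        coeff = -thermo.alpha_eps * eps_r + 1j * thermo.alpha_sigma * sigma / (omega * EPS0)
        Q = solver.distorted_receiver_operator(current, f)[:, sup_idx]  # (n_rx, n_sup)
        E = fields_per_freq[k][sup_idx]  # (n_sup, n_tx)
        # A[(tx, rx), m] = Q[rx, m] * E[m, tx] * coeff[m]
        block = np.einsum("rm,mt,m->trm", Q, E, coeff, optimize=True)
        blocks.append(block.reshape(-1, len(sup_idx)))
    A = np.concatenate(blocks, axis=0)
    return np.concatenate([A.real, A.imag], axis=0)


def _stack_data(diff: np.ndarray) -> np.ndarray:
    """(n_rx, n_tx, n_freq) complex -> stacked real vector, (freq, tx, rx)."""
    z = np.transpose(diff, (2, 1, 0)).reshape(-1)
    return np.concatenate([z.real, z.imag])


def regularized_solve(A: np.ndarray, d: np.ndarray, config: InverseConfig) -> np.ndarray:
    """Solve A x ~= d with the configured regularizer (real-valued system)."""
    if A.shape[0] != d.shape[0]:
        raise ValueError("operator and data are dimensionally inconsistent")
    if config.regularizer == "tr":
        return _solve_tikhonov(A, d, config)
    if config.regularizer == "tsvd":
        return _solve_tsvd(A, d, config)
    if config.regularizer == "cgls":
        return _solve_cgls(A, d, config)
    return _solve_fista(A, d, config)


def _svd(A):
    return np.linalg.svd(A, full_matrices=False)


def _solve_tikhonov(A, d, cfg: InverseConfig) -> np.ndarray:
    U, s, Vt = _svd(A)
    beta = U.T @ d
    perp2 = max(float(d @ d - beta @ beta), 0.0)

    def solution(lam):
        return Vt.T @ (s * beta / (s ** 2 + lam ** 2))

    if cfg.reg_param is not None:
        return solution(cfg.reg_param)
    if cfg.noise_norm is not None and cfg.noise_norm > 0:
        target2 = cfg.noise_norm ** 2

        def residual2(lam):
            filt = lam ** 2 / (s ** 2 + lam ** 2)
            return float(np.sum((filt * beta) ** 2)) + perp2

        lo, hi = 1e-12 * s[0], 1e3 * s[0]
        if residual2(lo) >= target2:
            return solution(lo)
        for _ in range(100):
            mid = np.sqrt(lo * hi)
            if residual2(mid) < target2:
                lo = mid
            else:
                hi = mid
        return solution(np.sqrt(lo * hi))
    return solution(0.01 * s[0])


def _solve_tsvd(A, d, cfg: InverseConfig) -> np.ndarray:
    U, s, Vt = _svd(A)
    beta = U.T @ d
    perp2 = max(float(d @ d - beta @ beta), 0.0)
    if cfg.reg_param is not None:
        k = int(cfg.reg_param)
    elif cfg.noise_norm is not None and cfg.noise_norm > 0:
        # smallest truncation index whose residual drops below the noise norm;
        # keeping the first k values leaves residual^2 = perp2 + sum_{i>k} beta_i^2
        cum = np.cumsum(beta ** 2)
        res2 = perp2 + (float(beta @ beta) - cum)
        below = np.flatnonzero(res2 <= cfg.noise_norm ** 2)
        k = int(below[0]) + 1 if below.size else len(s)
    else:
        k = int(np.sum(s >= 0.01 * s[0]))
    k = max(1, min(k, len(s)))
    return Vt[:k].T @ (beta[:k] / s[:k])


def _solve_cgls(A, d, cfg: InverseConfig) -> np.ndarray:
    """Conjugate-gradient least squares; iteration count is the regularizer."""
    max_iter = int(cfg.reg_param) if cfg.reg_param is not None else cfg.cgls_max_iter
    x = np.zeros(A.shape[1])
    r = d.copy()
    g = A.T @ r
    p = g.copy()
    gamma = float(g @ g)
    target = cfg.noise_norm if cfg.noise_norm else 0.0
    for _ in range(max_iter):
        if gamma == 0.0:
            break
        q = A @ p
        alpha = gamma / float(q @ q)
        x += alpha * p
        r -= alpha * q
        if target and np.linalg.norm(r) <= target:
            break
        g = A.T @ r
        gamma_new = float(g @ g)
        p = g + (gamma_new / gamma) * p
        gamma = gamma_new
    return x


def _solve_fista(A, d, cfg: InverseConfig) -> np.ndarray:
    """L1-penalized least squares via fast iterative shrinkage-thresholding."""
    L = float(np.linalg.norm(A, 2) ** 2)
    if L == 0.0:
        return np.zeros(A.shape[1])
    w = cfg.reg_param if cfg.reg_param is not None else 1e-3 * float(np.abs(A.T @ d).max())
    x = np.zeros(A.shape[1])
    y = x.copy()
    tk = 1.0
    for _ in range(cfg.fista_iterations):
        grad = A.T @ (A @ y - d)
        z = y - grad / L
        x_new = np.sign(z) * np.maximum(np.abs(z) - w / L, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * tk ** 2)) / 2.0
        y = x_new + ((tk - 1.0) / t_new) * (x_new - x)
        x, tk = x_new, t_new
    return x


def bim_invert(
    diff_data: ScatterData,
    reference: DielectricMap,
    tissue: TissueMap,
    config: InverseConfig | None = None,
    solver: MoMSolver | None = None,
    thermo: ThermoModel | None = None,
) -> BimResult:
    """Estimate the temperature-rise map from differential scattered data.

    Iterates linearize -> regularized solve -> dielectric update -> re-solve
    fields, starting from the cold reference.  The final map is thresholded
    at 40 °C for the hotspot image.  A diverging residual stops the loop and
    returns the best iterate, flagged unconverged.
    """
    cfg = config or InverseConfig()
    thermo = thermo or ThermoModel()
    solver = solver or MoMSolver(reference.grid, diff_data.antennas, reference.frequencies)
    support = tissue.interior_mask
    sup_idx = np.flatnonzero(support.ravel())
    n = reference.grid.n_cells_per_axis

    d_meas = _stack_data(diff_data.data)
    cold_sim = solver.simulate(reference)

    dT_sup = np.zeros(len(sup_idx))
    best = (np.inf, dT_sup.copy())
    history: list[float] = []
    converged = False
    d_norm = np.linalg.norm(d_meas)

    for it in range(cfg.outer_iterations):
        dT_full = np.zeros(n * n)
        dT_full[sup_idx] = dT_sup
        field = TemperatureField(
            reference.grid, cfg.baseline_T + dT_full.reshape(n, n), baseline_T=cfg.baseline_T
        )
        current = heated_dielectric_map(reference, field, thermo, tissue)

        fields = [
            solver.solve_total_field(current, f).E
            for f in solver.frequencies.frequencies
        ]
        est_sim = _simulate_from_fields(solver, current, fields)
        residual_vec = d_meas - _stack_data(est_sim - cold_sim.data)
        res = np.linalg.norm(residual_vec) / (d_norm if d_norm > 0 else 1.0)
        history.append(float(res))
        if res < best[0]:
            best = (res, dT_sup.copy())
        if d_norm == 0.0 or res < cfg.tolerance:
            converged = True
            break
        if it >= 1 and res > 1.5 * history[-2]:
            break  # diverging; fall back to the best iterate

        A = born_operator(solver, reference, fields, support, thermo, current=current)
        delta = regularized_solve(A, residual_vec, cfg)
        dT_sup = np.clip(dT_sup + delta, 0.0, cfg.delta_T_max)

    if not converged and len(history) >= 2 and history[-1] <= history[0]:
        converged = history[-1] < 1.0  # made progress; report soft convergence

    dT_full = np.zeros(n * n)
    dT_full[sup_idx] = best[1]
    dT_map = dT_full.reshape(n, n)
    hotspots = (cfg.baseline_T + dT_map) > cfg.threshold_C
    return BimResult(dT_map, hotspots, history, converged)


def _simulate_from_fields(
    solver: MoMSolver, dmap: DielectricMap, fields: list[np.ndarray]
) -> np.ndarray:
    n_ant = solver.antennas.n_antennas
    out = np.empty((n_ant, n_ant, len(solver.frequencies)), dtype=complex)
    for k, f in enumerate(solver.frequencies.frequencies):
        chi = solver.contrast(dmap, f)
        Q = solver.receiver_operator(f)
        out[..., k] = Q @ (chi[:, None] * fields[k])
    return out
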