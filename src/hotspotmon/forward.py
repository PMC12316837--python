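"""2-D TM method-of-moments forward scattering solver.

The breast sits in a lossy coupling medium and is probed by line-source
antennas on a surrounding circle.  For each frequency the total field inside
the computation domain D satisfies the domain integral equation

    E(r) = E_inc(r) + k_0^2 * integral_D G(r, r') chi(r') E(r') dr',

with the background Green's function G = (i/4) H_0^{(1)}(k_b |r - r'|) and
the contrast chi = eps_c - eps_cb (complex relative permittivities, e^{-jwt}
convention).  The domain is discretized on the phantom grid with pulse basis
functions on equivalent-area circular cells (Richmond's scheme); the cell
integrals of G then have closed Bessel/Hankel forms, including the
self-term.  One dense factorization per (map, frequency) is reused across
all transmitters, and cells with zero contrast are eliminated from the
system (the field there follows from the solved tissue cells).

Scattered fields at the receivers use the same cell-integral rule, which
makes the discrete multi-static matrix exactly reciprocal (symmetric) up to
solver round-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import hankel1, jv

from .geometry import AntennaArray, FrequencyGrid, GridSpec
from .phantom import DielectricMap, complex_permittivity

__all__ = [
    "C0",
    "BackgroundMedium",
    "ScatterData",
    "FieldSolution",
    "MoMSolver",
    "incident_field",
    "simulate_multistatic",
    "save_scatter",
    "load_scatter",
]

C0 = 299792458.0  # speed of light in vacuum, m/s


@dataclass(frozen=True)
class BackgroundMedium:
    """Homogeneous lossy coupling medium (default eps_r 20, sigma 0.6 S/m)."""

    eps_rb: float = 20.0
    sigma_b: float = 0.6

    def k0(self, omega: float) -> float:
        """Free-space wavenumber omega/c."""
        return omega / C0

    def eps_cb(self, f: float) -> complex:
        return complex(complex_permittivity(self.eps_rb, self.sigma_b, f))

    def kb(self, f: float) -> complex:
        """Background wavenumber k_0 sqrt(eps_cb), branch with Im(k_b) >= 0."""
        omega = 2.0 * np.pi * f
        kb = self.k0(omega) * np.sqrt(self.eps_cb(f))
        return kb if kb.imag >= 0 else -kb

    def wavelength(self, f: float) -> float:
        """Background wavelength 2 pi / Re(k_b)."""
        return 2.0 * np.pi / self.kb(f).real


@dataclass(frozen=True)
class ScatterData:
    """Multi-static complex scattering matrices, shape (n_rx, n_tx, n_freq)."""

    data: np.ndarray
    frequencies: FrequencyGrid
    antennas: AntennaArray

    def __post_init__(self) -> None:
        n = self.antennas.n_antennas
        expected = (n, n, len(self.frequencies))
        if self.data.shape != expected:
            raise ValueError(f"scatter data must have shape {expected}, got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite scattered-field entries")

    def __sub__(self, other: "ScatterData") -> "ScatterData":
        if (
            self.data.shape != other.data.shape
            or not np.array_equal(self.frequencies.frequencies, other.frequencies.frequencies)
            or self.antennas != other.antennas
        ):
            raise ValueError("scatter data geometries do not match")
        return ScatterData(self.data - other.data, self.frequencies, self.antennas)


@dataclass(frozen=True)
class FieldSolution:
    """Total field on every cell of D, per transmitter, at one frequency."""

    grid: GridSpec
    f: float
    E: np.ndarray  # (n_cells, n_tx) complex, row-major cell order


def incident_field(points: np.ndarray, tx_position: np.ndarray, kb: complex) -> np.ndarray:
    """Unit-amplitude line-source field (i/4) H_0^{(1)}(k_b |r - r_t|)."""
    d = np.linalg.norm(np.asarray(points) - np.asarray(tx_position)[None, :], axis=-1)
    if np.any(d == 0.0):
        raise ValueError("field point coincides with the source")
    return 0.25j * hankel1(0, kb * d)


class MoMSolver:
    """Forward solver bound to a grid, antenna array and frequency grid."""

    def __init__(
        self,
        grid: GridSpec,
        antennas: AntennaArray,
        frequencies: FrequencyGrid,
        background: BackgroundMedium | None = None,
    ):
        self.grid = grid
        self.antennas = antennas
        self.frequencies = frequencies
        self.background = background or BackgroundMedium()

        if np.any(np.linalg.norm(antennas.positions, axis=1) <= grid.extent * np.sqrt(0.5)):
            raise ValueError("antennas must lie outside the computation domain")

        self.cell_area = grid.cell_size ** 2
        #: equivalent-area circular-cell radius, pi a^2 = h^2
        self.a_eq = grid.cell_size / np.sqrt(np.pi)
        centers = grid.cell_centers_flat()
        self._centers = centers
        d = centers[:, None, :] - centers[None, :, :]
        self._R_cells = np.linalg.norm(d, axis=-1)
        self._R_ant = np.linalg.norm(
            antennas.positions[:, None, :] - centers[None, :, :], axis=-1
        )
        # geometry-only matrices are reused across maps; keyed by frequency
        self._cache: dict[tuple[str, float], np.ndarray] = {}

    # -- closed-form cell integrals -------------------------------------

    def _cell_coupling(self, kb: complex, k0: float) -> tuple[np.ndarray, complex]:
        """k_0^2 * integral of G over a source cell, for all cell pairs.

        Returns (M, self_term): M is (n_cells, n_cells) with the self term
        already placed on the diagonal.
        """
        a = self.a_eq
        off = k0 ** 2 * (0.5j * np.pi * a / kb) * jv(1, kb * a)
        R = self._R_cells
        with np.errstate(invalid="ignore"):
            M = off * hankel1(0, kb * R)
        self_term = k0 ** 2 * ((0.5j * np.pi * a / kb) * hankel1(1, kb * a) - 1.0 / kb ** 2)
        np.fill_diagonal(M, self_term)
        return M, self_term

    def _receiver_coupling(self, kb: complex, k0: float) -> np.ndarray:
        """k_0^2 * integral of G from each cell to each receiver."""
        a = self.a_eq
        off = k0 ** 2 * (0.5j * np.pi * a / kb) * jv(1, kb * a)
        return off * hankel1(0, kb * self._R_ant)

    def self_term(self, f: float) -> complex:
        """Closed-form k_0^2 * cell self-integral of G (for validation)."""
        omega = 2.0 * np.pi * f
        return self._cell_coupling(self.background.kb(f), self.background.k0(omega))[1]

    # -- contrast ---------------------------------------------------------

    def contrast(self, dmap: DielectricMap, f: float) -> np.ndarray:
        """Flat per-cell contrast chi = eps_c - eps_cb at frequency f."""
        k = self.frequencies.index_of(f)
        eps_c = complex_permittivity(dmap.eps_r[..., k], dmap.sigma[..., k], f)
        return (eps_c - self.background.eps_cb(f)).ravel()

    # -- solves -----------------------------------------------------------

    def incident_on_cells(self, f: float) -> np.ndarray:
        """(n_cells, n_tx) incident fields of all transmitters."""
        key = ("einc", f)
        if key not in self._cache:
            kb = self.background.kb(f)
            cols = [
                incident_field(self._centers, pos, kb) for pos in self.antennas.positions
            ]
            self._cache[key] = np.column_stack(cols)
        return self._cache[key]

    def _cached_cell_coupling(self, f: float) -> np.ndarray:
        key = ("cells", f)
        if key not in self._cache:
            omega = 2.0 * np.pi * f
            self._cache[key] = self._cell_coupling(
                self.background.kb(f), self.background.k0(omega)
            )[0]
        return self._cache[key]

    def solve_total_field(self, dmap: DielectricMap, f: float) -> FieldSolution:
        """Solve the domain equation for every transmitter at frequency f.

        The dense system is restricted to cells with nonzero contrast; the
        field on zero-contrast cells is recovered by back-substitution into
        the integral equation.  With chi == 0 everywhere the result is the
        incident field exactly.
        """
        chi = self.contrast(dmap, f)
        E_inc = self.incident_on_cells(f)

        active = chi != 0.0
        if not active.any():
            return FieldSolution(self.grid, f, E_inc)

        M = self._cached_cell_coupling(f)
        Maa = M[np.ix_(active, active)]
        A = -Maa * chi[active][None, :]
        A[np.diag_indices_from(A)] += 1.0
        try:
            lu = lu_factor(A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"MoM system factorization failed at {f/1e9:.3g} GHz: {exc}")
        E_active = lu_solve(lu, E_inc[active])

        E = E_inc.copy()
        E[active] = E_active
        passive = ~active
        if passive.any():
            E[passive] += M[np.ix_(passive, active)] @ (chi[active][:, None] * E_active)
        return FieldSolution(self.grid, f, E)

    def scattered_at_receivers(
        self, solution: FieldSolution, chi: np.ndarray
    ) -> np.ndarray:
        """Discretized data equation: one (n_rx, n_tx) matrix."""
        return self.receiver_operator(solution.f) @ (chi[:, None] * solution.E)

    def receiver_operator(self, f: float) -> np.ndarray:
        """(n_rx, n_cells) matrix of k_0^2-scaled cell-integrated Green's
        functions to the receivers (used by Born-type linearizations)."""
        key = ("rx", f)
        if key not in self._cache:
            omega = 2.0 * np.pi * f
            self._cache[key] = self._receiver_coupling(
                self.background.kb(f), self.background.k0(omega)
            )
        return self._cache[key]

    def distorted_receiver_operator(self, dmap: DielectricMap, f: float) -> np.ndarray:
        """Receiver operator of the *inhomogeneous* medium ``dmap``.

        The Frechet derivative of the data w.r.t. a contrast perturbation
        about a scattering reference carries the reference medium's Green's
        function, not the coupling medium's: a perturbation changes the
        internal field, and that change re-radiates through the reference
        contrast.  Algebraically Q_ref = Q + Q X (I - M X)^{-1} M, which
        reduces to Q when the reference contrast X vanishes.
        """
        chi = self.contrast(dmap, f)
        Q = self.receiver_operator(f)
        active = chi != 0.0
        if not active.any():
            return Q
        M = self._cached_cell_coupling(f)
        Maa = M[np.ix_(active, active)]
        A = -Maa * chi[active][None, :]
        A[np.diag_indices_from(A)] += 1.0
        B = Q[:, active] * chi[active][None, :]
        W = np.linalg.solve(A.T, B.T).T  # W = B (I - M_aa X_a)^{-1}
        return Q + W @ M[active, :]

    def simulate(self, dmap: DielectricMap, mask_monostatic: bool = False) -> ScatterData:
        """Full multi-static, multi-frequency simulation.

        The monostatic diagonal is computed and kept by default; set
        ``mask_monostatic`` to zero it out.
        """
        n = self.antennas.n_antennas
        out = np.empty((n, n, len(self.frequencies)), dtype=complex)
        for k, f in enumerate(self.frequencies.frequencies):
            sol = self.solve_total_field(dmap, f)
            out[..., k] = self.scattered_at_receivers(sol, self.contrast(dmap, f))
        if mask_monostatic:
            idx = np.arange(n)
            out[idx, idx, :] = 0.0
        return ScatterData(out, self.frequencies, self.antennas)


def simulate_multistatic(
    dmap: DielectricMap,
    antennas: AntennaArray | None = None,
    background: BackgroundMedium | None = None,
    mask_monostatic: bool = False,
) -> ScatterData:
    """Convenience wrapper building a solver from the map's own grids."""
    solver = MoMSolver(
        dmap.grid, antennas or AntennaArray(), dmap.frequencies, background
    )
    return solver.simulate(dmap, mask_monostatic=mask_monostatic)


# ---------------------------------------------------------------------------
# Container I/O

_FORMAT = "hotspotmon-scatter-v1"


def save_scatter(path, sdata: ScatterData) -> None:
    meta = {
        "format": _FORMAT,
        "f_min": sdata.frequencies.f_min,
        "f_max": sdata.frequencies.f_max,
        "n_frequencies": sdata.frequencies.n_frequencies,
        "n_antennas": sdata.antennas.n_antennas,
        "radius": sdata.antennas.radius,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        data=sdata.data,
    )


def load_scatter(path) -> ScatterData:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["meta"]).decode())
        if meta.get("format") != _FORMAT:
            raise ValueError(f"not a scatter container: {path}")
        freqs = FrequencyGrid(meta["f_min"], meta["f_max"], meta["n_frequencies"])
        ant = AntennaArray(meta["n_antennas"], meta["radius"])
        return ScatterData(payload["data"], freqs, ant)
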