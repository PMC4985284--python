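"""Numerical solution of the Lamm equation for sector-shaped AUC cells.

The Lamm equation governs the radial concentration evolution chi(r, t) of a
sedimenting, diffusing solute in a rotating sector-shaped cell:

    dchi/dt = -(1/r) d/dr ( s w^2 r^2 chi  -  D r dchi/dr )

with zero net flux through the meniscus and the cell bottom.  This module
provides a flux-conservative finite-volume discretization with
Scharfetter-Gummel (exponentially fitted) face fluxes and Crank-Nicolson time
stepping.  Total solute mass (the integral of chi * r dr over the closed cell)
is conserved to round-off by construction, and the scheme degenerates to
monotone upwinding in the diffusion-free limit.

A coupled two-state variant tracks fluorescent and dark sub-populations that
share the same s and D but interconvert with a space- and time-dependent
photoswitching rate; the sum of the two states obeys the plain Lamm equation
on the same discretization exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

# CGS-based physical constants
BOLTZMANN_ERG = 1.380649e-16     # erg/K
GAS_CONSTANT_ERG = 8.31446261815324e7   # erg/(mol K)
AVOGADRO = 6.02214076e23
SVEDBERG = 1.0e-13               # s (1 S = 1e-13 seconds)

__all__ = [
    "SolventModel",
    "CellGeometry",
    "SedimentingSpecies",
    "ConcentrationField",
    "diffusion_from_s",
    "molar_mass_from_sD",
    "solve_lamm",
    "solve_coupled_lamm",
]


@dataclass(frozen=True)
class SolventModel:
    """Solvent density/viscosity and the solute partial-specific volume.

    Defaults correspond to water at 20 degC and a typical protein vbar.
    Units: density g/mL, viscosity poise, temperature degC, vbar mL/g.
    """

    density: float = 0.99823
    viscosity: float = 0.010016
    temperature: float = 20.0
    partial_specific_volume: float = 0.73

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if not (0 < self.partial_specific_volume < 1.2):
            raise ValueError(
                "partial_specific_volume must lie in (0, 1.2) mL/g, got "
                f"{self.partial_specific_volume}"
            )

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature + 273.15

    @property
    def buoyancy(self) -> float:
        """(1 - vbar * rho), positive for sedimenting (non-floating) solutes."""
        return 1.0 - self.partial_specific_volume * self.density


@dataclass(frozen=True)
class CellGeometry:
    """Sector-cell solution column limits and rotor speed.

    Radii in cm (absolute rotor radii), rotor speed in rpm.
    """

    meniscus_radius: float = 6.0
    bottom_radius: float = 7.2
    rotor_speed: float = 50000.0

    def __post_init__(self) -> None:
        if not (5.5 < self.meniscus_radius < self.bottom_radius <= 7.3):
            raise ValueError(
                "require 5.5 < meniscus < bottom <= 7.3 cm, got "
                f"meniscus={self.meniscus_radius}, bottom={self.bottom_radius}"
            )
        if self.rotor_speed < 0:
            raise ValueError("rotor_speed must be non-negative")

    @property
    def omega(self) -> float:
        """Angular velocity in rad/s."""
        return 2.0 * math.pi * self.rotor_speed / 60.0

    @property
    def omega_sq(self) -> float:
        return self.omega**2

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.meniscus_radius + self.bottom_radius)

    def radial_grid(self, dr: float = 0.002) -> np.ndarray:
        """Uniform radial grid spanning the solution column.

        The default spacing of 20 um matches the radial resolution of FDS
        acquisition.
        """
        n = int(round((self.bottom_radius - self.meniscus_radius) / dr)) + 1
        return np.linspace(self.meniscus_radius, self.bottom_radius, n)


def diffusion_from_s(
    s: float,
    friction_ratio: float,
    solvent: SolventModel | None = None,
) -> float:
    """Diffusion coefficient (cm^2/s) from s via the hydrodynamic scaling law.

    For a particle of sedimentation coefficient s (in svedberg) and frictional
    ratio f/f0, the joint Svedberg/Stokes-Einstein relations give

        D(s) = (sqrt(2)/(18 pi)) * kB T * s^(-1/2)
               * (eta * f/f0)^(-3/2) * ((1 - vbar rho)/vbar)^(1/2)

    which closes the one-parameter family of (s, D) pairs used for
    distribution analysis at fixed f/f0.
    """
    solvent = solvent or SolventModel()
    if s <= 0:
        raise ValueError(f"s must be positive to apply the D(s) law, got {s}")
    if friction_ratio < 1.0:
        raise ValueError(f"friction_ratio must be >= 1, got {friction_ratio}")
    if solvent.buoyancy <= 0:
        raise ValueError(
            "flotation (1 - vbar*rho <= 0) is not supported by the D(s) law"
        )
    s_sec = s * SVEDBERG
    kbt = BOLTZMANN_ERG * solvent.temperature_kelvin
    return (
        (math.sqrt(2.0) / (18.0 * math.pi))
        * kbt
        * s_sec ** (-0.5)
        * (solvent.viscosity * friction_ratio) ** (-1.5)
        * (solvent.buoyancy / solvent.partial_specific_volume) ** 0.5
    )


def molar_mass_from_sD(s: float, D: float, solvent: SolventModel | None = None) -> float:
    """Svedberg equation: molar mass (g/mol) from s (svedberg) and D (cm^2/s)."""
    solvent = solvent or SolventModel()
    return (
        s * SVEDBERG * GAS_CONSTANT_ERG * solvent.temperature_kelvin
        / (D * solvent.buoyancy)
    )


@dataclass
class SedimentingSpecies:
    """One sedimenting solute: s in svedberg, optional explicit D in cm^2/s.

    When D is omitted it is derived from the frictional ratio through the
    D(s) scaling law.  A non-sedimenting species (s = 0) requires an explicit
    D (the scaling law diverges at s = 0).
    """

    s: float
    D: Optional[float] = None
    friction_ratio: float = 1.42
    loading_signal: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"s must be non-negative, got {self.s}")
        if self.D is not None and self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        if self.friction_ratio < 1.0:
            raise ValueError(f"friction_ratio must be >= 1, got {self.friction_ratio}")

    def diffusion(self, solvent: SolventModel | None = None) -> float:
        if self.D is not None:
            return self.D
        if self.s == 0:
            raise ValueError(
                "species with s = 0 requires an explicit D; the D(s) law "
                "diverges at s = 0"
            )
        return diffusion_from_s(self.s, self.friction_ratio, solvent)


@dataclass
class ConcentrationField:
    """chi(r, t) on a uniform radial grid; values indexed [time, radius]."""

    radii: np.ndarray
    times: np.ndarray
    values: np.ndarray
    state_label: str = "total"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.radii.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_times={self.times.size}, n_radii={self.radii.size})"
            )
        if self.state_label not in ("total", "fluorescent", "dark"):
            raise ValueError(f"unknown state_label {self.state_label!r}")

    @property
    def dr(self) -> float:
        return float(self.radii[1] - self.radii[0])

    def mass(self) -> np.ndarray:
        """Sector-cell mass integral  sum(chi * r * dr)  at each time."""
        return self.values @ self.radii * self.dr

    def at_radius(self, r: float) -> np.ndarray:
        """Signal trace at the grid point nearest to r."""
        idx = int(np.argmin(np.abs(self.radii - r)))
        return self.values[:, idx]


def _validate_grid(grid: np.ndarray, geometry: CellGeometry) -> float:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 5:
        raise ValueError("radial grid must be 1-D with at least 5 points")
    dr = np.diff(grid)
    if np.any(dr <= 0):
        raise ValueError("radial grid must be strictly increasing")
    if np.ptp(dr) > 1e-8 * dr.mean():
        raise ValueError("radial grid must be uniform")
    if grid[0] > geometry.meniscus_radius + 1e-9 or grid[-1] < geometry.bottom_radius - 1e-9:
        raise ValueError("radial grid must cover [meniscus, bottom]")
    return float(dr.mean())


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the exponential-fitting weight."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def _transport_operator(
    grid: np.ndarray, dr: float, s_sec: float, D: float, omega_sq: float
) -> sparse.csr_matrix:
    """Tridiagonal generator A with dchi/dt = A chi (zero-flux closed cell).

    Scharfetter-Gummel face fluxes: across the face between cells i and i+1,

        J = a * chi_i - b * chi_{i+1}

    with a = (D/dr) B(-Pe), b = (D/dr) B(Pe), Pe = v_f dr / D, v_f = s w^2 r_f.
    For D = 0 this reduces to pure upwinding (a = v_f, b = 0 since v_f >= 0).
    """
    n = grid.size
    r_face = 0.5 * (grid[:-1] + grid[1:])
    v_face = s_sec * omega_sq * r_face
    if D > 0:
        pe = v_face * dr / D
        a = (D / dr) * _bernoulli(-pe)
        b = (D / dr) * _bernoulli(pe)
    else:
        a = v_face.copy()
        b = np.zeros_like(v_face)

    # F_face = r_face * J ; dchi_i/dt = (F_{i-1/2} - F_{i+1/2}) / (r_i dr)
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    w_left = r_face / (grid[:-1] * dr)   # face flux scaled into left cell
    w_right = r_face / (grid[1:] * dr)   # ... and into right cell
    main[:-1] -= w_left * a
    upper += w_left * b
    main[1:] -= w_right * b
    lower += w_right * a
    return sparse.diags([lower, main, upper], offsets=[-1, 0, 1], format="csr")


class _CrankNicolsonStepper:
    """Constant-coefficient CN stepper with cached LU factorizations per dt."""

    def __init__(self, A: sparse.csr_matrix):
        self.A = A
        self.n = A.shape[0]
        self._eye = sparse.identity(self.n, format="csr")
        self._cache: dict[float, tuple] = {}

    def _factors(self, dt: float):
        key = round(dt, 12)
        if key not in self._cache:
            m_impl = (self._eye - 0.5 * dt * self.A).tocsc()
            m_expl = (self._eye + 0.5 * dt * self.A).tocsr()
            self._cache[key] = (splu(m_impl), m_expl)
        return self._cache[key]

    def step(self, chi: np.ndarray, dt: float) -> np.ndarray:
        lu, m_expl = self._factors(dt)
        return lu.solve(m_expl @ chi)


def _substeps(t0: float, t1: float, dt_max: float) -> tuple[int, float]:
    span = t1 - t0
    if span <= 0:
        return 0, 0.0
    n = max(1, int(math.ceil(span / dt_max - 1e-12)))
    return n, span / n


def _initial_profile(
    initial, grid: np.ndarray, loading: float
) -> np.ndarray:
    if initial is None:
        return np.full(grid.size, float(loading))
    if isinstance(initial, ConcentrationField):
        if initial.radii.size == grid.size and np.allclose(initial.radii, grid):
            return initial.values[-1].astype(float).copy()
        return np.interp(grid, initial.radii, initial.values[-1])
    arr = np.asarray(initial, dtype=float)
    if arr.ndim == 0:
        return np.full(grid.size, float(arr))
    if arr.shape != grid.shape:
        raise ValueError("initial profile shape does not match the grid")
    return arr.copy()


def solve_lamm(
    species: SedimentingSpecies,
    geometry: CellGeometry,
    times: Sequence[float],
    grid: np.ndarray | None = None,
    initial=None,
    solvent: SolventModel | None = None,
    dt_max: float = 10.0,
) -> ConcentrationField:
    """Solve the Lamm equation in a closed sector cell.

    Parameters
    ----------
    times:
        Non-decreasing output times in seconds (time zero = rotor at speed).
    grid:
        Uniform radial grid covering [meniscus, bottom]; defaults to the
        geometry's 20 um grid.
    initial:
        Uniform loading (scalar), a radial profile array, or a
        ConcentrationField whose last frame seeds the run.  Defaults to
        species.loading_signal everywhere.
    dt_max:
        Upper bound on the internal Crank-Nicolson step (s).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if grid is None:
        grid = geometry.radial_grid()
    grid = np.asarray(grid, dtype=float)
    dr = _validate_grid(grid, geometry)
    if dt_max <= 0:
        raise ValueError("dt_max must be positive")

    s_sec = species.s * SVEDBERG
    D = species.diffusion(solvent) if (species.s > 0 or species.D is not None) else 0.0
    chi = _initial_profile(initial, grid, species.loading_signal)

    if s_sec == 0.0 and D == 0.0:
        values = np.tile(chi, (times.size, 1))
        return ConcentrationField(grid, times, values)

    A = _transport_operator(grid, dr, s_sec, D, geometry.omega_sq)
    stepper = _CrankNicolsonStepper(A)

    values = np.empty((times.size, grid.size))
    t_cur = 0.0
    for k, t_out in enumerate(times):
        n_sub, dt = _substeps(t_cur, t_out, dt_max)
        for _ in range(n_sub):
            chi = stepper.step(chi, dt)
        t_cur = t_out
        values[k] = chi
    return ConcentrationField(grid, times, values)


def solve_coupled_lamm(
    species: SedimentingSpecies,
    geometry: CellGeometry,
    times: Sequence[float],
    grid: np.ndarray | None = None,
    switch_rate_field: Callable[[np.ndarray, float], np.ndarray] | None = None,
    init_f=None,
    init_d=None,
    reverse_rate_field: Callable[[np.ndarray, float], np.ndarray] | None = None,
    solvent: SolventModel | None = None,
    dt_max: float = 10.0,
) -> tuple[ConcentrationField, ConcentrationField]:
    """Coupled two-state Lamm equation for fluorescent/dark interconversion.

    Both states sediment and diffuse with the species' s and D; concentration
    moves from the fluorescent to the dark state with local rate
    k(r, t) = switch_rate_field(r, t) (and optionally back with
    reverse_rate_field, for on-switchers).  Strang splitting alternates the
    shared Crank-Nicolson transport step with the exact closed-form solution
    of the two-state exchange, so the sum chi_f + chi_d reproduces the
    single-state solution on the same discretization to round-off.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if grid is None:
        grid = geometry.radial_grid()
    grid = np.asarray(grid, dtype=float)
    dr = _validate_grid(grid, geometry)

    s_sec = species.s * SVEDBERG
    D = species.diffusion(solvent) if (species.s > 0 or species.D is not None) else 0.0

    chi_f = _initial_profile(init_f, grid, species.loading_signal)
    chi_d = _initial_profile(init_d, grid, 0.0)

    stepper = None
    if not (s_sec == 0.0 and D == 0.0):
        A = _transport_operator(grid, dr, s_sec, D, geometry.omega_sq)
        stepper = _CrankNicolsonStepper(A)

    def rate(fn, t: float) -> np.ndarray:
        if fn is None:
            return np.zeros(grid.size)
        k = np.asarray(fn(grid, t), dtype=float)
        k = np.broadcast_to(k, grid.shape).copy()
        if np.any(k < 0):
            raise ValueError("photoswitching rate field must be non-negative")
        return k

    def exchange(cf: np.ndarray, cd: np.ndarray, t_mid: float, dt: float):
        """Exact solution of df/dt = -k f + kb d, dd/dt = +k f - kb d."""
        k = rate(switch_rate_field, t_mid)
        kb = rate(reverse_rate_field, t_mid)
        ktot = k + kb
        total = cf + cd
        with np.errstate(divide="ignore", invalid="ignore"):
            f_eq = np.where(ktot > 0, kb / np.where(ktot > 0, ktot, 1.0) * total, cf)
        decay = np.exp(-ktot * dt)
        cf_new = f_eq + (cf - f_eq) * decay
        return cf_new, total - cf_new

    vals_f = np.empty((times.size, grid.size))
    vals_d = np.empty((times.size, grid.size))
    t_cur = 0.0
    for idx, t_out in enumerate(times):
        n_sub, dt = _substeps(t_cur, t_out, dt_max)
        for j in range(n_sub):
            t0 = t_cur + j * dt
            # Strang: half exchange, full transport, half exchange
            chi_f, chi_d = exchange(chi_f, chi_d, t0 + 0.25 * dt, 0.5 * dt)
            if stepper is not None:
                chi_f = stepper.step(chi_f, dt)
                chi_d = stepper.step(chi_d, dt)
            chi_f, chi_d = exchange(chi_f, chi_d, t0 + 0.75 * dt, 0.5 * dt)
        t_cur = t_out
        vals_f[idx] = chi_f
        vals_d[idx] = chi_d
    return (
        ConcentrationField(grid, times, vals_f, state_label="fluorescent"),
        ConcentrationField(grid, times, vals_d, state_label="dark"),
    )
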