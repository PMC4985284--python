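"""Synthetic FDS-SV scan generation for mixtures of (photoswitching) fluorophores.

The generator builds radial fluorescence scans as the superposition

    a(r, t) = sum_p  E_p(s_p, r, t) * chi(s_p, r, t)   (+ Gaussian noise)

with chi from the Lamm solver and E_p from the photoswitching signal model,
optionally with 405 nm "blinking" resets or a FRAP-like localized stationary
pre-exposure (in which case E_p * chi_f enters, with chi_f from the coupled
two-state Lamm equation).  Defaults emulate standard FDS-SV acquisition: a
12 mm solution column (6.0-7.2 cm) at 50,000 rpm and 20 degC, 20 um radial
intervals, scans every 5 min for up to 12 h.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lamm import (
    CellGeometry,
    ConcentrationField,
    SedimentingSpecies,
    SolventModel,
    solve_coupled_lamm,
    solve_lamm,
)
from .photoswitch import IlluminationProfile, Photoswitcher, ResetSchedule, signal_matrix
from .scanio import RadialScan, ScanSet

__all__ = [
    "SyntheticComponent",
    "SyntheticRunConfig",
    "generate_synthetic",
    "default_scan_times",
]


def default_scan_times(interval: float = 300.0, duration: float = 43200.0,
                       start: float | None = None) -> np.ndarray:
    """Scan schedule: every `interval` seconds out to `duration` (12 h default)."""
    if start is None:
        start = interval
    return np.arange(start, duration + 0.5 * interval, interval)


@dataclass
class SyntheticComponent:
    """One mixture component: a sedimenting species carrying a fluorophore."""

    species: SedimentingSpecies
    switcher: Photoswitcher
    resets: Optional[ResetSchedule] = None


@dataclass
class SyntheticRunConfig:
    """Complete description of a synthetic FDS-SV run."""

    components: list
    geometry: CellGeometry = field(default_factory=CellGeometry)
    solvent: SolventModel = field(default_factory=SolventModel)
    scan_times: np.ndarray = field(default_factory=default_scan_times)
    dr: float = 0.002
    noise_sd: float = 0.0          # fraction of the total loading signal
    seed: Optional[int] = None
    frap: Optional[IlluminationProfile] = None
    cell_id: int = 1
    dt_max: float = 10.0

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if not self.components:
            raise ValueError("at least one component is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sd > 0")
        if self.frap is not None and self.frap.windows:
            t_end = self.frap.end_of_exposure
            if np.any(self.scan_times < t_end):
                raise ValueError(
                    "FRAP exposure window overlaps scan times: scans start at "
                    f"{self.scan_times.min():g} s but exposure ends at {t_end:g} s"
                )

    @property
    def total_loading_signal(self) -> float:
        return float(
            sum(c.species.loading_signal * c.switcher.epsilon0 for c in self.components)
        )

    def config_hash(self) -> str:
        payload = repr(
            (
                [(c.species, c.switcher, c.resets) for c in self.components],
                self.geometry,
                self.solvent,
                self.scan_times.tolist(),
                self.dr,
                self.noise_sd,
                self.seed,
                self.frap,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def component_signal_field(
    species: SedimentingSpecies,
    switcher: Photoswitcher,
    geometry: CellGeometry,
    scan_times: np.ndarray,
    grid: np.ndarray,
    resets: ResetSchedule | None = None,
    frap: IlluminationProfile | None = None,
    solvent: SolventModel | None = None,
    dt_max: float = 10.0,
) -> np.ndarray:
    """E * chi for one component on the (scan_times x grid) lattice.

    This single code path is shared by the generator and by the fitting basis
    so that model conventions (dose clock, FRAP handling) cancel exactly in
    generator -> fitter closure.
    """
    scan_times = np.asarray(scan_times, dtype=float)
    if frap is not None and frap.windows:
        chi_f, _ = solve_coupled_lamm(
            species,
            geometry,
            scan_times,
            grid=grid,
            switch_rate_field=frap.rate,
            solvent=solvent,
            dt_max=dt_max,
        )
        chi = chi_f.values
        time_offset = frap.end_of_exposure
    else:
        chi = solve_lamm(
            species, geometry, scan_times, grid=grid, solvent=solvent, dt_max=dt_max
        ).values
        time_offset = 0.0
    E = signal_matrix(
        switcher, species.s, grid, scan_times, resets, geometry, time_offset=time_offset
    )
    return E * chi


def generate_synthetic(config: SyntheticRunConfig) -> tuple[ScanSet, dict]:
    """Generate a synthetic scan set plus a ground-truth sidecar dictionary."""
    grid = config.geometry.radial_grid(config.dr)
    total = np.zeros((config.scan_times.size, grid.size))
    truth_components = []
    for comp in config.components:
        total += component_signal_field(
            comp.species,
            comp.switcher,
            config.geometry,
            config.scan_times,
            grid,
            resets=comp.resets,
            frap=config.frap,
            solvent=config.solvent,
            dt_max=config.dt_max,
        )
        truth_components.append(
            {
                "name": comp.switcher.name,
                "s_svedberg": comp.species.s,
                "friction_ratio": comp.species.friction_ratio,
                "loading_signal": comp.species.loading_signal,
                "epsilon0": comp.switcher.epsilon0,
                "alpha": comp.switcher.alpha,
                "beta_per_s": comp.switcher.beta,
                "sw_true_svedberg": comp.species.s,
                "loading_total_signal": comp.species.loading_signal
                * comp.switcher.epsilon0,
                "reset_times_s": list(comp.resets.reset_times) if comp.resets else [],
            }
        )

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        total = total + config.noise_sd * config.total_loading_signal * rng.standard_normal(
            total.shape
        )

    scans = [
        RadialScan(
            time=float(t),
            rpm=config.geometry.rotor_speed,
            temperature=config.solvent.temperature,
            radii=grid,
            signal=total[i],
            cell_id=config.cell_id,
            description=f"synthetic FDS scan {i + 1}",
        )
        for i, t in enumerate(config.scan_times)
    ]
    sidecar = {
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "total_loading_signal": config.total_loading_signal,
        "config_hash": config.config_hash(),
        "components": truth_components,
    }
    return ScanSet(scans), sidecar


def write_sidecar(sidecar: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
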