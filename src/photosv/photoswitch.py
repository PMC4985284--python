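"""Temporal/spatial fluorescence signal model for photoswitchable FPs.

Under the scanning 488 nm excitation of a fluorescence detection system (FDS),
photoswitchable fluorescent proteins (psFPs) slowly interconvert between
fluorescent and dark states.  Because all molecules rotate with the same
angular velocity, a molecule at radius r traverses the fixed-width excitation
beam faster at larger radii, so the accumulated photon dose along the
sedimentation trajectory of a particle found at radius r after exposure time
dt is

    g(s, r, dt) = (r0 / r) * (w^2 s)^(-1) * (exp(w^2 s dt) - 1)

normalized to a reference radius r0 (series limit g -> (r0/r) dt for
w^2 s dt -> 0).  Photoswitching is modeled as a single-exponential two-state
relaxation with lumped rate constant beta and asymptotic fluorescence
fraction alpha, giving the specific signal increment

    E = eps0 * (alpha + (1 - alpha) * rho_i * exp(-beta * g(s, r, t - t405_i)))

where t405_i is the last 405 nm reset before t and rho_i the fractional
signal recovery of that reset (1 = full reset).  alpha < 1 switches off,
alpha > 1 switches on, alpha = 1 is a photostable fluorophore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .lamm import CellGeometry, SVEDBERG

__all__ = [
    "Photoswitcher",
    "ResetSchedule",
    "IlluminationProfile",
    "accumulated_exposure",
    "signal_increment",
    "illumination_rate",
    "read_photoswitcher",
]


@dataclass(frozen=True)
class Photoswitcher:
    """Per-fluorophore temporal signature.

    epsilon0: initial specific molar signal increment (arbitrary linear units)
    alpha:    asymptotic fluorescence fraction after long 488 nm exposure
    beta:     lumped illumination x quantum-yield switching rate (1/s) at r0
    r0:       reference radius (cm) for the exposure normalization
    q_strong: stationary-beam/scanning-beam exposure ratio (order 100), used
              to convert beta into a stationary-beam switching rate
    """

    name: str = "psFP"
    epsilon0: float = 1.0
    alpha: float = 1.0
    beta: float = 0.0
    r0: float = 6.6
    q_strong: float = 100.0

    def __post_init__(self) -> None:
        if not self.epsilon0 > 0:
            raise ValueError(f"epsilon0 must be positive, got {self.epsilon0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.q_strong <= 0:
            raise ValueError(f"q_strong must be positive, got {self.q_strong}")

    @property
    def is_switching(self) -> bool:
        return self.beta > 0 and self.alpha != 1.0

    def signature_key(self) -> tuple:
        """Parameters that determine the temporal signature (not amplitude)."""
        return (self.alpha, self.beta, self.r0)


@dataclass(frozen=True)
class ResetSchedule:
    """405 nm reset events: times (s) and fractional signal recovery levels."""

    reset_times: tuple = ()
    recovery_fractions: tuple = ()

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.reset_times)
        fracs = tuple(float(f) for f in self.recovery_fractions)
        if not fracs:
            fracs = tuple(1.0 for _ in times)
        if len(fracs) != len(times):
            raise ValueError("recovery_fractions length must match reset_times")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("reset_times must be strictly increasing")
        if any(not (0 < f <= 1.5) for f in fracs):
            raise ValueError("recovery_fractions must lie in (0, 1.5]")
        object.__setattr__(self, "reset_times", times)
        object.__setattr__(self, "recovery_fractions", fracs)

    @classmethod
    def full(cls, times: Sequence[float]) -> "ResetSchedule":
        """Full-recovery resets at the given times."""
        return cls(tuple(times), tuple(1.0 for _ in times))

    def last_reset(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(last reset time <= t, its recovery fraction); (0, 1) if none."""
        t = np.asarray(t, dtype=float)
        if not self.reset_times:
            return np.zeros_like(t), np.ones_like(t)
        rt = np.asarray(self.reset_times)
        rf = np.asarray(self.recovery_fractions)
        idx = np.searchsorted(rt, t, side="right") - 1
        t_last = np.where(idx >= 0, rt[np.clip(idx, 0, None)], 0.0)
        frac = np.where(idx >= 0, rf[np.clip(idx, 0, None)], 1.0)
        return t_last, frac


@dataclass(frozen=True)
class IlluminationProfile:
    """Localized illumination as a superposition of Gaussian beams.

    components: (amplitude 1/s, center cm, width cm) per beam; the amplitude
    is the photoswitching rate k = q * I at the beam center.
    windows: non-overlapping, increasing (start, end) exposure intervals (s).
    """

    components: tuple = ()
    windows: tuple = ()

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(c), float(w)) for a, c, w in self.components)
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        if any(a < 0 for a, _, _ in comps):
            raise ValueError("beam amplitudes must be non-negative")
        if any(w <= 0 for _, _, w in comps):
            raise ValueError("beam widths must be positive")
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ValueError("exposure windows must be non-overlapping, increasing")
        if any(e <= s for s, e in wins):
            raise ValueError("each exposure window must have end > start")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "windows", wins)

    def rate(self, r, t: float) -> np.ndarray:
        return illumination_rate(self, r, t)

    @property
    def end_of_exposure(self) -> float:
        return self.windows[-1][1] if self.windows else 0.0


def accumulated_exposure(
    s: float,
    r,
    dt,
    geometry: CellGeometry,
    r0: float,
) -> np.ndarray:
    """Normalized photon dose g(s, r, dt) along a sedimentation trajectory.

    s in svedberg, r in cm (scalar or array), dt in s (scalar or array,
    broadcast against r).  Uses a series expansion for w^2 s dt < 1e-6 to
    avoid 0/0 at s -> 0, where g -> (r0/r) dt.
    """
    r = np.asarray(r, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("exposure time dt must be non-negative")
    if np.any((r < geometry.meniscus_radius - 1e-9) | (r > geometry.bottom_radius + 1e-9)):
        raise ValueError("radius outside the solution column")
    w2s = geometry.omega_sq * s * SVEDBERG
    x = w2s * dt
    small = np.abs(x) < 1e-6
    # (exp(x)-1)/x -> 1 + x/2 + x^2/6 for small x
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(small, 1.0 + x / 2.0 + x * x / 6.0,
                          np.expm1(x) / np.where(x == 0.0, 1.0, x))
    return (r0 / r) * dt * factor


def signal_increment(
    ps: Photoswitcher,
    s: float,
    r,
    t,
    resets: ResetSchedule | None = None,
    geometry: CellGeometry | None = None,
) -> np.ndarray:
    """Time-dependent specific signal increment E(s, r, t).

    r and t may be scalars or arrays (broadcast together).  The dose clock
    restarts at the last 405 nm reset before t; a partial reset rescales the
    pre-exponential level by its recovery fraction.
    """
    geometry = geometry or CellGeometry()
    resets = resets or ResetSchedule()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    t_last, frac = resets.last_reset(t)
    g = accumulated_exposure(s, r, t - t_last, geometry, ps.r0)
    return ps.epsilon0 * (ps.alpha + (1.0 - ps.alpha) * frac * np.exp(-ps.beta * g))


def signal_matrix(
    ps: Photoswitcher,
    s: float,
    radii: np.ndarray,
    times: np.ndarray,
    resets: ResetSchedule | None = None,
    geometry: CellGeometry | None = None,
    time_offset: float = 0.0,
) -> np.ndarray:
    """E evaluated on a (times x radii) grid; times below time_offset clip to 0.

    time_offset shifts the dose clock, e.g. to start exposure accounting after
    a stationary pre-exposure period.
    """
    t_eff = np.clip(np.asarray(times, dtype=float) - time_offset, 0.0, None)
    return signal_increment(
        ps, s, np.asarray(radii)[None, :], t_eff[:, None], resets, geometry
    )


def illumination_rate(profile: IlluminationProfile, r, t: float) -> np.ndarray:
    """Photoswitching rate k(r, t) (1/s) from the Gaussian-beam superposition."""
    r = np.asarray(r, dtype=float)
    inside = any(start <= t < end for start, end in profile.windows)
    if not inside:
        return np.zeros_like(r)
    out = np.zeros_like(r)
    for amp, center, width in profile.components:
        out += amp * np.exp(-0.5 * ((r - center) / width) ** 2)
    return out


def read_photoswitcher(path) -> Photoswitcher:
    """Read a fluorophore parameter file (key: value lines or YAML mapping)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    known = {"name", "epsilon0", "alpha", "beta", "r0", "q_strong"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return Photoswitcher(**data)


def write_photoswitcher(ps: Photoswitcher, path) -> None:
    import yaml

    payload = {
        "name": ps.name,
        "epsilon0": float(ps.epsilon0),
        "alpha": float(ps.alpha),
        "beta": float(ps.beta),
        "r0": float(ps.r0),
        "q_strong": float(ps.q_strong),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
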