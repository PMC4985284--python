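"""Analytical prediction of component-discrimination errors for protocol design.

For two fluorophores p and q co-sedimenting at the same s-value, the relative
error in the decomposed component concentrations after discretization of the
superposition model is governed by the condition number of the temporal
signature cross-product matrix

    E_pq = sum_t  E_p(t) E_q(t) w(s, t),    w(s, t) = sum_r chi(s, r, t)^2

with signals evaluated at the reference radius (the weak radial dependence is
dropped) and the sedimentation weight taken from the unit-loading Lamm
solution over the fit range.  Given n data points of relative noise delta_a,

    delta_c = cond(E) * sqrt(2) * delta_a / sqrt(n)

This module evaluates delta_c as a function of the photoswitching rate beta
for a fully off-switching versus a photostable component, under constant
scanning or "blinking" protocols (405 nm resets), to locate the optimal rate
and the rate below which blinking hurts discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .lamm import CellGeometry, ConcentrationField, SedimentingSpecies, SolventModel, solve_lamm
from .photoswitch import Photoswitcher, ResetSchedule, signal_increment

__all__ = [
    "SignatureMatrix",
    "ErrorPrediction",
    "DesignCurve",
    "signature_matrix",
    "predicted_error",
    "error_vs_rate",
    "find_crossover",
    "sedimentation_weights",
]


@dataclass
class SignatureMatrix:
    """Mutual signal products E_pq summed over scan times, with weights w(s,t)."""

    matrix: np.ndarray
    scan_times: np.ndarray
    s_ref: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("signature matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-10, atol=0):
            raise ValueError("signature matrix must be symmetric")
        if np.any(np.diag(self.matrix) <= 0):
            raise ValueError("signature matrix diagonal must be positive")

    def condition_number(self) -> float:
        sv = np.linalg.svd(self.matrix, compute_uv=False)
        # numerically singular: smallest singular value at round-off level
        if sv[-1] <= sv[0] * 1e-12 or sv[-1] == 0.0:
            return np.inf
        return float(sv[0] / sv[-1])


@dataclass
class ErrorPrediction:
    """Predicted relative concentration error and its ingredients."""

    delta_c: float
    cond: float
    delta_a: float
    n_points: int
    cause: str = ""

    def __post_init__(self) -> None:
        if self.delta_c < 0:
            raise ValueError("delta_c must be non-negative")
        if np.isfinite(self.cond) and self.cond < 1:
            raise ValueError("condition number must be >= 1")


@dataclass
class DesignCurve:
    """delta_c as a function of the switching rate beta, with its minimum."""

    betas: np.ndarray
    delta_c: np.ndarray
    protocol: str

    @property
    def beta_opt(self) -> float:
        finite = np.isfinite(self.delta_c)
        if not np.any(finite):
            return np.nan
        idx = np.nanargmin(np.where(finite, self.delta_c, np.inf))
        return float(self.betas[idx])

    @property
    def delta_c_min(self) -> float:
        return float(np.nanmin(self.delta_c))


def sedimentation_weights(
    s_ref: float,
    geometry: CellGeometry,
    scan_times: np.ndarray,
    solvent: SolventModel | None = None,
    friction_ratio: float = 1.42,
    fit_range: tuple[float, float] | None = None,
    dt_max: float = 10.0,
) -> tuple[np.ndarray, ConcentrationField]:
    """w(s, t) = sum_r chi(s_ref, r, t)^2 from the unit-loading Lamm solution."""
    species = SedimentingSpecies(s=s_ref, friction_ratio=friction_ratio,
                                 loading_signal=1.0)
    chi = solve_lamm(species, geometry, np.asarray(scan_times, dtype=float),
                     solvent=solvent, dt_max=dt_max)
    if fit_range is None:
        fit_range = (geometry.meniscus_radius + 0.03, geometry.bottom_radius - 0.05)
    mask = (chi.radii >= fit_range[0]) & (chi.radii <= fit_range[1])
    w = np.sum(chi.values[:, mask] ** 2, axis=1)
    return w, chi


def signature_matrix(
    components: Sequence,
    s_ref: float,
    geometry: CellGeometry,
    scan_times: np.ndarray,
    solvent: SolventModel | None = None,
    friction_ratio: float = 1.42,
    fit_range: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
    dt_max: float = 10.0,
) -> SignatureMatrix:
    """Build the p x p temporal signature matrix for co-sedimenting components.

    ``components`` is a sequence of Photoswitcher or (Photoswitcher,
    ResetSchedule) pairs.  Signals are evaluated at each fluorophore's
    reference radius; ``weights`` may carry a precomputed w(s, t) so one Lamm
    solution can be reused across many rate evaluations.
    """
    comps = []
    for item in components:
        if isinstance(item, Photoswitcher):
            comps.append((item, None))
        else:
            ps, resets = item
            comps.append((ps, resets))
    if len(comps) < 2:
        raise ValueError("signature analysis needs at least two components")
    scan_times = np.asarray(scan_times, dtype=float)
    if np.any(np.diff(scan_times) < 0):
        raise ValueError("scan_times must be sorted")

    if weights is None:
        weights, _ = sedimentation_weights(
            s_ref, geometry, scan_times, solvent, friction_ratio, fit_range, dt_max
        )
    weights = np.asarray(weights, dtype=float)
    if weights.shape != scan_times.shape:
        raise ValueError("weights must match scan_times in length")

    E = np.vstack([
        signal_increment(ps, s_ref, ps.r0, scan_times, resets, geometry)
        for ps, resets in comps
    ])
    matrix = np.einsum("pt,t,qt->pq", E, weights, E)
    return SignatureMatrix(matrix=matrix, scan_times=scan_times, s_ref=s_ref,
                           weights=weights)


def predicted_error(
    sig: SignatureMatrix,
    delta_a: float,
    n_points: int,
    constant: float = np.sqrt(2.0),
) -> ErrorPrediction:
    """delta_c = cond(E) * sqrt(2) * delta_a / sqrt(n)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if delta_a < 0:
        raise ValueError("delta_a must be non-negative")
    cond = sig.condition_number()
    if not np.isfinite(cond):
        return ErrorPrediction(
            delta_c=np.inf, cond=np.inf, delta_a=delta_a, n_points=n_points,
            cause="singular signature matrix: identical temporal signatures",
        )
    delta_c = cond * constant * delta_a / np.sqrt(n_points)
    return ErrorPrediction(delta_c=float(delta_c), cond=cond, delta_a=delta_a,
                           n_points=n_points)


def error_vs_rate(
    rate_grid: np.ndarray,
    *,
    s_ref: float,
    geometry: CellGeometry,
    scan_times: np.ndarray,
    delta_a: float,
    n_points: int,
    protocol: str = "constant",
    resets: ResetSchedule | None = None,
    alpha: float = 0.0,
    r0: float | None = None,
    solvent: SolventModel | None = None,
    friction_ratio: float = 1.42,
    fit_range: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
    constant: float = np.sqrt(2.0),
    dt_max: float = 10.0,
) -> DesignCurve:
    """delta_c(beta) for an off-switching vs. photostable component pair.

    protocol 'constant': uninterrupted scanning.  protocol 'blinking': full
    405 nm resets at the times in ``resets`` restore the switching component's
    signal during the run.  The Lamm-solution weight w(s, t) is computed once
    and reused across all rates.
    """
    rate_grid = np.asarray(rate_grid, dtype=float)
    if np.any(rate_grid <= 0):
        raise ValueError("rate_grid entries must be positive")
    if protocol not in ("constant", "blinking"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if protocol == "blinking" and resets is None:
        raise ValueError("blinking protocol requires a ResetSchedule")
    scan_times = np.asarray(scan_times, dtype=float)
    if r0 is None:
        r0 = geometry.midpoint

    if weights is None:
        weights, _ = sedimentation_weights(
            s_ref, geometry, scan_times, solvent, friction_ratio, fit_range, dt_max
        )

    stable = Photoswitcher(name="stable", epsilon0=1.0, alpha=1.0, beta=0.0, r0=r0)
    use_resets = resets if protocol == "blinking" else None
    delta_c = np.empty_like(rate_grid)
    for i, beta in enumerate(rate_grid):
        switcher = Photoswitcher(name="switching", epsilon0=1.0, alpha=alpha,
                                 beta=beta, r0=r0)
        sig = signature_matrix(
            [(switcher, use_resets), (stable, None)],
            s_ref, geometry, scan_times, weights=weights,
        )
        delta_c[i] = predicted_error(sig, delta_a, n_points, constant=constant).delta_c
    return DesignCurve(betas=rate_grid, delta_c=delta_c, protocol=protocol)


def find_crossover(curve_a: DesignCurve, curve_b: DesignCurve) -> float:
    """Rate beta at which two design curves cross (log-linear interpolation).

    Returns NaN when the curves do not cross on the common grid.
    """
    if curve_a.betas.shape != curve_b.betas.shape or not np.allclose(
        curve_a.betas, curve_b.betas
    ):
        raise ValueError("curves must share the same rate grid")
    diff = np.log(curve_a.delta_c) - np.log(curve_b.delta_c)
    sign = np.sign(diff)
    for i in range(len(sign) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            x0, x1 = np.log(curve_a.betas[i]), np.log(curve_a.betas[i + 1])
            y0, y1 = diff[i], diff[i + 1]
            return float(np.exp(x0 - y0 * (x1 - x0) / (y1 - y0)))
        if sign[i + 1] == 0:
            return float(curve_a.betas[i + 1])
    return np.nan
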