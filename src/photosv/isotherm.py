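"""Mass-action equilibria and sw isotherms for competitive dimerization.

Two protomers A and B can form homodimers A2, B2 and a heterodimer AB, with
dissociation constants Kd22, Kd33, Kd23.  Free concentrations (a, b) satisfy
the coupled mass balances

    a + 2 a^2/Kd22 + a b/Kd23 = total_A
    b + 2 b^2/Kd33 + a b/Kd23 = total_B

For a rapid association/dissociation equilibrium on the sedimentation time
scale, the observable per fluorophore component is the signal-weighted
average sedimentation coefficient (protomer-proportional signal):

    sw_A = (a s_A + 2 A2 s_A2 + AB s_AB) / (a + 2 A2 + AB)

and analogously for B.  Dissociation constants are fitted to measured
sw(total) isotherms by weighted nonlinear least squares, with confidence
intervals from parametric Monte-Carlo resampling within the sw error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BindingSystem",
    "SpeciesConcentrations",
    "IsothermData",
    "IsothermFit",
    "MassActionError",
    "solve_mass_action",
    "component_sw",
    "sw_isotherm",
    "fit_isotherm",
]


class MassActionError(RuntimeError):
    """Mass-action solve failed to reach the required residual."""


@dataclass(frozen=True)
class BindingSystem:
    """Species s-values (svedberg) and dissociation constants (molar).

    Kd may be numpy.inf to switch an association off entirely.
    """

    kd22: float        # A homodimer
    kd33: float        # B homodimer
    kd23: float        # heterodimer
    s_A: float
    s_A2: float
    s_B: float
    s_B2: float
    s_AB: float
    signal_per_protomer_A: float = 1.0
    signal_per_protomer_B: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kd22", "kd33", "kd23"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive (may be inf)")
        if not self.s_A2 > self.s_A:
            raise ValueError("s_A2 must exceed s_A")
        if not self.s_B2 > self.s_B:
            raise ValueError("s_B2 must exceed s_B")
        if not self.s_AB > max(self.s_A, self.s_B):
            raise ValueError("s_AB must exceed both monomer s-values")


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Equilibrium molar concentrations of all five species."""

    a: float
    b: float
    A2: float
    B2: float
    AB: float

    @property
    def total_A(self) -> float:
        return self.a + 2.0 * self.A2 + self.AB

    @property
    def total_B(self) -> float:
        return self.b + 2.0 * self.B2 + self.AB


def _free_a(b: float, total_A: float, kd22: float, kd23: float) -> float:
    """Exact free-A concentration given free B (quadratic mass balance).

    Uses the cancellation-safe root  a = 2 tA / (c1 + sqrt(c1^2 + 8 tA/Kd22)).
    """
    if total_A <= 0:
        return 0.0
    c1 = 1.0 + (b / kd23 if np.isfinite(kd23) else 0.0)
    if not np.isfinite(kd22):
        return total_A / c1
    disc = c1 * c1 + 8.0 * total_A / kd22
    return 2.0 * total_A / (c1 + np.sqrt(disc))


def solve_mass_action(
    total_A: float,
    total_B: float,
    system: BindingSystem,
    rtol: float = 1e-12,
) -> SpeciesConcentrations:
    """Equilibrium species concentrations at the given loading totals.

    Free A is eliminated exactly via its quadratic mass balance; the free-B
    balance f(b) is then monotone in b and bracketed by [0, total_B], so Brent
    root-finding cannot fail.  Mass-balance residuals are verified to be below
    1e-10 relative.
    """
    if total_A < 0 or total_B < 0:
        raise ValueError("totals must be non-negative")

    if total_B == 0:
        b = 0.0
        a = _free_a(0.0, total_A, system.kd22, system.kd23)
    else:

        def f(b: float) -> float:
            a = _free_a(b, total_A, system.kd22, system.kd23)
            homo = 2.0 * b * b / system.kd33 if np.isfinite(system.kd33) else 0.0
            hetero = a * b / system.kd23 if np.isfinite(system.kd23) else 0.0
            return b + homo + hetero - total_B

        try:
            b = optimize.brentq(f, 0.0, total_B, xtol=1e-300, rtol=8.9e-16,
                                maxiter=200)
        except Exception as exc:  # pragma: no cover - bracket is guaranteed
            raise MassActionError(
                f"free-B root search failed for totals ({total_A}, {total_B}): {exc}"
            ) from exc
        a = _free_a(b, total_A, system.kd22, system.kd23)

    A2 = a * a / system.kd22 if np.isfinite(system.kd22) else 0.0
    B2 = b * b / system.kd33 if np.isfinite(system.kd33) else 0.0
    AB = a * b / system.kd23 if np.isfinite(system.kd23) else 0.0
    conc = SpeciesConcentrations(a=a, b=b, A2=A2, B2=B2, AB=AB)

    for total, got in ((total_A, conc.total_A), (total_B, conc.total_B)):
        if total > 0 and abs(got - total) > 1e-10 * total:
            raise MassActionError(
                f"mass balance residual {abs(got - total) / total:.3e} exceeds "
                f"1e-10 at totals ({total_A:.3e}, {total_B:.3e})"
            )
    return conc


def component_sw(
    conc: SpeciesConcentrations, system: BindingSystem, component: str
) -> float:
    """Signal-weighted average s of one component (protomer-weighted signal)."""
    if component == "A":
        denom = conc.a + 2.0 * conc.A2 + conc.AB
        if denom <= 0:
            raise ValueError("component A has zero total concentration")
        return (conc.a * system.s_A + 2.0 * conc.A2 * system.s_A2
                + conc.AB * system.s_AB) / denom
    if component == "B":
        denom = conc.b + 2.0 * conc.B2 + conc.AB
        if denom <= 0:
            raise ValueError("component B has zero total concentration")
        return (conc.b * system.s_B + 2.0 * conc.B2 * system.s_B2
                + conc.AB * system.s_AB) / denom
    raise ValueError(f"component must be 'A' or 'B', got {component!r}")


def sw_isotherm(
    totals_A: np.ndarray, totals_B: np.ndarray, system: BindingSystem
) -> tuple[np.ndarray, np.ndarray]:
    """sw_A and sw_B along an isotherm of loading totals."""
    totals_A = np.asarray(totals_A, dtype=float)
    totals_B = np.asarray(totals_B, dtype=float)
    sw_A = np.empty_like(totals_A)
    sw_B = np.empty_like(totals_B)
    for i, (ta, tb) in enumerate(zip(totals_A, totals_B)):
        conc = solve_mass_action(ta, tb, system)
        sw_A[i] = component_sw(conc, system, "A") if ta > 0 else np.nan
        sw_B[i] = component_sw(conc, system, "B") if tb > 0 else np.nan
    return sw_A, sw_B


@dataclass
class IsothermData:
    """Measured per-component sw versus loading totals, with 68% error bars."""

    totals_A: np.ndarray
    totals_B: np.ndarray
    sw_A: np.ndarray
    sw_B: np.ndarray
    sw_A_err: Optional[np.ndarray] = None
    sw_B_err: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arrays = ["totals_A", "totals_B", "sw_A", "sw_B", "sw_A_err", "sw_B_err"]
        n = None
        for name in arrays:
            val = getattr(self, name)
            if val is None:
                continue
            val = np.asarray(val, dtype=float)
            setattr(self, name, val)
            if n is None:
                n = val.size
            elif val.size != n:
                raise ValueError("all isotherm arrays must have equal length")
        if np.any(self.totals_A < 0) or np.any(self.totals_B < 0):
            raise ValueError("totals must be non-negative")

    @property
    def n_points(self) -> int:
        return int(np.isfinite(self.sw_A).sum() + np.isfinite(self.sw_B).sum())

    @classmethod
    def from_csv(cls, path) -> "IsothermData":
        df = pd.read_csv(path)
        def col(name):
            return df[name].to_numpy() if name in df.columns else None
        return cls(
            totals_A=df["total_A_molar"].to_numpy(),
            totals_B=df["total_B_molar"].to_numpy(),
            sw_A=df["sw_A"].to_numpy(),
            sw_B=df["sw_B"].to_numpy(),
            sw_A_err=col("sw_A_err"),
            sw_B_err=col("sw_B_err"),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "total_A_molar": self.totals_A,
                "total_B_molar": self.totals_B,
                "sw_A": self.sw_A,
                "sw_A_err": self.sw_A_err if self.sw_A_err is not None else np.nan,
                "sw_B": self.sw_B,
                "sw_B_err": self.sw_B_err if self.sw_B_err is not None else np.nan,
            }
        ).to_csv(path, index=False)


_LOG_PARAMS = {"kd22", "kd33", "kd23"}
_FITTABLE = _LOG_PARAMS | {"s_A", "s_A2", "s_B", "s_B2", "s_AB"}


@dataclass
class IsothermFit:
    """Best-fit binding parameters with Monte-Carlo confidence intervals."""

    system: BindingSystem
    free_params: tuple
    params: dict
    intervals68: dict
    intervals95: dict
    rmsd: float
    mc_samples: Optional[dict] = None

    def interval(self, name: str, level: int = 95) -> tuple[float, float]:
        table = self.intervals95 if level == 95 else self.intervals68
        return table[name]


def _weights(data: IsothermData) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance weights; undetermined errors get the median error."""
    def norm(err, sw):
        if err is None:
            err = np.full_like(np.asarray(sw, dtype=float), np.nan)
        err = np.where(np.isfinite(err) & (err > 0), err, np.nan)
        med = np.nanmedian(err)
        if not np.isfinite(med):
            med = 1.0
        return np.where(np.isfinite(err), err, med)

    return norm(data.sw_A_err, data.sw_A), norm(data.sw_B_err, data.sw_B)


def fit_isotherm(
    data: IsothermData,
    system: BindingSystem,
    free: Sequence[str] = ("kd23",),
    mc_iterations: int = 0,
    seed: int | None = None,
) -> IsothermFit:
    """Weighted least-squares fit of binding parameters to sw isotherms.

    ``system`` supplies starting values and every fixed parameter; ``free``
    names the parameters to optimize (Kd values are fitted on a log scale,
    s-values linearly).  Both components' sw data enter a single weighted
    objective.  With mc_iterations > 0, sw values are resampled within their
    error bars and refitted to produce 68%/95% percentile intervals;
    identifiability problems surface as interval blow-up, never silently.
    """
    free = tuple(free)
    unknown = set(free) - _FITTABLE
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if data.n_points < len(free):
        raise ValueError(
            f"isotherm has {data.n_points} usable points but {len(free)} free "
            "parameters; the fit is not identifiable"
        )
    err_A, err_B = _weights(data)
    mask_A = np.isfinite(data.sw_A)
    mask_B = np.isfinite(data.sw_B)

    def pack(sys: BindingSystem) -> np.ndarray:
        vals = []
        for name in free:
            v = getattr(sys, name)
            vals.append(np.log(v) if name in _LOG_PARAMS else v)
        return np.array(vals)

    def unpack(x: np.ndarray) -> BindingSystem:
        changes = {}
        for name, v in zip(free, x):
            changes[name] = float(np.exp(v)) if name in _LOG_PARAMS else float(v)
        return replace(system, **changes)

    def residuals(x: np.ndarray, sw_A_obs: np.ndarray, sw_B_obs: np.ndarray):
        try:
            sys_x = unpack(x)
            model_A, model_B = sw_isotherm(data.totals_A, data.totals_B, sys_x)
        except (ValueError, MassActionError):
            return np.full(mask_A.sum() + mask_B.sum(), 1e6)
        res_A = (model_A[mask_A] - sw_A_obs[mask_A]) / err_A[mask_A]
        res_B = (model_B[mask_B] - sw_B_obs[mask_B]) / err_B[mask_B]
        return np.concatenate([res_A, res_B])

    x0 = pack(system)

    def solve(sw_A_obs, sw_B_obs, start):
        res = optimize.least_squares(
            residuals, start, args=(sw_A_obs, sw_B_obs), method="lm"
            if len(free) <= data.n_points else "trf",
        )
        return res

    best = solve(data.sw_A, data.sw_B, x0)
    best_sys = unpack(best.x)
    params = {name: getattr(best_sys, name) for name in free}
    rmsd = float(np.sqrt(np.mean(best.fun**2)))

    intervals68: dict = {}
    intervals95: dict = {}
    samples: dict = {name: np.array([]) for name in free}
    if mc_iterations >= 2:
        rng = np.random.default_rng(seed)
        model_A, model_B = sw_isotherm(data.totals_A, data.totals_B, best_sys)
        draws = {name: np.empty(mc_iterations) for name in free}
        for it in range(mc_iterations):
            sw_A_sim = model_A + err_A * rng.standard_normal(model_A.size)
            sw_B_sim = model_B + err_B * rng.standard_normal(model_B.size)
            fit_it = solve(sw_A_sim, sw_B_sim, best.x)
            sys_it = unpack(fit_it.x)
            for name in free:
                draws[name][it] = getattr(sys_it, name)
        for name in free:
            arr = draws[name]
            intervals68[name] = (
                float(np.percentile(arr, 16)), float(np.percentile(arr, 84))
            )
            intervals95[name] = (
                float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))
            )
        samples = draws
    return IsothermFit(
        system=best_sys,
        free_params=free,
        params=params,
        intervals68=intervals68,
        intervals95=intervals95,
        rmsd=rmsd,
        mc_samples=samples if mc_iterations >= 2 else None,
    )
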