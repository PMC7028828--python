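"""Exact Gaussian reduction of the two-population dynamics.

When both initial phenotype distributions are Gaussian and ``zeta == gamma``
the non-local PDE system stays Gaussian for all time:

    n_i(x, t) = rho_i(t) sqrt(v_i(t) / 2 pi) exp(-v_i(t) (x - mu_i(t))^2 / 2),

with the inverse variance ``v_i``, mean trait ``mu_i`` and size ``rho_i``
solving, per population i in {H, L},

    v_i'   = 2 (gamma - beta_i v_i^2)
    mu_i'  = (2 gamma / v_i) (phi(t) - mu_i)
    rho_i' = (F_i(t) - d rho(t)) rho_i,       rho = rho_H + rho_L,
    F_i(t) = gamma g(t) - gamma / v_i - gamma (mu_i - phi(t))^2.

The v-equation is autonomous and separable; its closed-form solution is
exposed in :func:`v_closed_form` and relaxes to ``sqrt(gamma / beta_i)``
at rate ``4 sqrt(gamma beta_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .environment import FitnessModel, NutrientSignal
from .errors import AnalyticPreconditionError, IntegrationError, StateError

__all__ = [
    "PopulationSpec",
    "GaussianState",
    "MomentTrajectory",
    "default_population_pair",
    "moment_rhs",
    "solve_cauchy",
    "v_closed_form",
    "reconstruct_density",
]

#: populations with size below this floor are reported as effectively extinct
EXTINCTION_FLOOR = 1e-6


@dataclass(frozen=True)
class PopulationSpec:
    """One competing population: its variation rate and Gaussian initial data."""

    label: str  # "H" or "L"
    beta: float  # rate of spontaneous phenotypic variation (> 0)
    rho0: float = 800.0  # initial size (> 0)
    mu0: float = 0.0  # initial mean phenotype
    v0: float = 20.0  # initial inverse variance (> 0)

    def __post_init__(self) -> None:
        if self.label not in ("H", "L"):
            raise StateError("population label must be 'H' or 'L'")
        if self.beta <= 0 or self.rho0 <= 0 or self.v0 <= 0:
            raise StateError("beta, rho0 and v0 must all be positive")


def default_population_pair(beta_H: float = 0.025, beta_L: float = 0.01,
                            rho0: float = 800.0, mu0: float = 0.0,
                            v0: float = 20.0) -> Tuple[PopulationSpec, PopulationSpec]:
    """The (H, L) pair used throughout the numerical experiments."""
    return (PopulationSpec("H", beta_H, rho0, mu0, v0),
            PopulationSpec("L", beta_L, rho0, mu0, v0))


def _check_pair(specs: Sequence[PopulationSpec]) -> Tuple[PopulationSpec, PopulationSpec]:
    if len(specs) != 2 or {s.label for s in specs} != {"H", "L"}:
        raise StateError("expected exactly one 'H' and one 'L' population spec")
    sH = next(s for s in specs if s.label == "H")
    sL = next(s for s in specs if s.label == "L")
    if not sH.beta > sL.beta:
        raise StateError("population H must have the larger variation rate (beta_H > beta_L)")
    return sH, sL


@dataclass(frozen=True)
class GaussianState:
    """Instantaneous Gaussian state of both populations.

    Arrays are ordered (H, L).  ``sigma2 = 1 / v``.
    """

    t: float
    rho: np.ndarray
    mu: np.ndarray
    v: np.ndarray
    labels: Tuple[str, str] = ("H", "L")

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.v <= 0):
            raise StateError("inverse variances must stay positive")
        if np.any(self.rho < 0):
            raise StateError("population sizes must stay nonnegative")

    @property
    def sigma2(self) -> np.ndarray:
        return 1.0 / self.v

    @property
    def rho_total(self) -> float:
        return float(self.rho.sum())


@dataclass(frozen=True)
class MomentTrajectory:
    """Time-sampled moment solution plus the realized environment series."""

    t: np.ndarray
    rho: np.ndarray  # shape (2, n): rows H, L
    mu: np.ndarray
    v: np.ndarray
    S: np.ndarray
    g: np.ndarray
    phi: np.ndarray
    labels: Tuple[str, str] = ("H", "L")

    def __post_init__(self) -> None:
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise StateError("trajectory times must be strictly increasing")

    @property
    def sigma2(self) -> np.ndarray:
        return 1.0 / self.v

    def state(self, k: int) -> GaussianState:
        return GaussianState(float(self.t[k]), self.rho[:, k], self.mu[:, k], self.v[:, k])

    def final_state(self) -> GaussianState:
        return self.state(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "rho_H": self.rho[0], "rho_L": self.rho[1],
            "mu_H": self.mu[0], "mu_L": self.mu[1],
            "var_H": self.sigma2[0], "var_L": self.sigma2[1],
            "S": self.S, "g": self.g, "phi": self.phi,
        })

    def extinct(self, floor: float = EXTINCTION_FLOOR) -> Tuple[bool, bool]:
        """Whether each population's final size lies below the reporting floor."""
        return tuple(self.rho[:, -1] < floor)


def _require_analytic(model: FitnessModel) -> None:
    if not model.analytic_valid:
        raise AnalyticPreconditionError(
            "the Gaussian moment reduction requires zeta == gamma")


def moment_rhs(t: float, y: np.ndarray, model: FitnessModel, signal: NutrientSignal,
               specs: Sequence[PopulationSpec], _strict: bool = True) -> np.ndarray:
    """Right-hand side of the 6-d moment system.

    ``y = [v_H, mu_H, rho_H, v_L, mu_L, rho_L]``.  With ``_strict=False``
    (used internally by the adaptive integrator, whose rejected trial
    stages may overshoot) a non-positive inverse variance is clamped to a
    tiny positive value instead of raising, which blows up the error
    estimate and forces step rejection; the converged solution itself
    always keeps ``v > 0``.
    """
    _require_analytic(model)
    sH, sL = _check_pair(specs)
    v = np.array([y[0], y[3]])
    mu = np.array([y[1], y[4]])
    rho = np.array([y[2], y[5]])
    if np.any(v <= 0):
        if _strict:
            raise StateError(f"inverse variance became non-positive at t={t}")
        v = np.maximum(v, 1e-12)
    beta = np.array([sH.beta, sL.beta])
    gamma, d = model.gamma, model.d
    S = signal(t)
    g, phi = model.g(S), model.phi(S)
    F = gamma * g - gamma / v - gamma * (mu - phi) ** 2
    dv = 2.0 * (gamma - beta * v**2)
    dmu = (2.0 * gamma / v) * (phi - mu)
    drho = (F - d * rho.sum()) * rho
    return np.array([dv[0], dmu[0], drho[0], dv[1], dmu[1], drho[1]])


def solve_cauchy(specs: Sequence[PopulationSpec], model: FitnessModel,
                 signal: NutrientSignal, t_final: float, n_samples: int = 1000,
                 rtol: float = 1e-8, atol: float = 1e-10,
                 method: str = "RK45") -> MomentTrajectory:
    """Integrate the moment system from t = 0 to ``t_final``.

    Uses an adaptive explicit Runge-Kutta pair; output is re-sampled on a
    uniform grid of ``n_samples + 1`` points (internal steps stay adaptive).
    """
    _require_analytic(model)
    sH, sL = _check_pair(specs)
    y0 = np.array([sH.v0, sH.mu0, sH.rho0, sL.v0, sL.mu0, sL.rho0])
    if t_final < 0:
        raise StateError("t_final must be nonnegative")
    if t_final == 0:
        t = np.array([0.0])
        ys = y0[:, None]
    else:
        t = np.linspace(0.0, t_final, n_samples + 1)
        sol = solve_ivp(moment_rhs, (0.0, t_final), y0, t_eval=t, method=method,
                        rtol=rtol, atol=atol, args=(model, signal, specs, False))
        if not sol.success:
            raise IntegrationError(f"moment ODE solver failed: {sol.message}")
        ys = sol.y
    S = np.asarray(signal(t), dtype=float)
    return MomentTrajectory(
        t=t,
        rho=np.vstack([ys[2], ys[5]]),
        mu=np.vstack([ys[1], ys[4]]),
        v=np.vstack([ys[0], ys[3]]),
        S=S, g=np.asarray(model.g(S)), phi=np.asarray(model.phi(S)),
    )


def v_closed_form(spec: PopulationSpec, model: FitnessModel, t) -> np.ndarray:
    """Closed-form inverse variance

        v(t) = sqrt(gamma/beta) * (c + v0 - (c - v0) e^{-4 sqrt(gamma beta) t})
                                / (c + v0 + (c - v0) e^{-4 sqrt(gamma beta) t}),

    with ``c = sqrt(gamma/beta)``; relaxes to ``c`` as t -> infinity.
    """
    _require_analytic(model)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise StateError("time must be nonnegative")
    c = np.sqrt(model.gamma / spec.beta)
    e = np.exp(-4.0 * np.sqrt(model.gamma * spec.beta) * t)
    out = c * (c + spec.v0 - (c - spec.v0) * e) / (c + spec.v0 + (c - spec.v0) * e)
    return out if out.ndim else float(out)


def reconstruct_density(state: GaussianState, x: np.ndarray,
                        mass_tol: float = 1e-3) -> np.ndarray:
    """Evaluate both Gaussian densities on the grid ``x``.

    Returns an array of shape ``(2, len(x))`` ordered (H, L).  Emits a
    truncation warning when the grid covers less than ``1 - mass_tol`` of
    the mass of a non-negligible population.
    """
    x = np.asarray(x, dtype=float)
    n = (state.rho[:, None] * np.sqrt(state.v[:, None] / (2.0 * np.pi))
         * np.exp(-0.5 * state.v[:, None] * (x - state.mu[:, None]) ** 2))
    if x.size > 1:
        captured = np.trapezoid(n, x, axis=1)
        for i, lab in enumerate(state.labels):
            if state.rho[i] > EXTINCTION_FLOOR and captured[i] < (1.0 - mass_tol) * state.rho[i]:
                warnings.warn(
                    f"grid truncates population {lab}: captured "
                    f"{captured[i]:.6g} of {state.rho[i]:.6g}", RuntimeWarning)
    return n
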