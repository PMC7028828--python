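"""Explicit finite-difference solver for the coupled non-local PDE system

    dn_H/dt = beta_H d2n_H/dx2 + R(x, S(t), rho(t)) n_H
    dn_L/dt = beta_L d2n_L/dx2 + R(x, S(t), rho(t)) n_L

on a truncated trait domain with no-flux boundaries, where
``rho(t) = integral (n_H + n_L) dx`` couples the two equations through the
shared fitness functional ``R = p(x, S) - d rho``.

The scheme is fully explicit forward Euler: a centred three-point stencil
for the diffusion term (no-flux enforced through reflected ghost nodes) and
the reaction evaluated at the current time level, with ``rho`` obtained by
trapezoidal quadrature of the current densities.  This serves as the
independent check of the Gaussian moment reduction in :mod:`.moments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .environment import FitnessModel, NutrientSignal
from .errors import DivergenceError, StabilityError, StateError
from .moments import EXTINCTION_FLOOR, PopulationSpec, _check_pair

__all__ = ["PDEGrid", "DensitySnapshot", "PDESolution",
           "initial_condition", "pde_step", "solve_pde", "compute_moments"]

_NEG_TOL = 1e-12  # tiny negative densities tolerated (round-off), larger aborts


@dataclass(frozen=True)
class PDEGrid:
    """Uniform trait grid and time step.

    Defaults reproduce the reference discretisation: 2000 nodes on
    ``[-5, 5]`` (so ``dx = 10/1999``) and ``dt = 1e-4``.
    """

    x_min: float = -5.0
    x_max: float = 5.0
    n_x: int = 2000
    dt: float = 1e-4
    t_final: float = 10.0

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.n_x < 3:
            raise StateError("need x_max > x_min and at least 3 nodes")
        if self.dt <= 0 or self.t_final < 0:
            raise StateError("need dt > 0 and t_final >= 0")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_x)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n_x - 1)

    def check_diffusion_stability(self, beta_max: float) -> float:
        """Return ``beta_max dt / dx^2``; raise if it exceeds 1/2."""
        number = beta_max * self.dt / self.dx**2
        if number > 0.5:
            raise StabilityError(
                f"diffusion stability violated: beta dt/dx^2 = {number:.3g} > 0.5")
        return number


@dataclass(frozen=True)
class DensitySnapshot:
    """Gridded densities of both populations at one time."""

    t: float
    x: np.ndarray
    n_H: np.ndarray
    n_L: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "n_H", "n_L"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("n_H", "n_L"):
            n = getattr(self, name)
            if n.shape != self.x.shape:
                raise StateError(f"{name} does not match the grid")
            if np.any(n < -_NEG_TOL):
                raise StateError(
                    f"{name} developed negative values beyond round-off at t={self.t}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "n_H": self.n_H, "n_L": self.n_L})


def _check_reaction_stability(R: np.ndarray, beta_max: float, dt: float,
                              dx: float, t: float) -> None:
    """Forward-Euler amplification guard.

    The per-node growth factor of the scheme is
    ``1 + dt R - 4 beta dt/dx^2 sin^2(k dx/2)``; non-divergence requires
    ``dt max(R) < 1`` on the growth side and
    ``dt max(-R) + 4 beta dt/dx^2 < 2`` on the decay side (the strongly
    negative fitness at the domain edges is harmless while the factor
    stays inside (-1, 1))."""
    grow = dt * float(np.max(R, initial=0.0))
    decay = dt * float(np.max(-R, initial=0.0)) + 4.0 * beta_max * dt / dx**2
    if grow >= 1.0 or decay >= 2.0:
        raise StabilityError(
            f"reaction stability violated at t={t:.6g}: dt max(R) = {grow:.3g} "
            f"(limit 1), dt max(-R) + 4 beta dt/dx^2 = {decay:.3g} (limit 2)")


def initial_condition(specs: Sequence[PopulationSpec], grid: PDEGrid) -> DensitySnapshot:
    """Gaussian initial densities from the population specs."""
    sH, sL = _check_pair(specs)
    x = grid.x
    dens = []
    for s in (sH, sL):
        dens.append(s.rho0 * np.sqrt(s.v0 / (2 * np.pi))
                    * np.exp(-0.5 * s.v0 * (x - s.mu0) ** 2))
    return DensitySnapshot(0.0, x, dens[0], dens[1])


def _laplacian(n: np.ndarray, dx: float) -> np.ndarray:
    """Centred three-point Laplacian with no-flux (reflected ghost) boundaries."""
    lap = np.empty_like(n)
    lap[1:-1] = n[2:] - 2.0 * n[1:-1] + n[:-2]
    lap[0] = 2.0 * (n[1] - n[0])  # ghost n[-1] = n[1]
    lap[-1] = 2.0 * (n[-2] - n[-1])
    return lap / dx**2


def pde_step(snapshot: DensitySnapshot, model: FitnessModel, signal: NutrientSignal,
             specs: Sequence[PopulationSpec], grid: PDEGrid) -> DensitySnapshot:
    """One forward-Euler step from ``snapshot.t`` to ``snapshot.t + dt``."""
    sH, sL = _check_pair(specs)
    grid.check_diffusion_stability(max(sH.beta, sL.beta))
    x, dx, dt = snapshot.x, grid.dx, grid.dt
    rho = np.trapezoid(snapshot.n_H + snapshot.n_L, dx=dx)
    R = model.fitness(x, signal(snapshot.t), rho)
    _check_reaction_stability(R, max(sH.beta, sL.beta), dt, dx, snapshot.t)
    new = []
    for n, s in ((snapshot.n_H, sH), (snapshot.n_L, sL)):
        new.append(n + dt * (s.beta * _laplacian(n, dx) + R * n))
    for n in new:
        if not np.all(np.isfinite(n)):
            raise DivergenceError(f"solution diverged (NaN/Inf) at t={snapshot.t + dt}")
    return DensitySnapshot(snapshot.t + dt, x, new[0], new[1])


def compute_moments(snapshot: DensitySnapshot,
                    floor: float = EXTINCTION_FLOOR) -> dict:
    """Trapezoidal size, mean and variance of each population.

    Populations with size below ``floor`` get NaN mean/variance markers.
    """
    x = snapshot.x
    out = {}
    for lab, n in (("H", snapshot.n_H), ("L", snapshot.n_L)):
        rho = float(np.trapezoid(n, x))
        if rho < floor:
            out[lab] = (rho, float("nan"), float("nan"))
            continue
        mu = float(np.trapezoid(x * n, x) / rho)
        var = float(np.trapezoid(x**2 * n, x) / rho - mu**2)
        out[lab] = (rho, mu, max(var, 0.0))
    return out


@dataclass(frozen=True)
class PDESolution:
    """Moment series at every step plus decimated density snapshots."""

    t: np.ndarray
    rho: np.ndarray  # (2, n_steps+1) rows H, L
    mu: np.ndarray
    var: np.ndarray
    snapshots: List[DensitySnapshot] = field(repr=False, default_factory=list)

    def to_frame(self, model: FitnessModel, signal: NutrientSignal) -> pd.DataFrame:
        S = np.asarray(signal(self.t), dtype=float)
        return pd.DataFrame({
            "t": self.t,
            "rho_H": self.rho[0], "rho_L": self.rho[1],
            "mu_H": self.mu[0], "mu_L": self.mu[1],
            "var_H": self.var[0], "var_L": self.var[1],
            "S": S, "g": np.asarray(model.g(S)), "phi": np.asarray(model.phi(S)),
        })


def solve_pde(model: FitnessModel, signal: NutrientSignal,
              specs: Sequence[PopulationSpec], grid: PDEGrid,
              snapshot_every: int = 1000,
              boundary_tol: float = 1e-6) -> PDESolution:
    """Time-march the system to ``grid.t_final``.

    The moment series (size, mean, variance per population) is recorded at
    every time step; full density snapshots are kept every
    ``snapshot_every`` steps (and at the final time) to bound memory.
    Warns when boundary density exceeds ``boundary_tol`` times the peak,
    indicating an inadequate trait domain.
    """
    sH, sL = _check_pair(specs)
    grid.check_diffusion_stability(max(sH.beta, sL.beta))
    x, dx, dt = grid.x, grid.dx, grid.dt
    n_steps = int(round(grid.t_final / dt))
    beta = np.array([sH.beta, sL.beta])

    n = np.vstack([initial_condition(specs, grid).n_H,
                   initial_condition(specs, grid).n_L])
    w = np.full(grid.n_x, dx)  # trapezoid weights
    w[0] = w[-1] = dx / 2

    t = dt * np.arange(n_steps + 1)
    rho = np.empty((2, n_steps + 1))
    mu = np.empty((2, n_steps + 1))
    var = np.empty((2, n_steps + 1))
    snapshots: List[DensitySnapshot] = []
    boundary_flag = False

    def record(k: int) -> None:
        m = n @ w
        rho[:, k] = m
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = ((x * n) @ w) / m
            second = ((x**2 * n) @ w) / m
        dead = m < EXTINCTION_FLOOR
        mean[dead] = np.nan
        mu[:, k] = mean
        var[:, k] = np.maximum(second - mean**2, 0.0)

    record(0)
    if snapshot_every > 0:
        snapshots.append(DensitySnapshot(0.0, x, n[0].copy(), n[1].copy()))

    for k in range(n_steps):
        tk = t[k]
        rho_tot = rho[:, k].sum()
        R = model.fitness(x, signal(tk), rho_tot)
        _check_reaction_stability(R, beta.max(), dt, dx, tk)
        lap = np.empty_like(n)
        lap[:, 1:-1] = n[:, 2:] - 2.0 * n[:, 1:-1] + n[:, :-2]
        lap[:, 0] = 2.0 * (n[:, 1] - n[:, 0])
        lap[:, -1] = 2.0 * (n[:, -2] - n[:, -1])
        n = n + dt * (beta[:, None] * (lap / dx**2) + R * n)
        if not np.all(np.isfinite(n)):
            raise DivergenceError(f"solution diverged (NaN/Inf) at t={tk + dt:.6g}")
        if np.any(n < -_NEG_TOL):
            raise DivergenceError(
                f"densities went negative beyond round-off at t={tk + dt:.6g}")
        record(k + 1)
        if not boundary_flag:
            peak = n.max()
            if peak > 0 and max(n[:, 0].max(), n[:, -1].max()) > boundary_tol * peak:
                boundary_flag = True
        if snapshot_every > 0 and ((k + 1) % snapshot_every == 0 or k + 1 == n_steps):
            snapshots.append(DensitySnapshot(t[k + 1], x, n[0].copy(), n[1].copy()))

    if boundary_flag:
        warnings.warn("boundary density exceeded tolerance: trait domain may be "
                      "too narrow; results near the boundary are unreliable",
                      RuntimeWarning)
    return PDESolution(t=t, rho=rho, mu=mu, var=var, snapshots=snapshots)
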