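"""Closed-form long-time theory for T-periodic environments.

For each population the mean trait relaxes to the unique T-periodic
solution ``u(t)`` of

    u' = 2 sqrt(gamma beta) (phi(t) - u),    u(0) = u(T),

a low-pass-filtered copy of the fittest state ``phi(t)`` whose time
average equals that of ``phi``.  Long-run competitive ability is measured
by the invasion quantity

    Lambda = sqrt(beta) + (sqrt(gamma)/T) * integral_0^T (u - phi)^2 dt,

the sum of a cost of phenotypic variation and a cost of lagging behind the
moving fitness peak.  With the survival threshold
``theta = (sqrt(gamma)/T) integral_0^T g dt``:

* ``min(Lambda_H, Lambda_L) >= theta``  -> both populations die out;
* otherwise the population with the smaller ``Lambda`` excludes the other
  and its size relaxes to the unique nonnegative T-periodic solution
  ``w(t)`` of the periodic logistic equation ``w' = (Q(t) - d w) w`` with
  ``Q = gamma g - sqrt(gamma beta) - gamma (u - phi)^2``, while its
  variance tends to ``sqrt(beta/gamma)``.

For a constant environment ``u == phi``, ``Lambda = sqrt(beta)`` exactly
and the classification reduces to comparing ``sqrt(beta_i)`` with
``sqrt(gamma) * g(S)``, recovering the constant-environment theory.

All exponentials are evaluated with nonpositive exponents (or in log
space, for the cumulative integrals entering ``w``), so that integrated
growth rates of order 10^3 cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .environment import FitnessModel, NutrientSignal
from .errors import AnalyticPreconditionError, SurvivalHypothesisError
from .moments import PopulationSpec, _check_pair

__all__ = [
    "PeriodicSolution", "CompetitionSummary",
    "BOTH_EXTINCT", "H_WINS", "L_WINS", "TIE",
    "periodic_mean_trait", "invasion_lambda", "invasion_lambda_lag_form",
    "survival_threshold", "periodic_size", "classify_outcome", "competition_map",
]

BOTH_EXTINCT = "BOTH_EXTINCT"
H_WINS = "H_WINS"
L_WINS = "L_WINS"
TIE = "TIE"

#: relative tolerance on |Lambda_H - Lambda_L| below which the outcome is a TIE
TIE_RTOL = 1e-10


@dataclass(frozen=True)
class PeriodicSolution:
    """Uniform samples of a T-periodic attractor over one period ``[0, T]``.

    ``T`` is ``None`` for the constant-environment degenerate case, where
    the attractor is a single constant value.
    """

    T: Optional[float]
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def time_average(self) -> float:
        if self.T is None or self.t.size < 2:
            return float(self.values.mean())
        return float(np.trapezoid(self.values, self.t) / self.T)

    def __call__(self, t):
        """Periodic interpolation of the sampled attractor."""
        if self.T is None:
            return np.full_like(np.asarray(t, dtype=float), self.values[0])
        return np.interp(np.mod(t, self.T), self.t, self.values)


def _require(model: FitnessModel) -> None:
    if not model.analytic_valid:
        raise AnalyticPreconditionError("the asymptotic theory requires zeta == gamma")


def _period_grid(signal: NutrientSignal, n_quad: int) -> np.ndarray:
    if not signal.is_periodic:
        raise AnalyticPreconditionError("a periodic nutrient signal is required")
    return np.linspace(0.0, signal.T, n_quad)


def periodic_mean_trait(spec: PopulationSpec, model: FitnessModel,
                        signal: NutrientSignal, n_quad: int = 2001) -> PeriodicSolution:
    """The unique T-periodic mean-trait attractor ``u(t)``.

    Evaluated in the convolution form

        u(t) = 2a [ J(t) + e^{-2at} J(T) / (1 - e^{-2aT}) ],
        J(t) = integral_0^t e^{-2a(t - s)} phi(s) ds,    a = sqrt(gamma beta),

    with ``J`` computed by a one-pole recursion over a uniform period grid
    whose per-interval convolution is exact for piecewise-linear ``phi``
    (an exponential-integrator rule); every exponent is nonpositive.
    Periodicity ``u(0) == u(T)`` holds by construction, and a piecewise
    linear (hence constant) ``phi`` is reproduced exactly.
    """
    _require(model)
    if not signal.is_periodic:
        phi_bar = float(model.phi(signal.M))
        return PeriodicSolution(None, np.array([0.0]), np.array([phi_bar]))
    t = _period_grid(signal, n_quad)
    phi = np.asarray(model.phi(signal(t)), dtype=float)
    a = np.sqrt(model.gamma * spec.beta)
    dt = t[1] - t[0]
    q = np.exp(-2.0 * a * dt)
    # int_0^dt e^{-2a tau} dtau and int_0^dt tau e^{-2a tau} dtau
    I0 = (1.0 - q) / (2.0 * a)
    I1 = (1.0 - q * (1.0 + 2.0 * a * dt)) / (2.0 * a) ** 2
    b = np.zeros_like(phi)
    b[1:] = phi[1:] * I0 - (phi[1:] - phi[:-1]) / dt * I1
    J = lfilter([1.0], [1.0, -q], b)  # J_k = q J_{k-1} + b_k
    decay = np.exp(-2.0 * a * t)
    qT = np.exp(-2.0 * a * signal.T)
    u = 2.0 * a * (J + decay * J[-1] / (1.0 - qT))
    return PeriodicSolution(signal.T, t, u)


def survival_threshold(model: FitnessModel, signal: NutrientSignal,
                       n_quad: int = 2001) -> float:
    """``(sqrt(gamma)/T) integral_0^T g(t) dt`` (just ``sqrt(gamma) g(S)``
    for a constant signal)."""
    _require(model)
    if not signal.is_periodic:
        return float(np.sqrt(model.gamma) * model.g(signal.M))
    t = _period_grid(signal, n_quad)
    g = np.asarray(model.g(signal(t)), dtype=float)
    return float(np.sqrt(model.gamma) / signal.T * np.trapezoid(g, t))


def invasion_lambda(spec: PopulationSpec, model: FitnessModel,
                    signal: NutrientSignal, n_quad: int = 2001) -> float:
    """Invasion quantity ``Lambda = sqrt(beta) + (sqrt(gamma)/T) int (u - phi)^2 dt``.

    Exactly ``sqrt(beta)`` for a constant signal (zero lag integrand).
    """
    _require(model)
    if not signal.is_periodic:
        return float(np.sqrt(spec.beta))
    u = periodic_mean_trait(spec, model, signal, n_quad)
    phi = np.asarray(model.phi(signal(u.t)), dtype=float)
    lag = np.trapezoid((u.values - phi) ** 2, u.t)
    return float(np.sqrt(spec.beta) + np.sqrt(model.gamma) / signal.T * lag)


def invasion_lambda_lag_form(spec: PopulationSpec, model: FitnessModel,
                             signal: NutrientSignal, n_quad: int = 2001) -> float:
    """Equivalent form ``Lambda = sqrt(beta) + (1/(2 sqrt(beta) T)) int (phi - u) phi' dt``.

    Obtained by integrating the lag dynamics over one period; used as a
    cross-check of :func:`invasion_lambda`.
    """
    _require(model)
    if not signal.is_periodic:
        return float(np.sqrt(spec.beta))
    u = periodic_mean_trait(spec, model, signal, n_quad)
    S = np.asarray(signal(u.t), dtype=float)
    phi = np.asarray(model.phi(S), dtype=float)
    phi_dot = np.asarray(model.phi_prime_of_S(S), dtype=float) * np.asarray(
        signal.derivative(u.t), dtype=float)
    integral = np.trapezoid((phi - u.values) * phi_dot, u.t)
    return float(np.sqrt(spec.beta)
                 + integral / (2.0 * np.sqrt(spec.beta) * signal.T))


def _log_expm1(c: float) -> float:
    """log(e^c - 1) for c > 0, safe for large c."""
    if c > 36.0:  # e^{-c} below double precision: log(e^c - 1) == c
        return c
    return float(np.log(np.expm1(c)))


def periodic_size(spec: PopulationSpec, model: FitnessModel,
                  signal: NutrientSignal, n_quad: int = 2001) -> PeriodicSolution:
    """The unique nonnegative T-periodic size attractor ``w(t)``.

    Closed form of the periodic logistic equation,

        w(t) = d^{-1} e^{C(t)} / [ I(T)/(e^{C(T)} - 1) + I(t) ],
        C(t) = int_0^t Q,   I(t) = int_0^t e^{C(s)} ds,

    evaluated entirely in log space (running log-sum-exp for ``I``) since
    ``C(T)`` reaches O(10^3) for realistic parameters.  Requires
    ``Lambda < threshold``; otherwise the attractor is the zero solution
    and a :class:`SurvivalHypothesisError` is raised.
    """
    _require(model)
    lam = invasion_lambda(spec, model, signal, n_quad)
    theta = survival_threshold(model, signal, n_quad)
    if not lam < theta:
        raise SurvivalHypothesisError(
            f"Lambda = {lam:.6g} >= threshold = {theta:.6g}: the periodic size "
            "attractor is the zero solution")
    if not signal.is_periodic:
        g_bar = float(model.g(signal.M))
        w_bar = (model.gamma * g_bar - np.sqrt(model.gamma * spec.beta)) / model.d
        return PeriodicSolution(None, np.array([0.0]), np.array([w_bar]))

    t = _period_grid(signal, n_quad)
    dt = t[1] - t[0]
    S = np.asarray(signal(t), dtype=float)
    g = np.asarray(model.g(S), dtype=float)
    u = periodic_mean_trait(spec, model, signal, n_quad)
    phi = np.asarray(model.phi(S), dtype=float)
    Q = (model.gamma * g - np.sqrt(model.gamma * spec.beta)
         - model.gamma * (u.values - phi) ** 2)

    # C_k = int_0^{t_k} Q (trapezoid)
    C = np.concatenate([[0.0], np.cumsum(0.5 * dt * (Q[:-1] + Q[1:]))])
    # per-interval log int e^{C(s)} ds, exact for piecewise-linear C:
    # int_{t_k}^{t_{k+1}} e^C ds = dt e^{C_k} (e^{dC} - 1)/dC
    dC = C[1:] - C[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(np.abs(np.expm1(dC))) - np.log(np.abs(dC))
    seg = C[:-1] + np.log(dt) + np.where(np.abs(dC) > 1e-10, ratio, 0.5 * dC)
    # logI_k = log int_0^{t_k} e^{C(s)} ds, cumulative log-sum-exp
    logI = np.concatenate([[-np.inf], np.logaddexp.accumulate(seg)])
    logA0 = logI[-1] - _log_expm1(C[-1])  # C(T) > 0 given Lambda < theta
    logw = -np.log(model.d) + C - np.logaddexp(logA0, logI)
    return PeriodicSolution(signal.T, t, np.exp(logw))


@dataclass(frozen=True)
class CompetitionSummary:
    """Outcome of the competition and the winner's asymptotic attractors."""

    Lambda_H: float
    Lambda_L: float
    threshold: float
    outcome: str
    winner: Optional[str]  # "H", "L" or None
    u: Optional[PeriodicSolution]  # winner's periodic mean trait
    w: Optional[PeriodicSolution]  # winner's periodic size
    sigma2_inf: Optional[float]  # winner's limit variance sqrt(beta/gamma)
    mean_trait: Optional[float]  # time average of u == time average of phi
    mean_size: Optional[float]  # (sqrt(gamma)/d) (threshold - Lambda_winner)

    def as_dict(self) -> dict:
        return {
            "Lambda_H": self.Lambda_H, "Lambda_L": self.Lambda_L,
            "threshold": self.threshold, "outcome": self.outcome,
            "winner": self.winner, "sigma2_inf": self.sigma2_inf,
            "mean_trait": self.mean_trait, "mean_size": self.mean_size,
        }


def classify_outcome(specs: Sequence[PopulationSpec], model: FitnessModel,
                     signal: NutrientSignal, n_quad: int = 2001) -> CompetitionSummary:
    """Predict which population survives and its long-time attractors.

    Joint extinction when ``min(Lambda_H, Lambda_L) >= threshold`` (weak
    inequality, as in the theory); otherwise the population with the
    strictly smaller ``Lambda`` wins.  Equality of the two Lambdas within
    ``TIE_RTOL`` relative is reported as a TIE without claiming dynamics.
    """
    _require(model)
    sH, sL = _check_pair(specs)
    lamH = invasion_lambda(sH, model, signal, n_quad)
    lamL = invasion_lambda(sL, model, signal, n_quad)
    theta = survival_threshold(model, signal, n_quad)

    if min(lamH, lamL) >= theta:
        return CompetitionSummary(lamH, lamL, theta, BOTH_EXTINCT, None,
                                  None, None, None, None, None)
    if abs(lamH - lamL) < TIE_RTOL * max(abs(lamH), abs(lamL)):
        return CompetitionSummary(lamH, lamL, theta, TIE, None,
                                  None, None, None, None, None)
    winner, lam_w = (("H", lamH) if lamH < lamL else ("L", lamL))
    spec_w = sH if winner == "H" else sL
    u = periodic_mean_trait(spec_w, model, signal, n_quad)
    w = periodic_size(spec_w, model, signal, n_quad)
    return CompetitionSummary(
        lamH, lamL, theta,
        H_WINS if winner == "H" else L_WINS, winner, u, w,
        sigma2_inf=float(np.sqrt(spec_w.beta / model.gamma)),
        mean_trait=u.time_average,
        mean_size=float(np.sqrt(model.gamma) / model.d * (theta - lam_w)),
    )


def competition_map(model: FitnessModel, M: float, A: float,
                    beta_H_grid: np.ndarray, T_grid: np.ndarray,
                    beta_L: float = 0.01,
                    n_quad: int = 2001) -> Tuple[np.ndarray, np.ndarray]:
    """Sign map of ``Lambda_H - Lambda_L`` over a (T, beta_H) grid.

    Returns ``(signs, diffs)`` of shape ``(len(T_grid), len(beta_H_grid))``:
    ``+1`` where the low-variation population wins (``Lambda_L < Lambda_H``),
    ``-1`` where the high-variation population wins, ``0`` for ties.
    """
    _require(model)
    beta_H_grid = np.asarray(beta_H_grid, dtype=float)
    T_grid = np.asarray(T_grid, dtype=float)
    diffs = np.empty((T_grid.size, beta_H_grid.size))
    for i, T in enumerate(T_grid):
        signal = NutrientSignal("sinusoidal", M=M, A=A, T=float(T))
        lamL = invasion_lambda(PopulationSpec("L", beta_L), model, signal, n_quad)
        for j, bH in enumerate(beta_H_grid):
            lamH = invasion_lambda(PopulationSpec("H", bH), model, signal, n_quad)
            diffs[i, j] = lamH - lamL
    scale = np.maximum(np.abs(diffs), 1.0)
    signs = np.sign(diffs)
    signs[np.abs(diffs) < TIE_RTOL * scale] = 0.0
    return signs, diffs
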