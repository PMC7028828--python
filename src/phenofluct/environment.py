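"""Nutrient signal and phenotypic fitness landscape.

The environment is a given nonnegative nutrient concentration ``S(t)``,
either constant, sinusoidal ``S(t) = M + A sin(2 pi t / T)`` with
``0 <= A <= M``, or an arbitrary user-supplied T-periodic sampled signal.

The fitness landscape is the net proliferation rate

    p(x, S) = gamma * S/(1+S) * (1 - x^2) + zeta * (1 - S/(1+S)) * (1 - (1-x)^2)

with ``0 < zeta <= gamma``, which completes the square as

    p(x, S) = gamma * g(S) - h(S) * (x - phi(S))^2,

where ``phi(S)`` is the fittest phenotypic state, ``gamma * g(S)`` the
maximum fitness and ``h(S)`` the selection gradient.  Competition adds a
death term ``-d * rho`` proportional to the total population size, giving
the fitness functional ``R(x, S, rho) = p(x, S) - d * rho``.

Most of the analytic machinery in the rest of the package assumes
``zeta == gamma`` (flag :attr:`FitnessModel.analytic_valid`), under which
``g(S) = (S + 1/(1+S))/(1+S)``, ``phi(S) = 1/(1+S)`` and ``h(S) == gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidSignalError

__all__ = [
    "NutrientSignal",
    "FitnessModel",
    "evaluate_nutrient",
    "rescaled_max_fitness",
    "fittest_state",
    "selection_gradient",
    "net_proliferation",
    "fitness_functional",
]

# floating slack below which a slightly negative concentration is clamped to 0
_NEG_CLAMP = 1e-12
# relative tolerance on endpoint periodicity of user-supplied sampled signals
_PERIODICITY_RTOL = 1e-9


@dataclass(frozen=True)
class NutrientSignal:
    """Nonnegative nutrient concentration ``S(t)``.

    Parameters
    ----------
    kind :
        ``"constant"``, ``"sinusoidal"`` or ``"user-periodic"``.
    M :
        Mean concentration (dimensionless, >= 0).
    A :
        Semi-amplitude of the oscillations (0 for constant signals).
    T :
        Period (> 0); ``None`` for constant signals.
    times, values :
        For ``"user-periodic"`` only: samples of one period on ``[0, T]``,
        linearly interpolated and extended periodically.  The endpoint
        values must agree to within ``1e-9`` relative.
    """

    kind: str = "constant"
    M: float = 1.0
    A: float = 0.0
    T: Optional[float] = None
    times: Optional[np.ndarray] = field(default=None, repr=False)
    values: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoidal", "user-periodic"):
            raise InvalidSignalError(f"unknown signal kind {self.kind!r}")
        if self.kind == "constant":
            if self.M < 0:
                raise InvalidSignalError("constant signal requires M >= 0")
            if self.A != 0:
                raise InvalidSignalError("constant signal requires A = 0")
            object.__setattr__(self, "T", None)
            return
        if self.T is None or self.T <= 0:
            raise InvalidSignalError("periodic signal requires a period T > 0")
        if self.kind == "sinusoidal":
            if self.A < 0 or self.A > self.M:
                raise InvalidSignalError(
                    f"sinusoidal signal requires 0 <= A <= M, got A={self.A}, M={self.M}"
                )
        else:  # user-periodic
            if self.times is None or self.values is None:
                raise InvalidSignalError("user-periodic signal requires samples")
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 3:
                raise InvalidSignalError("need matching 1-d sample arrays (>= 3 points)")
            if not (np.all(np.diff(t) > 0) and t[0] == 0.0 and np.isclose(t[-1], self.T)):
                raise InvalidSignalError("sample times must increase from 0 to T")
            if np.any(v < -_NEG_CLAMP):
                raise InvalidSignalError("sampled concentrations must be nonnegative")
            scale = max(abs(v[0]), abs(v[-1]), 1.0)
            if abs(v[0] - v[-1]) > _PERIODICITY_RTOL * scale:
                raise InvalidSignalError("endpoint values violate periodicity")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "values", np.clip(v, 0.0, None))
            object.__setattr__(self, "M", float(np.trapezoid(v, t) / self.T))
            object.__setattr__(self, "A", float((v.max() - v.min()) / 2))

    @property
    def is_periodic(self) -> bool:
        return self.kind != "constant"

    def __call__(self, t):
        """Evaluate ``S(t)``; accepts scalars or arrays, requires ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("time must be nonnegative")
        if self.kind == "constant":
            out = np.full_like(t, self.M)
        elif self.kind == "sinusoidal":
            out = self.M + self.A * np.sin(2.0 * np.pi * t / self.T)
        else:
            out = np.interp(np.mod(t, self.T), self.times, self.values)
        out = np.where((out < 0) & (out > -_NEG_CLAMP), 0.0, out)
        return out if out.ndim else float(out)

    def derivative(self, t):
        """``dS/dt``; analytic for constant/sinusoidal, central difference
        (step ``T * 1e-6``) for sampled signals."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.zeros_like(t)
        elif self.kind == "sinusoidal":
            w = 2.0 * np.pi / self.T
            out = self.A * w * np.cos(w * t)
        else:
            h = self.T * 1e-6
            tp = np.mod(t + h, self.T)
            tm = np.mod(t - h, self.T)
            out = (np.interp(tp, self.times, self.values)
                   - np.interp(tm, self.times, self.values)) / (2 * h)
        return out if out.ndim else float(out)


def _check_S(S):
    S = np.asarray(S, dtype=float)
    if np.any(S < -_NEG_CLAMP):
        raise DomainError("nutrient concentration must be nonnegative")
    return np.clip(S, 0.0, None)


@dataclass(frozen=True)
class FitnessModel:
    """Fitness-landscape parameters gamma, zeta, d.

    ``gamma`` and ``zeta`` are the maximum proliferation rates of the
    variants best adapted to nutrient-rich (x -> 0) and nutrient-scarce
    (x -> 1) conditions; ``d`` scales the density-dependent death rate.
    """

    gamma: float = 100.0
    zeta: Optional[float] = None
    d: float = 0.01

    def __post_init__(self) -> None:
        if self.zeta is None:
            object.__setattr__(self, "zeta", self.gamma)
        if not (0 < self.zeta <= self.gamma):
            raise DomainError(f"need 0 < zeta <= gamma, got zeta={self.zeta}, gamma={self.gamma}")
        if self.d <= 0:
            raise DomainError("competition death-rate coefficient d must be positive")

    @property
    def analytic_valid(self) -> bool:
        """True iff zeta == gamma, the regime where the Gaussian closure and
        the asymptotic theory hold."""
        return self.zeta == self.gamma

    # --- derived landscape functions -------------------------------------

    def g(self, S):
        """Rescaled maximum fitness g(S) = (S + (zeta/gamma) zeta/(zeta+gamma S))/(1+S)."""
        S = _check_S(S)
        return (S + (self.zeta / self.gamma) * self.zeta / (self.zeta + self.gamma * S)) / (1.0 + S)

    def phi(self, S):
        """Fittest phenotypic state phi(S) = zeta/(zeta + gamma S), in [0, 1]."""
        S = _check_S(S)
        return self.zeta / (self.zeta + self.gamma * S)

    def h(self, S):
        """Selection gradient h(S) = zeta + (gamma - zeta) S/(1+S); == gamma when zeta == gamma."""
        S = _check_S(S)
        return self.zeta + (self.gamma - self.zeta) * S / (1.0 + S)

    def phi_prime_of_S(self, S):
        """d phi / d S = -gamma zeta / (zeta + gamma S)^2 (used via the chain rule)."""
        S = _check_S(S)
        return -self.gamma * self.zeta / (self.zeta + self.gamma * S) ** 2

    def p(self, x, S):
        """Net proliferation rate p(x, S) in its defining (weighted-parabolas) form."""
        S = _check_S(S)
        x = np.asarray(x, dtype=float)
        frac = S / (1.0 + S)
        return self.gamma * frac * (1.0 - x**2) + self.zeta * (1.0 - frac) * (1.0 - (1.0 - x) ** 2)

    def fitness(self, x, S, rho_total):
        """Fitness functional R(x, S, rho) = p(x, S) - d * rho."""
        if np.any(np.asarray(rho_total) < 0):
            raise DomainError("total population size must be nonnegative")
        return self.p(x, S) - self.d * np.asarray(rho_total, dtype=float)


# --- thin functional interface -------------------------------------------

def evaluate_nutrient(signal: NutrientSignal, t):
    """Concentration ``S(t)`` of the given signal."""
    return signal(t)


def rescaled_max_fitness(model: FitnessModel, S):
    return model.g(S)


def fittest_state(model: FitnessModel, S):
    return model.phi(S)


def selection_gradient(model: FitnessModel, S):
    return model.h(S)


def net_proliferation(model: FitnessModel, x, S):
    return model.p(x, S)


def fitness_functional(model: FitnessModel, x, S, rho_total):
    return model.fitness(x, S, rho_total)
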