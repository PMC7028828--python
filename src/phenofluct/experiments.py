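"""Reproducible experiment layer: canonical fixtures, config parsing and
artifact writers.

Each experiment is described by a small YAML document with blocks
``fitness``, ``nutrient``, ``populations``, and (depending on mode)
``grid``, ``solver`` or ``sweep``.  The canonical parameter set is
gamma = 100, d = 0.01, beta_L = 0.01, beta_H in [0.01, 0.1], with both
populations starting from the same Gaussian (rho0 = 800, mu0 = 0, v0 = 20);
fixture ids cover the standard scenarios: constant nutrient, low and high
sinusoidal variability, sign-map sweeps and high-amplitude regimes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymptotics import classify_outcome, competition_map
from .environment import FitnessModel, NutrientSignal
from .errors import ConfigError, InvalidSignalError
from .moments import PopulationSpec, solve_cauchy
from .pde import PDEGrid, solve_pde

__all__ = ["ExperimentConfig", "FIXTURE_IDS", "fixture_config", "load_config",
           "run_experiment"]

log = logging.getLogger("phenofluct")

_MODES = ("simulate-ode", "simulate-pde", "asymptotics", "sweep")

_TOP_KEYS = {"experiment", "mode", "fitness", "nutrient", "populations",
             "grid", "solver", "sweep", "seed"}
_BLOCK_KEYS = {
    "fitness": {"gamma", "zeta", "d"},
    "nutrient": {"kind", "M", "A", "T"},
    "grid": {"x_min", "x_max", "n_x", "dt", "t_final", "snapshot_every"},
    "solver": {"t_final", "n_samples", "rtol", "atol", "method"},
    "sweep": {"beta_H_min", "beta_H_max", "n_beta_H", "T_min", "T_max",
              "n_T", "n_quad"},
}
_POP_KEYS = {"beta", "rho0", "mu0", "v0"}

# Table-style defaults shared by every fixture
_BASE = {
    "fitness": {"gamma": 100.0, "zeta": 100.0, "d": 0.01},
    "populations": {
        "H": {"beta": 0.025, "rho0": 800.0, "mu0": 0.0, "v0": 20.0},
        "L": {"beta": 0.01, "rho0": 800.0, "mu0": 0.0, "v0": 20.0},
    },
    "seed": 0,
}

_SWEEP_DEFAULT = {"beta_H_min": 0.0118, "beta_H_max": 0.1, "n_beta_H": 50,
                  "T_min": 1.0, "T_max": 20.0, "n_T": 50, "n_quad": 2001}

# final times chosen per fixture so transients visibly settle
_FIXTURES = {
    "fig3a": {"mode": "simulate-ode",
              "nutrient": {"kind": "constant", "M": 1.0, "A": 0.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig3b": {"mode": "simulate-ode",
              "nutrient": {"kind": "sinusoidal", "M": 1.0, "A": 0.5, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig3c": {"mode": "simulate-ode",
              "nutrient": {"kind": "sinusoidal", "M": 1.0, "A": 1.0, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig4a": {"mode": "sweep",
              "nutrient": {"kind": "sinusoidal", "M": 60.0, "A": 10.0, "T": 5.0}},
    "fig4b": {"mode": "sweep",
              "nutrient": {"kind": "sinusoidal", "M": 1.0, "A": 0.5, "T": 5.0}},
    "fig4c": {"mode": "sweep",
              "nutrient": {"kind": "sinusoidal", "M": 10.0, "A": 10.0, "T": 5.0}},
    "fig5a": {"mode": "simulate-pde",
              "nutrient": {"kind": "sinusoidal", "M": 70.0, "A": 20.0, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig5b": {"mode": "simulate-pde",
              "nutrient": {"kind": "sinusoidal", "M": 50.0, "A": 50.0, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig5c": {"mode": "simulate-pde",
              "nutrient": {"kind": "sinusoidal", "M": 10.0, "A": 10.0, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
    "fig5d": {"mode": "simulate-pde",
              "nutrient": {"kind": "sinusoidal", "M": 0.1, "A": 0.1, "T": 5.0},
              "grid": {"t_final": 10.0}, "solver": {"t_final": 10.0}},
}

FIXTURE_IDS = tuple(sorted(_FIXTURES))

_GRID_DEFAULT = {"x_min": -5.0, "x_max": 5.0, "n_x": 2000, "dt": 1e-4,
                 "t_final": 10.0, "snapshot_every": 1000}
_SOLVER_DEFAULT = {"t_final": 10.0, "n_samples": 1000, "rtol": 1e-8,
                   "atol": 1e-10, "method": "RK45"}

#: reduced-resolution profile for quick end-to-end runs
SMOKE_OVERRIDES = {"grid": {"n_x": 400, "dt": 5e-4, "t_final": 2.0,
                            "snapshot_every": 1000},
                   "solver": {"t_final": 2.0},
                   "sweep": {"n_beta_H": 5, "n_T": 5, "n_quad": 501}}


def _check_keys(name: str, block: dict, allowed: set) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r} block: {sorted(unknown)}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated, fully resolved experiment description."""

    experiment: str
    mode: str
    fitness: dict
    nutrient: dict
    populations: dict
    grid: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    seed: int = 0  # reserved; the model is deterministic

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        _check_keys("top-level", raw, _TOP_KEYS)
        mode = raw.get("mode")
        if mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {mode!r}")
        for block in ("fitness", "nutrient", "populations"):
            if block not in raw:
                raise ConfigError(f"missing required {block!r} block")
        for block in ("fitness", "nutrient", "grid", "solver", "sweep"):
            if block in raw:
                _check_keys(block, raw[block], _BLOCK_KEYS[block])
        pops = raw["populations"]
        if set(pops) != {"H", "L"}:
            raise ConfigError("populations block must define exactly 'H' and 'L'")
        for lab in ("H", "L"):
            _check_keys(f"populations.{lab}", pops[lab], _POP_KEYS)
        cfg = cls(
            experiment=raw.get("experiment", "custom"),
            mode=mode,
            fitness={**_BASE["fitness"], **raw["fitness"]},
            nutrient=dict(raw["nutrient"]),
            populations={lab: {**_BASE["populations"][lab], **pops[lab]}
                         for lab in ("H", "L")},
            grid={**_GRID_DEFAULT, **raw.get("grid", {})},
            solver={**_SOLVER_DEFAULT, **raw.get("solver", {})},
            sweep={**_SWEEP_DEFAULT, **raw.get("sweep", {})},
            seed=int(raw.get("seed", 0)),
        )
        # fail fast on invalid physical parameters
        cfg.model()
        cfg.signal()
        cfg.specs()
        return cfg

    def to_dict(self) -> dict:
        return {"experiment": self.experiment, "mode": self.mode,
                "fitness": dict(self.fitness), "nutrient": dict(self.nutrient),
                "populations": {k: dict(v) for k, v in self.populations.items()},
                "grid": dict(self.grid), "solver": dict(self.solver),
                "sweep": dict(self.sweep), "seed": self.seed}

    def with_profile(self, profile: str) -> "ExperimentConfig":
        if profile == "paper":
            return self
        if profile != "smoke":
            raise ConfigError(f"unknown profile {profile!r}")
        raw = self.to_dict()
        for block, over in SMOKE_OVERRIDES.items():
            raw[block] = {**raw[block], **over}
        return ExperimentConfig.from_dict(raw)

    # --- resolved model objects ------------------------------------------

    def model(self) -> FitnessModel:
        return FitnessModel(**self.fitness)

    def signal(self) -> NutrientSignal:
        try:
            return NutrientSignal(**self.nutrient)
        except InvalidSignalError as exc:
            raise ConfigError(f"invalid nutrient block: {exc}") from exc

    def specs(self) -> Tuple[PopulationSpec, PopulationSpec]:
        return tuple(PopulationSpec(label=lab, **self.populations[lab])
                     for lab in ("H", "L"))

    def pde_grid(self) -> PDEGrid:
        g = {k: v for k, v in self.grid.items() if k != "snapshot_every"}
        return PDEGrid(**g)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def fixture_config(experiment_id: str) -> ExperimentConfig:
    """Canonical config for one of the shipped experiment ids."""
    if experiment_id not in _FIXTURES:
        raise ConfigError(
            f"unknown experiment id {experiment_id!r}; available: {list(FIXTURE_IDS)}")
    fx = _FIXTURES[experiment_id]
    raw = {"experiment": experiment_id, "mode": fx["mode"],
           "fitness": dict(_BASE["fitness"]),
           "nutrient": dict(fx["nutrient"]),
           "populations": {k: dict(v) for k, v in _BASE["populations"].items()},
           "seed": _BASE["seed"]}
    for block in ("grid", "solver", "sweep"):
        if block in fx:
            raw[block] = dict(fx[block])
    return ExperimentConfig.from_dict(raw)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    cfg = ExperimentConfig.from_dict(raw)
    log.info("loaded config %s (experiment=%s, mode=%s)", path, cfg.experiment, cfg.mode)
    return cfg


def _write_manifest(cfg: ExperimentConfig, out: Path, artifacts: list) -> Path:
    manifest = {"package": "phenofluct", "version": __version__,
                "config_hash": cfg.config_hash(), "artifacts": artifacts,
                "config": cfg.to_dict()}
    path = out / "manifest.yaml"
    with path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_manifest_config(path) -> ExperimentConfig:
    """Re-load the exact config recorded in a run manifest."""
    with Path(path).open() as fh:
        manifest = yaml.safe_load(fh)
    return ExperimentConfig.from_dict(manifest["config"])


def run_experiment(cfg: ExperimentConfig, out_dir, profile: str = "paper") -> dict:
    """Dispatch the configured computation and write its artifacts.

    Returns a summary dict (also written as ``summary.json``); all file
    outputs are deterministic for identical configs on identical platforms
    (bitwise floating-point reproducibility is platform-dependent).
    """
    cfg = cfg.with_profile(profile)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, signal, specs = cfg.model(), cfg.signal(), cfg.specs()
    artifacts: list = []
    summary: dict = {"experiment": cfg.experiment, "mode": cfg.mode,
                     "profile": profile}

    outcome = None
    if cfg.mode in ("simulate-ode", "simulate-pde", "asymptotics"):
        outcome = classify_outcome(specs, model, signal)
        summary["classification"] = outcome.as_dict()

    if cfg.mode == "simulate-ode":
        s = cfg.solver
        traj = solve_cauchy(specs, model, signal, t_final=s["t_final"],
                            n_samples=s["n_samples"], rtol=s["rtol"],
                            atol=s["atol"], method=s["method"])
        path = out / "moments_ode.csv"
        traj.to_frame().to_csv(path, index=False)
        artifacts.append(path.name)
        summary["final"] = {"t": float(traj.t[-1]),
                            "rho_H": float(traj.rho[0, -1]),
                            "rho_L": float(traj.rho[1, -1]),
                            "mu_H": float(traj.mu[0, -1]),
                            "mu_L": float(traj.mu[1, -1]),
                            "var_H": float(traj.sigma2[0, -1]),
                            "var_L": float(traj.sigma2[1, -1])}
    elif cfg.mode == "simulate-pde":
        grid = cfg.pde_grid()
        stab = grid.check_diffusion_stability(max(s.beta for s in specs))
        log.info("stability: beta dt/dx^2 = %.4g, dt = %.4g", stab, grid.dt)
        sol = solve_pde(model, signal, specs, grid,
                        snapshot_every=cfg.grid["snapshot_every"])
        path = out / "moments_pde.csv"
        sol.to_frame(model, signal).to_csv(path, index=False)
        artifacts.append(path.name)
        dens = out / "densities.csv"
        pd.concat([s.to_frame() for s in sol.snapshots]).to_csv(dens, index=False)
        artifacts.append(dens.name)
        summary["final"] = {"t": float(sol.t[-1]),
                            "rho_H": float(sol.rho[0, -1]),
                            "rho_L": float(sol.rho[1, -1])}
    elif cfg.mode == "asymptotics":
        if outcome.u is not None:
            summary["u_samples"] = {"t": outcome.u.t.tolist()[:: max(1, outcome.u.t.size // 100)],
                                    "values": outcome.u.values.tolist()[:: max(1, outcome.u.t.size // 100)]}
            summary["w_samples"] = {"t": outcome.w.t.tolist()[:: max(1, outcome.w.t.size // 100)],
                                    "values": outcome.w.values.tolist()[:: max(1, outcome.w.t.size // 100)]}
    elif cfg.mode == "sweep":
        sw = cfg.sweep
        beta_H = np.linspace(sw["beta_H_min"], sw["beta_H_max"], sw["n_beta_H"])
        T_grid = np.linspace(sw["T_min"], sw["T_max"], sw["n_T"])
        signs, diffs = competition_map(model, cfg.nutrient["M"], cfg.nutrient["A"],
                                       beta_H, T_grid,
                                       beta_L=cfg.populations["L"]["beta"],
                                       n_quad=sw["n_quad"])
        cols = [f"{b:.6g}" for b in beta_H]
        for name, mat in (("sign_map.csv", signs), ("lambda_diff.csv", diffs)):
            frame = pd.DataFrame(mat, index=[f"{T:.6g}" for T in T_grid], columns=cols)
            frame.index.name = "T"
            frame.to_csv(out / name)
            artifacts.append(name)
        summary["sweep"] = {"n_plus": int((signs > 0).sum()),
                            "n_minus": int((signs < 0).sum()),
                            "n_tie": int((signs == 0).sum())}

    spath = out / "summary.json"
    with spath.open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts.append(spath.name)
    _write_manifest(cfg, out, sorted(artifacts))
    return summary
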