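# Methods

## Model and assumptions

Two well-mixed asexual populations, labelled `H` (high variation rate) and
`L` (low), are structured by a continuous phenotype `x ∈ ℝ` with densities
`n_H(x,t)`, `n_L(x,t)`. Spontaneous heritable phenotypic variation is
modelled as linear diffusion in trait space with coefficients
`β_H > β_L > 0`; reproduction and death enter through a shared fitness
functional

```
R(x, S, ρ) = p(x, S) − d ρ,
p(x, S) = γ S/(1+S) (1 − x²) + ζ (1 − S/(1+S)) (1 − (1−x)²),
```

with `0 < ζ ≤ γ` and total size `ρ(t) = ρ_H + ρ_L` (logistic-type
competition between and within populations; `d` sets the carrying scale).
The two weighted parabolas encode the assumption that `x → 0` is optimal
under nutrient abundance and `x → 1` under starvation; completing the square
gives `p = γ g(S) − h(S)(x − φ(S))²` with fittest state
`φ(S) = ζ/(ζ + γS) ∈ [0,1]`, rescaled maximum fitness `g`, and selection
gradient `h`. The environment is an externally prescribed nonnegative
nutrient signal; no consumption feedback, no spatial structure, no
stochastic environments (all out of scope by design).

The analytic machinery — the Gaussian reduction and everything built on it —
requires `ζ = γ`, under which `φ = 1/(1+S)`, `g = (S + 1/(1+S))/(1+S)` and
`h ≡ γ`. The landscape module and the PDE solver accept `ζ < γ` (the general
landscape is useful on its own); the analytic modules check
`FitnessModel.analytic_valid` and refuse otherwise, since a non-constant `h`
breaks the closure.

Useful landscape facts (all asserted in tests): `φ` is strictly decreasing
with `φ(0) = 1`; `g` attains its minimum `3/4` at `S = 1`, approaches `1` at
both extremes, and stays strictly below `2` — that uniform bound is what
caps population sizes at `2γ/d`.

## Exact Gaussian reduction

If both initial densities are Gaussian (`ρ⁰ = 800`, `μ⁰ = 0`, `v⁰ = 20` in
the canonical setup) and `ζ = γ`, each density remains Gaussian for all time
with size `ρ_i`, mean `μ_i` and inverse variance `v_i` solving

```
v_i'  = 2(γ − β_i v_i²)
μ_i'  = (2γ/v_i)(φ(t) − μ_i)
ρ_i'  = (F_i − dρ) ρ_i,     F_i = γ g(t) − γ/v_i − γ(μ_i − φ(t))².
```

`v_i` is autonomous with closed form relaxing to `√(γ/β_i)` at rate
`4√(γβ_i)`; the closed form is exposed separately and cross-checked against
the integrated solution to 10⁻⁶ relative. The 6-d system is integrated with
an adaptive explicit Runge–Kutta 4(5) pair (`rtol 1e-8`, `atol 1e-10`),
resampled on a uniform output grid (default 10³ intervals). The system is
non-stiff for the canonical parameters; for very large `β` the `v`-equation
becomes fast, and rejected trial stages of the integrator may overshoot
`v ≤ 0` — the internal right-hand side clamps `v` to a tiny positive value
in that case (which inflates the error estimate and forces rejection) while
the public `moment_rhs` keeps the strict positivity contract. Extinction is
*reported* below a floor of 10⁻⁶ individuals but never enforced: the
dynamics keep `ρ_i > 0` exactly.

## Finite-difference PDE solver

Fully explicit forward Euler on a uniform trait grid, defaults
`x ∈ [−5, 5]` with 2000 nodes (both endpoints included, `Δx = 10/1999`) and
`Δt = 1e-4`: centred three-point Laplacian; no-flux boundaries by
second-order ghost-node reflection; reaction evaluated at the current time
level with `S(t_k)`; the non-local coupling `ρ(t_k)` computed by the same
trapezoidal rule used for the diagnostic moments, so coupling and
diagnostics cannot drift apart. Moments are recorded at every step; full
density snapshots are decimated (default every 10³ steps) to bound memory.

Stability is guarded at every step by the von Neumann bounds for this
scheme: `β Δt/Δx² ≤ 1/2` for diffusion, and for the reaction
`Δt·max(R₊) < 1` (growth side) together with
`Δt·max(−R) + 4βΔt/Δx² < 2` (decay side). The decay-side form matters: on
the default domain the fitness at the edges is ≈ −3000, yet the scheme is
contractive there as long as the amplification factor stays inside (−1, 1);
a naive `Δt·max|R| < 1` guard would spuriously reject resolutions that are
demonstrably convergent (the reduced-resolution profile below sits at
`Δt·max(−R) ≈ 1.5`). Tiny negative densities within 10⁻¹² of zero are
tolerated as round-off; anything larger, or any NaN/Inf, aborts with the
offending time. A warning is emitted if boundary density exceeds 10⁻⁶ of
the peak (domain too narrow).

Resolution choices used by the suite: the PDE↔ODE equivalence checks run at
`n_x = 1000`, `Δt = 2e-4`, `t_final = 5` (maximum size discrepancy
≈ 1.4·10⁻³ relative, dominated by the first-order time error during the
initial fast growth; each run a few seconds), and the end-to-end fixture
smoke profile at `n_x = 400`, `Δt = 5e-4`, `t_final = 2`. Refinement tests
(halving `Δt`, doubling `n_x`) move final sizes by < 0.5% and variances by
< 2% — variance is the most grid-sensitive moment, with only ≈ 4.5 nodes
per standard deviation at the coarsest grid.

## Periodic asymptotics

For a Lipschitz T-periodic signal, the mean trait of each population relaxes
to the unique T-periodic solution of `u' = 2√(γβ)(φ(t) − u)`, computed in
the convolution form

```
u(t) = 2a [ J(t) + e^{−2at} J(T)/(1 − e^{−2aT}) ],
J(t) = ∫₀ᵗ e^{−2a(t−s)} φ(s) ds,    a = √(γβ),
```

so every exponent is nonpositive and periodicity `u(0) = u(T)` holds by
construction. `J` is evaluated by a one-pole recursion (a single
`scipy.signal.lfilter` pass) whose per-interval convolution integrates a
piecewise-linear interpolant of `φ` exactly — an exponential-integrator
rule. Plain trapezoid here left O(Δ²) errors with constants large enough to
spoil the 10⁻⁶-level agreement of the two Λ forms; the exact-linear rule
brings the residual of the `u`-equation below 10⁻⁵ and makes a constant `φ`
reproduce `u ≡ φ` to machine precision. Default period grid: 2001 uniform
samples.

The invasion quantity is computed in two algebraically equivalent forms —
the quadratic-lag form `Λ = √β + (√γ/T)∫(u−φ)²` and the lag-velocity form
`Λ = √β + (1/(2√β T))∫(φ−u)φ'` — which agree to 10⁻⁶ relative on the
canonical fixtures and to a few times 10⁻⁵ on the sharpest admissible ones
(`A = M` large, where `φ(t)` develops narrow spikes); the second form uses
the analytic chain-rule derivative of `φ` along the signal. A constant
signal yields `Λ = √β` exactly.

The winner's periodic size attractor solves the periodic logistic equation
`w' = (Q − dw)w` with `Q = γg − √(γβ) − γ(u−φ)²` and closed form involving
`exp(∫₀ᵗ Q)`; since `∫₀ᵀ Q` reaches O(10³) for the canonical parameters,
the entire expression is evaluated in log space: cumulative `C(t) = ∫₀ᵗ Q`
by trapezoid, per-interval `∫ e^{C}` by the rule exact for piecewise-linear
`C` (`Δ e^{C_k}(e^{ΔC}−1)/ΔC`), accumulated with a running log-sum-exp, and
`log w` assembled from differences of logs. This reproduces the
constant-environment plateau `(γḡ − √(γβ))/d` to 10⁻¹⁰ relative when
`A = 0` and satisfies the mean-size identity
`(1/T)∫w = (√γ/d)(θ − Λ)` (with threshold `θ = (√γ/T)∫g`) to ~10⁻⁸.

Outcome classification follows the theory literally: joint extinction when
`min(Λ_H, Λ_L) ≥ θ` (weak inequality), otherwise the strict argmin wins;
`|Λ_H − Λ_L| < 10⁻¹⁰·max(Λ)` is reported as `TIE` without claiming
dynamics, since the theory does not treat exact equality. Constant signals
take a dedicated branch (`Λ_i = √β_i`, `θ = √γ·ḡ`) that coincides exactly
with the `A = 0` periodic branch — the reduction is itself a test.

## Experiment layer

Fixture ids map to the canonical scenarios: `fig3a/b/c` are moment-ODE runs
at `M = 1` with `A = 0, 0.5, 1` (`T = 5`), `fig4a/b/c` are 50×50 sign-map
sweeps over `β_H ∈ (0.01, 0.1]`, `T ∈ [1, 20]` at `(M,A) = (60,10)`,
`(1,0.5)`, `(10,10)` (the `M = A` family is represented by its middle
member; other members are one config file away), and `fig5a–d` are PDE runs
at `T = 5` with `(M,A) = (70,20)`, `(50,50)`, `(10,10)`, `(0.1,0.1)`.
Final times of 10 are used for the dynamic fixtures — long enough for the
size transients to settle at these rates. Tracking tests that compare the
dynamics against the periodic attractors integrate to `t = 50` so that the
loser's residual competition (`d·ρ_loser`) decays below the 1% band being
asserted. Configs are YAML with strict unknown-key rejection; every run
writes a manifest embedding the fully resolved config, a hash, and the
artifact list, and re-loading a manifest reproduces the config exactly.
The `seed` field is reserved plumbing: the model is fully deterministic.

## What the tests do and do not show

All dynamical checks run on the model's own synthetic scenarios — sinusoidal
or sampled periodic signals and Gaussian initial data. They validate the
equivalence of the three computational routes and the closed-form limits,
not the biological fidelity of the fitness landscape: real nutrient or
oxygen dynamics include consumption feedback, spatial gradients and
stochasticity, none of which are modelled here. Non-Gaussian initial data
void the moment reduction (the PDE solver still applies); `ζ < γ` voids the
asymptotic theory. The TIE outcome is a numerical report, not a statement
about coexistence; the model generically excludes one population.

## Known limitations

* Explicit time stepping ties `Δt` to the domain width through the edge
  fitness; very wide domains need small steps (no IMEX variant).
* The periodic attractors are sampled on a uniform grid; signals with
  features much narrower than `T/2000` need a larger `n_quad`.
* At `t = 10` the canonical constant-environment run still carries ≈ 0.4%
  of the excluded population relative to the winner (the exclusion rate is
  `√γ(√β_H − √β_L) ≈ 0.58` per unit time); statements about the ratio
  falling below 10⁻³ require horizons of ≈ 12.5 or faster-varying
  competitors.
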