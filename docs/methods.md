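# Methods

## Statistical model

`relfit` estimates the parameters of an ODE model

    dx/dt = f(x(t, θ), θ),   x(t0, θ) = x0(θ),   y = h(x, θ),

from *relative* measurements. Each record (observable i, time t_k,
replicate/experiment r) is modeled as

    ȳ = s_g · h_i(x(t_k, θ), θ) + ε,

where the scaling parameter s_g and the noise parameter σ_g are owned by
*groups* of records. The default grouping gives every observable one s and
one σ shared over time points (the typical one-blot-per-antibody layout);
groups may equally be per replicate (one blot per observable/replicate
pair) or shared across replicates or observables. Noise is either Gaussian
(ε ~ N(0, σ²)) or Laplace (ε ~ Laplace(0, σ)), the latter appropriate for
outlier-prone densitometry. Observables may be declared on log10 scale, in
which case residuals are log10 ȳ − log10(s·h) and σ is in decades
(multiplicative noise). Likelihood densities always use the natural
logarithm; "log10" refers only to the observation scale and to the
parameter transform used during optimization.

## Hierarchical reformulation

The joint ("standard") problem min over q = (θ, s, σ) of the negative
log-likelihood J is restructured as an outer problem over θ only, with the
inner problem over (s, σ) solved at every evaluation:

* Gaussian/linear: ŝ = Σȳh / Σh², σ̂² = mean((ȳ − ŝh)²) per group. These
  are the unique stationary points of a smooth convex-in-(s) objective.
* Gaussian/log10: log10 ŝ = mean(log10 ȳ − log10 h), σ̂² the mean squared
  log-residual.
* Laplace: J is piecewise linear in s with kinks at the jump points
  ȳ/h (records with h = 0 contribute a constant |ȳ|/σ and no kink). The
  implementation sorts the kinks and locates the sign change of
  ∂J/∂s ∝ −Σ|h|·sgn(ȳ/h − s), which is the |h|-weighted median of the
  ratios. σ̂ is the mean absolute residual. When the derivative is exactly
  zero on a segment (even total weight) the lower adjacent kink is
  returned — every point of the flat segment is optimal.
* σ̂² uses the 1/n normalization (the ML estimator), so it is biased low
  by the factor (n−1)/n; a Monte-Carlo test confirms exactly this bias.

None of these steps integrates the ODE; a call-counting test enforces
that.

Grouping structures where a scaling group's records span several noise
groups (or vice versa) couple the per-group formulas. Such connected
components are solved by coordinate descent over *exact* block updates
(precision-weighted least squares for s under Gaussian noise, the
|h|/σ-weighted median under Laplace, closed-form σ updates), which is
monotone; iteration stops when the component objective decreases by less
than 1e-10 or after 100 sweeps. The resulting parameter accuracy is of
order 1e-5 in strongly curved directions — adequate because the outer
optimizer only consumes the objective value and its θ-gradient.

Degenerate groups (all simulated observables exactly zero) make ŝ
unidentifiable; the solver raises a group-labeled error, which the outer
objective maps to an infinite value rather than a crash. σ̂ = 0 (exactly
proportional data) is returned as-is; the objective layer floors σ at
1e-10 inside the likelihood and flags the result.

## Outer optimization

The outer (and, for comparison, the joint) problem is solved by
multi-start local optimization: start points uniform on the
log10-transformed parameter box, L-BFGS-B with analytic gradients per
start, results sorted by final J. The θ-gradient of the hierarchical
objective is evaluated at fixed (ŝ, σ̂) — the envelope simplification,
exact for Gaussian noise because the inner stationarity conditions hold,
and valid almost everywhere for Laplace. At a Laplace kink the objective
reports the right-hand derivative in s (a valid subgradient element) and
sets a flag; a gradient-free Powell fallback is exposed for rough Laplace
problems. Defaults: 2000 iterations, gradient tolerance 1e-6, parameter
bounds 1e-5..1e5 on log10 scale unless the problem declares tighter ones.

Gradients use forward sensitivities: the variational system
dS/dt = (∂f/∂x)S + ∂f/∂θ is integrated as one augmented ODE (LSODA,
default tolerances atol 1e-8 / rtol 1e-6; signaling models are stiff).
Model plugins may supply analytic Jacobians; otherwise central finite
differences on the right-hand side are used. Integrator failures are
encoded in the result and surface as J = +∞, so multi-start runs survive
pathological draws.

A start counts as *converged* when its final J lies within
½·χ²₀.₉₅(1) ≈ 1.9207 of the best J found (a likelihood-ratio-style
threshold; the quantile is a documented choice and configurable). The
standard-vs-hierarchical comparison reuses the θ-block of the standard
start points for the hierarchical runs, so it isolates the effect of
eliminating the nuisance parameters, and judges convergence against the
pooled best across both approaches.

## Synthetic benchmarks and what they do (not) show

All tests run on generated problems: the true model is simulated, true
scalings applied per group, seeded noise added. Noise levels are relative
(σ_true = 0.1 × mean |signal| per group by default — typical densitometry
precision). The outlier mechanism is scale contamination: a configurable
fraction of records receives noise at 5× the group scale. Measurement
grids are 20 equidistant time points including t = 0.

Built-in topologies:

* `conversion_reaction` — A ⇌ B, k1 = 0.8, k2 = 0.2, both species
  observed; mass conservation plus the known initial state make rates and
  scalings structurally identifiable.
* `cascade3` — a three-tier phosphorylation cascade relaxing after
  stimulus step-down: the top tier's activity u(t) is a known measured
  input profile, the two downstream tiers (conserved pools, initially
  fully phosphorylated) are estimated (k = 1.2, 0.4, 1.0, 0.5). This
  mirrors how published pathway studies anchor relative data: free
  multiplicative scalings combined with an activation-from-zero cascade
  would leave an exact gain/scaling trade-off (the structural
  non-identifiability that scaling factors are known to cause), whereas
  the known initial phosphorylation level pins y_i(0) = s_i and the
  non-constant input separates activation from deactivation rates. A
  deactivation-rate/activation-rate ridge remains weakly identified at
  10% noise; recovery is therefore assessed in units of the Monte-Carlo
  spread across seeds.
* `spline_input_pathway` — a two-state pathway driven by a fixed smooth
  transient input (difference of exponentials), standing in for
  receptor-driven signaling with an estimated-elsewhere input curve.

The benchmark suite is three desk-scale designs: `small`
(conversion reaction, per-observable s/σ), `medium` (cascade with
scalings shared across two replicates but replicate-specific noises — a
coupled inner problem), `robust` (conversion reaction, Laplace noise, 10%
outliers). Synthetic data share the generative form of the statistical
model, so passing tests demonstrate the correctness and the relative
merits of the optimization approaches — not robustness to model
misspecification, non-Gaussian real blot noise, missing data patterns, or
the scale of real 40+-parameter pathway models. The published case
studies appear only as parameter-structure skeletons (their counts:
16 = 11 + 5, 112 = 58 + 54, 28 = 12 + 16); no experimental data are
included or refitted.

Problem sizes in the validation studies (oracle comparisons at 200
instances per configuration, 50 matched starts for the agreement check,
10 seeded replicates × 16 starts for the convergence comparison, 10 seeds
× 15 starts for recovery) are chosen to give stable statistics at
desk scale on one CPU; fractions estimated from fewer than ~16 starts are
too granular to compare reliably.

## Numerical choices and edge cases

* Start-point sampling is uniform on the transformed box, seeded via
  numpy's Generator; identical seeds give bitwise-identical starts, and
  hierarchical runs reuse the θ-block of the standard starts.
* Objective evaluations with failed simulations return +∞; inside
  L-BFGS-B the value is capped at 1e100 with a zero gradient so the line
  search can retreat.
* Negative simulated observables are permitted in the inner solver
  (ratios remain well-defined); concentrations are expected non-negative,
  so this indicates a poor θ rather than an error.
* The Hessian-based standard errors in the Results object come from
  central finite differences of the analytic gradient at the optimum,
  pseudo-inverted; non-positive curvature yields NaN rather than a
  fabricated uncertainty.
* Monte-Carlo spread in the recovery study is floored at 1e-3 decades to
  avoid zero-spread degeneracy when a direction is recovered exactly.

## Known limitations

* Laplace noise on log10-scale observables is not implemented.
* Offset/background parameters are not eliminated analytically (scalings
  and noises only).
* Sensitivities are forward-mode; adjoint methods for large models and
  profile-likelihood machinery are out of scope.
* The kink-aware treatment of the Laplace outer problem is heuristic
  (envelope subgradients with a derivative-free fallback); convergence
  rates under Laplace noise are accordingly noisier, for both approaches.
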