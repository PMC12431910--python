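# Methods

## Model

Each node `i` of a network carries a frequency vector `x^i` on the simplex
S_n and evolves by the replicator equation with payoff matrix `A^i` plus an
exchange term over the neighbor set `c(i)`:

    dx^i_k/dt = x^i_k ((A^i x^i)_k − (x^i)^T A^i x^i) + T_k .

Per-node payoff matrices are supported; every shipped experiment uses one
shared matrix.  Two exchange mechanisms are implemented:

* **Linear velocity transport** `T^ν_i = Σ_{j∈c(i)} ν_ij (x^j(t) − x^i(t))`.
  ν (1/time) is a per-edge transfer velocity.  Row sums of the full
  right-hand side vanish identically on the simplex, so per-node density is
  conserved by the exact flow; with ν below the maximum-degree bound 1/Δ
  positivity is preserved too (simplex invariance).
* **Delayed, survival-weighted transport**
  `T^p_i = Σ_{j∈c(i)} e^{−p_ij τ_ij} (x^j(t) − x^i(t − τ_ij))`, with τ (time)
  the per-edge travel time and p (1/time) the mortality rate en route.  This
  makes the system a delay differential equation; the pre-initial history is
  the constant initial condition (the source text is silent on the initial
  function).  Note the term pairs the neighbor's *current* state with the
  node's own *delayed* state, exactly as the source model writes it.  The
  more conventional "arrivals" pairing `e^{−pτ}(x^j(t−τ) − x^i(t))` is
  available behind `TransportSpec(delayed_form="arrivals")` for sensitivity
  checks only.

**Positivity under delayed transport is not guaranteed**, and this is
observable: in the roundabout experiment the synchronized cyclic orbit grazes
the simplex boundary, frequencies turn slightly negative (≈ −4e−3 from
t ≈ 35), and the off-simplex replicator dynamics eventually diverges (t ≈ 78
for τ¹ = ½, τ² = 1 with the default seed).  The integrator therefore carries
two guards: a row-sum drift guard (default 10⁻⁶) that signals a step size too
large for the corrector, and a negativity guard (default −0.1) that stops a
run whose state has genuinely left the admissible region, with an error
message saying so.  The preset horizon for the delayed experiment is 75 time
units, which covers the synchronization event; the "arrivals" form integrates
stably to t = 200 and shows the same qualitative behavior, which is why we
regard the printed pairing as the likelier typo of the two — but the printed
form is the default because it is the model as specified.  States are never
renormalized or clipped.

## Equilibria and stability classification

* `interior_equilibrium` solves the linear system `(Ax)_k = (Ax)_n`
  (k = 1..n−1) with `Σ x_k = 1` and returns the solution only if strictly
  positive (margin 10⁻¹²).  Singular-but-consistent systems are reported as
  a "degenerate" equilibrium manifold rather than silently absent.
* `is_nash` compares `(x*)^T A x*` against the pure strategies only — exact,
  since `x ↦ x^T A x*` is linear over the simplex.
* `is_ess` uses an exact sign analysis of the shifted payoffs
  `a' = a − c`, `b' = d − b` for 2×2 games.  For n ≥ 3 it samples seeded
  random simplex directions `d = x − x*` and tests the small-deviation
  expansion `ψ(x* + εd) = ε(−d^T A x*) + ε²(−d^T A d)` exactly per
  direction (tie tolerance 10⁻¹²).  This decides "strictly out-scores
  invaders in *some* neighborhood" without committing to a neighborhood
  radius; a fixed-radius pointwise test provably disagrees with the exact
  2×2 classification for weakly-strict vertices, which is why the
  directional form is used.  It is still a sampled test: a violated
  direction that none of the `n_samples` draws hits goes unnoticed.
* `diagonal_reduction` shifts columns (which never changes the replicator
  field on the simplex): to `diag(a − c, d − b)` for n = 2, to a zero last
  row for n ≥ 3.
* `check_stability_condition` evaluates the coupled stability margins
  `(x*)^T A x^i − (x^i)^T A x^i − ν|c(i)|`.  Taken literally the margin is
  −ν|c(i)| at `x^i = x*`, so the condition is a sufficient criterion on a
  punctured neighborhood; callers should read the per-node margins, not only
  the flag.

## Networks

Nodes are labelled 1..N.  Prototypes: the chain (`inline`), the triangle,
and the six-node roundabout — chain ends 1–2 and 5–6 attached to the
quadrangle 2–3–5–4 (degree sequence 1,3,2,2,3,1).  Stability bounds 1/Δ:
1/2, 1/2, 1/3.

For directed variants the default convention is **incoming flow**: an arc
j→i moves density from j's state into i's balance, so `c(i)` is the
in-neighbor set (`direction="out"` flips this).  The arc choices are fixed
by the qualitative behavior they must reproduce, since only the unoriented
topologies are fully specified by the source text:

* oriented triangle = cycle 1→3→2→1, so node 3 couples directly to node 1
  and equilibrates before node 2;
* oriented roundabout = quadrangle 2→4→5→3→2 with feeds 1→2 and 5→6, so
  nodes 3 and 6 share the single upstream neighbor 5 and their trajectories
  coincide exactly for identical initial data.

## Integrator

Two-stage Gauss–Legendre collocation (order 4, A-stable; tableau
a₁₁ = a₂₂ = 1/4, a₁₂ = 1/4 − √3/6, a₂₁ = 1/4 + √3/6, b = (1/2, 1/2),
c = 1/2 ∓ √3/6).  The implicit stages are solved predictor–corrector style:

1. explicit-Euler predictors at the two stage abscissae,
2. fixed-point sweeps `k_i ← f(t_n + c_i Δt, y_n + Δt Σ_j a_ij k_j)` until
   `max(‖k₁ − k₁ᶜ‖₂, ‖k₂ − k₂ᶜ‖₂) < ε` (Euclidean norm over all N×n
   components; the number of sweeps is not fixed a priori),
3. update `y_{n+1} = y_n + (Δt/2)(k₁ + k₂)`.

Defaults ε = 10⁻¹², at most 50 sweeps.  Fixed-point iteration contracts when
Δt·L < 1, which holds for every bounded-payoff experiment here (Δt ≤ 0.1).
When it does not converge (stiff probes such as λΔt = −100) the stage system
is solved by Newton iteration with a forward-difference Jacobian — exact for
linear problems and ample for these ≤ 18-unknown systems, so no analytic
Jacobian is carried.  Implicit Euler uses the same Newton machinery.  No
adaptive stepping: all experiments are fixed-step.

Delay lookups interpolate the history of *accepted* steps with cubic Hermite
segments built from stored states and right-hand sides (locally O(Δt⁴), so
the lookups do not throttle the scheme's order; this is the potential
order-limiting choice for the delay case).  Stage-time lookups within the
current step may fall up to one step beyond the last accepted time and use
the last segment's polynomial extension; predictor/corrector stage values
are never inserted into the history.

## Analysis conventions

* Errors against a reference run of the same scheme on a nested finer grid:
  L∞ = max pointwise difference over stored times/nodes/species; L₂ =
  √(Δt · Σ(differences)²), a time-weighted discrete norm.  Raw error
  magnitudes therefore depend on this convention and on the horizon; the
  experimental orders of convergence (consecutive-pair log ratio) do not,
  and they are the quantity to compare across implementations.
* Convergence-study problem sizes: single-node cyclic game over T = 20
  against reference Δt = 1.25·10⁻³ (halving sequence 0.1…0.0125) or 10⁻³
  (the 0.02/0.01 pair); coupled chain over T = 10 against Δt = 10⁻⁴.  EOCs
  are ≈ 4.00 in all cases and insensitive to these choices.
* `time_to_equilibrium`: earliest stored time after which every node stays
  within tolerance (max norm) of the target.  Default tolerance 10⁻³: near
  the mixed hawk-dove point the reduced game contracts like e^{−t}, so each
  tolerance decade shifts the settling time by ln 10 ≈ 2.30; 10⁻³ is the
  criterion consistent with the reported settling times (6.5/6.8/8.2 on the
  chain for ν = 1/0.5/0.1).
* `synchronization_time`: earliest stored time after which the largest
  inter-node spread per species stays below tolerance (default 10⁻³;
  the coupled-orbit checks in the test suite use 10⁻²).  Both event
  detectors use a trailing window — the condition must hold at *every* later
  stored time, so they are robust to transient touches.

## Synthetic inputs

Random payoff matrices draw i.i.d. normal entries with a given scale (the
scale-zero degenerate case returns the zero matrix); random initial
frequencies draw flat Dirichlet (uniform on the simplex).  Both are seeded
and deterministic.  These emulate the study's "random game / random start"
conditions only: real interaction matrices are neither i.i.d. nor
symmetric-free, and real initial abundances are not uniform — passing tests
say nothing about ecological realism, only about the dynamics and numerics.
Some Dirichlet draws start the delayed-transport experiment close enough to
the simplex boundary that the divergence described above arrives before the
synchronization event (seeds 3 and 4 of the shipped preset do); the preset
default seed 0 and the neighboring seeds 1, 2, 5 complete the measurement.

## Known limitations

* The delayed transport term, as specified, can leave the simplex; long
  horizons require the "arrivals" variant (see above).
* The ESS sampler is probabilistic for n ≥ 3 (exact per sampled direction,
  but finitely many directions).
* For three-species networks with coupling at or above 1/Δ the mixed point
  loses attractiveness and stable synchronized orbits appear; this regime is
  reproduced qualitatively, not analyzed (no bifurcation study).
* Degree-0/1 graphs, weighted adjacency beyond presence/absence, and
  adaptive stepping are out of scope.
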