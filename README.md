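# replinet

Replicator dynamics on dispersal networks: evolutionary games played locally
on the nodes of a graph, coupled by migration, integrated with a fourth-order
implicit Gauss–Legendre Runge–Kutta scheme.

## The model

An ecosystem is a set of *N* habitats (nodes) connected by edges.  Each node
*i* carries frequencies **x**ⁱ(t) of *n* species on the probability simplex
*Sₙ*, evolving by the replicator equation with payoff matrix *A*:

    dxⁱₖ/dt = xⁱₖ ((A xⁱ)ₖ − (xⁱ)ᵀ A xⁱ) + Tₖ(xⁱ, ...)

The exchange term *T* couples a node to its neighbor set *c(i)*, in one of
two forms:

* **linear velocity transport** — Σ_{j∈c(i)} ν_ij (xʲ(t) − xⁱ(t)), diffusive
  mixing with transfer velocity ν per edge;
* **delayed, survival-weighted transport** — Σ_{j∈c(i)} e^(−p_ij τ_ij)
  (xʲ(t) − xⁱ(t − τ_ij)), where journeys take τ time units and only a
  fraction e^(−pτ) survives them (a delay system; history is interpolated by
  cubic Hermite segments).

For linear transport, an evolutionarily stable state x\* shared by all nodes
is asymptotically stable when the per-node margin
(x\*)ᵀA xⁱ − (xⁱ)ᵀA xⁱ − ν|c(i)| stays positive, which a coupling below the
maximum-degree bound **ν < 1/Δ** guarantees near x\* (certified by the
relative-entropy Lyapunov function V = −Σᵢ Σₖ x\*ₖ ln(xⁱₖ/x\*ₖ)).  The package
ships the classical test games (`RPS`, the skew-symmetric rock–paper–scissors
game with closed orbits around (⅓,⅓,⅓), and `HDG`, a hawk–dove variant whose
mixed point (½,½) is the unique Nash equilibrium and an ESS), the prototype
topologies (chain, triangle, six-node roundabout, and oriented variants), and
Nash/ESS/fixed-point classification with the column-shift diagonal reduction.

Time stepping uses the two-stage Gauss–Legendre collocation method (order 4,
A-stable, amplification = the (2,2) Padé approximant of eᶻ) in a
predictor–corrector formulation: explicit-Euler predictors at the stage
abscissae, then fixed-point corrector sweeps until
max(‖k₁−k₁ᶜ‖₂, ‖k₂−k₂ᶜ‖₂) < ε, with a Newton fallback for stiff probes.
First-order explicit/implicit Euler baselines are included for comparison —
on the cyclic game they visibly spiral outward/inward while the
Gauss–Legendre orbit holds the conserved quantity Σₖ x\*ₖ ln xₖ to < 10⁻⁶
over hundreds of time units.

## Worked example

Couple three hawk–dove nodes in a chain, start node 1 at the mixed
equilibrium and nodes 2–3 at the pure dove state, and measure when transport
pulls the whole chain onto the equilibrium:

```python
import numpy as np
from replinet import (
    ModelSpec, TransportSpec, IntegratorConfig, integrate,
    build_inline, hdg, interior_equilibrium, is_ess, time_to_equilibrium,
)

game = hdg()
xstar = interior_equilibrium(game)
print("mixed equilibrium:", xstar, "| ESS:", is_ess(game, xstar))

model = ModelSpec(build_inline(3), game, TransportSpec(kind="linear", nu=1.0))
print("stability bound 1/Delta:", model.graph.stability_bound())

x0 = [[0.5, 0.5], [0.0, 1.0], [0.0, 1.0]]
traj = integrate(model, x0, IntegratorConfig(dt=0.01, t_end=20.0))
print("max simplex drift:", f"{traj.meta['max_simplex_drift']:.2e}")
print("settling time (tol 1e-3):", time_to_equilibrium(traj, xstar).time)
```

Output:

```
mixed equilibrium: [0.5 0.5] | ESS: True
stability bound 1/Delta: 0.5
max simplex drift: 4.44e-16
settling time (tol 1e-3): 6.5
```

The mixed point (½,½) is an ESS; the chain's maximum degree is 2 so coupling
below ½ is provably stable (ν = 1 exceeds the bound but still settles here);
per-node densities stay on the simplex to machine precision; and all three
nodes are within 10⁻³ of the equilibrium from t = 6.5 on.  Slower coupling
settles later (8.2 at ν = 0.1): migration is what rescues the extinct hawk
strategy on nodes 2–3.

The same machinery is scriptable from the shell:

```sh
replinet test2-linear inline --nu 1.0 --out results/ --plots
replinet test1 IC1 --out results/
replinet analyze results/trajectory.csv --game HDG
```

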