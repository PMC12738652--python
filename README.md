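# turingtda

Topological classification of Turing patterns in reaction–diffusion
systems.

Reaction–diffusion models can form spots, stripes or labyrinths from a
spatially uniform state, but which pattern emerges at a given parameter
point is governed by nonlinear dynamics that linear theory cannot predict.
This package implements a pipeline that answers the question empirically:
simulate the model across its Turing space, summarise every stable pattern
by the persistent homology of its concentration fields, and cluster
parameter points by how topologically similar their patterns are.  It is
aimed at researchers studying pattern selection, parameter inference and
model comparison for two-species Turing systems.

## Models and methods

Two kinetics are built in (both nondimensional, on a rectangle with
zero-flux boundaries):

* **CIMA** (Lengyel–Epstein chlorite–iodide–malonic acid reaction):

  u_τ = ∇²u + α − u − 4uv/(1+u²),
  v_τ = σ(δ∇²v + βu − βuv/(1+u²)),

  with feed rate α, kinetic rate β, diffusivity ratio δ and starch
  factor σ.

* **Schnakenberg** (cross kinetics):
  u_τ = ∇²u + α − u + u²v,  v_τ = δ∇²v + β − u²v.

The package provides:

* **Linear analysis** — steady states, Jacobians, the Turing conditions
  C1–C4, the dispersion relation h(k²) and growth rate λ(k²), unstable
  Neumann-mode enumeration on the rectangle, and the weakly nonlinear
  (Ermentrout) stripe/spot criterion with its critical feed rates.
* **Simulation** — finite-difference method-of-lines integration
  (adaptive explicit Runge–Kutta or semi-implicit IMEX) from seeded
  Gaussian perturbations of the steady state, with numerical steady-state
  detection.
* **Persistence** — a fixed-diagonal triangulation of the grid, 20-level
  lower/upper-star filtrations that normalise pattern amplitude,
  degree-0/1 barcodes by boundary-matrix reduction over a prime field,
  and barcode cleaning by length cutoff.
* **Metrics and clustering** — exact q-Wasserstein/bottleneck distances
  between diagrams via optimal assignment, the composite node metrics
  d₁ = Σ W₂,₂ (plus d₂ and d∞), hierarchical clustering on the
  precomputed distance matrix, and silhouette-based selection of linkage
  and cluster count.
* **Synthetic patterns** — seeded spot/stripe/labyrinth generators with
  ground-truth feature counts, so the topological machinery is testable
  without PDE runs.
* **Pipeline** — Turing-space discretisation by rejection-sampled
  low-discrepancy points, a cached and resumable sweep, and report
  generation; also exposed as a thin `turing-tda` CLI.

## Worked example

`examples/persistence_basics.py` builds a four-step filtration of a
filled triangle and a synthetic spots field:

```
filled triangle  B0 = ((1.0, inf), (2.0, 3.0))  B1 = ((3.0, 4.0),)
spots field      ground-truth minima = 12, cleaned degree-0 bars = 12
```

The first component (born at step 1) never dies; the second (the vertex
added at step 2) merges into it at step 3; the loop closed at step 3 is
filled by the triangle at step 4.  For the spots field, each of the 12
persistent degree-0 bars of the lower-star filtration is one spot basin —
the barcode counts the spots.

`examples/cluster_synthetic.py` clusters thirty synthetic fields (ten
seeds each of spots, stripes and labyrinths) by the d₁ barcode metric:

```
selected         k = 3 clusters, linkage = single
silhouette       0.743  (1 = perfectly separated)
adjusted Rand    1.000  vs the planted classes (1 = exact recovery)
```

The three planted pattern classes are recovered exactly, with the cluster
count chosen automatically by silhouette score.

Other examples: `linear_analysis.py` (Turing conditions, mode counting,
critical feed rates), `simulate_pattern.py` (one PDE run with its barcode
summary), `small_sweep.py` (a 12-node end-to-end sweep with a report).

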