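# Methods

This note documents the models, numerical choices and design decisions
behind `turingtda`, and what the test suite does and does not establish.

## Models and linear theory

Both kinetics are nondimensional two-species reaction–diffusion systems on
a closed rectangle [0, Lx] × [0, Ly] with zero-flux (Neumann) boundaries.
For CIMA, the σ prefactor of the v equation is folded into the Jacobian
entries and the effective diffusivity, so the linearised system carries
d_u = 1, d_v = σδ and the Jacobian

  (f_u f_v; g_u g_v) = 1/(α²+25) · (3α²−125, −20α; 2α²βσ, −5αβσ)

at the steady state (α/5, 1 + α²/25).  The Schnakenberg steady state
(α+β, β/(α+β)²) and its Jacobian are derived from the kinetics (they are
standard but are re-derived here and verified against central differences
in the tests).

The Turing conditions C1–C4 are strict inequalities; points on the Hopf
boundary (f_u + g_v = 0) are outside the Turing space.  The dispersion
relation h(k²) is the determinant of the k²-shifted Jacobian; a
wavenumber is unstable iff h(k²) < 0, which under C1 forces a positive
growth rate λ(k²) (real eigenvalues of opposite sign).  λ is defined as
the largest *real part*, since complex pairs occur near the Hopf
boundary.

Neumann modes are indexed by integer pairs (m, n), not both zero, with
(m, n) and (n, m) counted separately; on a square domain they tie in k²
and the dominant-mode routine returns the representative with m ≥ n.  The
eigenvalue gap between the two largest growth rates is computed over
*distinct* k² values (so the symmetric tie does not produce a spurious
zero gap) as 100·(λ₁−λ₂)/λ₁; the exact formula is a documented package
choice.

### Minimal-wavelength mode and the stepsize bound

The mesh must resolve the finest unstable oscillation: the stepsize is
bounded by half the minimal unstable wavelength, with the per-axis cosine
half-period (Lx/m along x, Ly/n along y) as the wavelength convention.
Accordingly, the scan for the binding mode maximises the per-axis
resolution requirement max(m/Lx, n/Ly) over all unstable modes over a
dense parameter scan (α, σ grids at step 0.1; β scanned at step 0.01 over
its Turing-feasible range at each point, determined numerically from
C1–C4).  Ties are broken by smaller k², then m ≥ n.  For the restricted
CIMA space (α ∈ [0, 20], σ ∈ [1, 20], δ = 1.5, 20×20 domain) the binding
mode is (9, 0), giving a bound of 10/9 ≈ 1.11; the pipeline default
stepsize 0.5 is comfortably finer.  (Maximising raw k² instead would
return (9, 3), which imposes the same per-axis requirement; the per-axis
criterion is the one that controls meshing.)

### Weakly nonlinear stripe/spot selection

The Ermentrout coefficients a(α), b(α) for CIMA (small square, periodic
boundaries) classify stripes (b < a < 0) versus spots (a < −|b| < 0).
Because the (δ, σ)-dependent prefactor is common to a and b, the
classification depends on α alone wherever the prefactor is positive.
The three boundaries in (0, 20) are located by a 0.01-step scan plus
bisection to 1e−4 — the closed-form equalities defining each boundary
individually are not relied upon — giving 2.501, 11.581, 12.630 (3 d.p.).

## Numerical integration

Method of lines on the closed vertex grid; the Laplacian is the 5-point
stencil with mirrored ghost nodes (second-order Neumann).  This stencil
conserves the trapezoid-weighted spatial mean exactly under pure
diffusion, which the tests verify to 1e−8.

Two integrators:

* `explicit` (default in `SimConfig`): adaptive Bogacki–Shampine 3(2)
  embedded pair with FSAL, error control per species (rtol 1e−6,
  atol 1e−9) and a diffusive stability cap on the step.
* `imex`: fixed-step backward-Euler diffusion (factorised once with
  sparse LU) plus forward-Euler reaction, dt = 0.01.  First order, but
  unconditionally stable in the diffusion and ~50× faster at pattern
  scale; parameter sweeps use it by default.  The two integrators agree
  per-seed on final pattern topology at the exemplar nodes, which is the
  sense of accuracy the pipeline needs.

Initial conditions are i.i.d. Gaussian N(0, 0.1²) perturbations of the
steady state, one seed per node split deterministically into u and v
streams.  A numerical steady state is declared when the sup-norm of the
time derivative falls below 1e−5 (the notion of convergence is
*computational*: patterns are read at τ = 250 whether or not the
derivative tolerance has been met, matching the physically observable
intermediate-time patterns).  Simulations warn when the grid violates the
Nyquist bound for the parameters being run.

Realised morphology at τ = 250 can depend on the seed: at the spotted
exemplar (α = 9.74, β = 0.27, σ = 12.5, just above the Hopf boundary)
some seeds give stripes and others spotted/broken-stripe states, with
both integrators agreeing per-seed.  Tests of such qualitative outcomes
therefore assert attainability over a small fixed seed ensemble rather
than a property of every realisation.

### Grid convergence

The convergence check evolves the *same* smooth multi-mode initial
perturbation (i.i.d. vertex noise is not resolution-consistent) at
stepsizes 1.0 and 0.5 and compares cleaned bar counts.  The B0u, B1u and
B1v counts are invariant; B0v at the test node has bars of lengths 4–6,
straddling the cleaning cutoff 5, so its cleaned count is not a stable
observable — one reason to prefer cutoffs on B0u/B1v when robustness
matters.

## Persistence

Each grid cell is split along the lower-left→upper-right diagonal
(configurable; any fixed choice gives a contractible triangulation of the
rectangle, Euler characteristic 1).  The star filtration cuts the field
range into n_levels = 20 equal slices; vertex level = smallest j whose
threshold admits the vertex, simplex level = max over its vertices.
Because thresholds are fractions of the per-field range, the filtration
normalises amplitude and diagrams of different nodes are directly
comparable; bar lengths (and the cleaning cutoff 5) are in these level
units.  A constant field degenerates to a single level.  Setting
`n_levels=None` filters by exact sorted vertex values — the
discretisation-free object for which the stability theorem
(bottleneck ≤ ‖f−g‖∞) holds; stability tests use it because 20-level
quantisation adds O(range/20) threshold error, larger than the smallest
perturbations tested.

Barcodes are computed by standard column reduction of the level-sorted
boundary matrix — bitmask columns over F₂ (default), dict columns with
modular inverses for any other prime.  Zero-length pairs are dropped;
essential classes get death = ∞.  The engine is validated against an
independent oracle that computes persistent Betti numbers from
boundary-matrix ranks and kernels and recovers multiplicities by
inclusion–exclusion, and F₂/F₁₁ agreement confirms no torsion on the
pipeline's complexes.

Cleaning drops finite bars shorter than the cutoff (infinite bars always
kept).  Default per-channel cutoffs: 5 levels for B0u, B0v, B1v; B1u kept
in full.  The histogram helper smooths the length distribution with a
small Gaussian kernel and proposes the valley between the two
lowest-length modes as a cutoff, or none when unimodal.

## Diagram distances and clustering

W_{p,q} matches points to each other or to the diagonal under the ℓ_p
ground cost, with ∞−∞ = 0: infinite bars may only match infinite bars
(cost = birth difference), and mismatched infinite-bar counts give
distance +∞.  Finite problems are solved exactly by linear assignment on
the diagonal-augmented cost matrix; the bottleneck (q = ∞) by binary
search over attained costs with an assignment feasibility check.  Both
agree with exhaustive matching enumeration on small diagrams.

Node metrics over the four channels (B0u, B1u, B0v, B1v) with W₂,₂:
d₁ = sum, d∞ = max, d₂ = √(Σ W²) — with the literal sum-of-roots reading
of d₂ (identical to d₁) available behind `literal_d2`.  Distances are
computed on cleaned barcodes by default (raw available).  Clustering uses
single/complete/average linkage on the precomputed matrix (centroid-type
linkages need a Euclidean embedding, which a general metric does not
provide); linkage and cluster count are chosen by silhouette score over
k = 2..12, ties broken by smaller k then linkage order.  Singleton
clusters contribute silhouette 0.

## Synthetic patterns

Spots are the product mode cos(mπx/Lx)·cos(nπy/Ly); stripes a single-axis
mode; labyrinths a seeded random superposition of ≥ 6 modes with
near-equal k² (mode mixing of a degenerate spectrum).  Amplitude 1 and
Gaussian vertex noise with sd 0.05 (≈5 % of amplitude) are the default
test conditions.  Ground truth is measured on the generated field by
direct grid search: strict local minima below mid-range ((max+min)/2) for
spots, connected sub-mid-range components for stripes/labyrinths.  These
fixtures reproduce topology classes only — not PDE amplitude profiles or
interface shapes — so tests that pass on them certify the topological
machinery, not the fidelity of any simulation.

## Pipeline

Nodes are scrambled-Halton points in the parameter box, rejection-sampled
against C1–C4 (CIMA: (α, β, σ) with δ fixed at 1.5, β box (0, 17] which
contains the feasible range for α ≤ 20; Schnakenberg: (α, β, δ) with
δ ∈ [25, 45] and default α ∈ [0, 0.2], β ∈ (0, 1.5] — its bounded Turing
region).  Filtration conventions follow the kinetics type: CIMA (pure
kinetics, in-phase species) uses lower-star u / upper-star v;
Schnakenberg (cross kinetics) upper-star for both.  Sweep results are
cached per node keyed by a configuration hash, making reruns bit-identical
and sweeps resumable; failed nodes are flagged, never interpolated.  The
per-node amplitude max u − min u is exported as a boundary-proximity
diagnostic.

Desk-scale defaults used by the test suite: ~30 nodes, stepsize 1.0
(within the 1.11 Nyquist bound), τ = 250, IMEX integrator — a sweep of
this size runs in a few minutes on one CPU.  The full-scale configuration
(549 nodes, stepsize 0.5) is expressible with the same `SweepConfig` but
is a multi-hour computation.

## Known limitations

* Rectangular domains and spatially homogeneous, time-independent
  parameters only.
* Degree-2 homology is not computed (2-D domains) and there is no
  cubical-complex backend.
* The IMEX integrator is first order in time; conclusions drawn from it
  are topological, not amplitude-accurate.
* Silhouette-selected cluster counts on small node sets are sensitive to
  the sample; only the cluster *separation* of topologically distinct
  patterns is a robust desk-scale observable.
* Near the Turing-space boundary, pattern amplitude can be arbitrarily
  small and transients arbitrarily slow; nodes there may be flagged
  unconverged at τ = 250.
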