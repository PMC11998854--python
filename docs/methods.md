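# Methods

`vesiclemc` simulates the nonequilibrium growth of fluid vesicles and
analyses the resulting trajectory ensembles.  This note records the model,
the numerical choices behind it, and the limits of what the bundled tests
demonstrate.

## Model

A vesicle is a closed, orientable, sphere-topology triangulated surface:
N vertices (surface particles) with positions `r`, connected by the
adjacency `A` kept as ordered one-rings.  The configurational energy is

    E_tot = E_bend + E_tether + E_area

* `E_bend = (kappa/2) ∮ (2H)^2 dA`, discretized with the
  cotangent-Laplacian vertex mean curvature and barycentric (one-third)
  vertex areas.  On subdivided icosahedra this converges to the continuum
  value `8 pi kappa` (within 0.2% at 2562 vertices).  A dihedral-angle
  variant, `2 sqrt(3) kappa * sum_e (1 - cos theta_e)`, is provided behind
  the same interface as a cross-check; the cotangent form is the default
  because the downstream analysis fits continuum shell theory.
* `E_tether` is a hard square well on edge lengths, default bounds
  `(0.45, 1.70) l0`.  The lower bound is deliberately below half the upper
  bound so that the edge-split insertion move (which halves an edge) has
  valid proposals; the geometry self-organizes to mean edge length ~1 l0.
* `E_area = (k_a/2) sum_f (A_f - a0)^2` with `a0 = sqrt(3)/4 l0^2` (the
  equilateral area at unit edge) and default `k_a = 25 kBT/l0^4`.  This
  value keeps the *vertex density* rho0 = N/A stable at the 2-3% level
  (so surface area tracks particle number, `A ≈ N/rho0`), while leaving
  individual faces soft enough (~40% area fluctuations) that
  grand-canonical exchange moves retain workable acceptance (~5-15%).
  A percent-level per-face stiffness would cost tens of kBT per
  insertion and freeze particle exchange entirely.

The vesicle exchanges surface particles with a reservoir at chemical
potential `mu`, volume with an osmotic reservoir at pressure difference
`dp`, and heat at `kBT = 1`.  Moves are accepted on the change of
`Phi = E_tot - mu N - dp V` via
`P_acc = min(1, [Pgen(rev)/Pgen(fwd)] exp(-dPhi/kBT))`.

## Move set and reversibility

One sweep attempts exactly N vertex translations (uniform displacements
in a cube of side `2*step`), `Binomial(E, pflip)` edge flips and
`Binomial(E, pexchange)` insertions and removals each, interleaved in
uniformly random order; E = 3N - 6 is the edge count implied by sphere
topology.

* **Flip**: a uniformly chosen edge is exchanged for the opposite
  diagonal of its two faces; `Pgen` is 1/E in both directions.
* **Insertion**: a uniformly chosen edge (i,j) is split; the new vertex
  is placed uniformly in a cube of side `h = 0.5 l0` centred on the edge
  midpoint, so the forward generation *density* is `1/(E h^3)`.
* **Removal**: one of the `2 n4` ordered (degree-4 vertex, diagonal)
  pairs is chosen uniformly; the vertex is deleted and the quadrilateral
  hole re-triangulated with that diagonal.  The proposal is invalid when
  the doomed vertex lies outside the cube of side h around the diagonal
  midpoint — the reverse insertion could never generate its position —
  and the reverse generation density is `1/(E' h^3)`.

The finite placement window is essential, not cosmetic: a deterministic
midpoint placement is a delta-function proposal density in the continuous
configuration space and has no measure-consistent reverse.  Early
experiments with deterministic placement showed the symptom directly —
the chain densified the mesh to nearly twice the target vertex density
because insertions were effectively entropically free.  With the window,
a single-move audit (`engine.detailed_balance_audit`) verifies the
transition-ratio identity `W(G->G')/W(G'->G) = exp(-dPhi/kBT)` exactly:
for sampled moves of every topological kind, the generation probability
of the regenerated reverse proposal matches the one recorded by the
forward proposal to machine precision.

`h = 0.5 l0` trades insertion acceptance (which falls as h grows, via
the `E h^3` factor at fixed entropy) against removal acceptance (which
requires the degree-4 vertex inside the window).  Both land near 5-15%
at equilibrium with the defaults; equal insert/accept and remove/accept
traffic at `mu_eq` is asserted in the tests.

Invalid proposals (tetrahedral flips, missing degree-4 vertices,
out-of-window removals, tether violations) count as attempted-and-
rejected null moves, preserving the sweep's attempt schedule.  The
minimum system size is the icosahedron (N = 12).

Translation steps are auto-tuned toward 40% acceptance during
equilibration only and frozen for production, so driven dynamics are not
confounded by a drifting proposal scale.

## Equilibrium chemical potential

`mu_eq(dp)` is located as the root of the mean particle current: coarse
bisection on short runs brackets the root, then Newton-like refinements
exploit linear response (`j ≈ D_N dmu`), correcting `mu` by `-j/D_N`
with the current and diffusivity measured from block increments of one
longer trace.  Two caveats are documented rather than hidden:

* the quasispherical vesicle is a *critical-nucleus-like* equilibrium:
  `mu_eq` decreases slowly with vesicle size, so `mu = mu_eq(R0)` is
  marginally unstable and the equilibrium ensemble is quasi-stationary
  over finite horizons (very small systems, N ~ 40, visibly run away;
  at N >= 160 the drift is negligible over the horizons used);
* repeated calibrations agree to ~±0.1-0.3 kBT across seeds because the
  vesicle size random-walks during the measurement; all analyses treat
  dmu as an offset from the *same* calibration, which cancels the shared
  error;
* for large vesicles (~2500 vertices) the flux response dj/dmu is small
  — growth is rate-limited by slow area relaxation, so j(mu) is shallow
  and noisy over a wide mu range.  The calibration therefore grows its
  bracket only on statistically significant flux (|j| > 2 SE) and
  confines the Newton refinement to the coarse bracket; without these
  guards a noise draw can walk the estimate several kBT from the root.

## Shape spectroscopy

Configurations are decomposed as `r(theta, phi) = R (1 + sum u_lm Y_lm)`
about the vertex centroid with orthonormal real spherical harmonics
(Condon-Shortley-free), by weighted least squares with solid-angle
weights (barycentric vertex area / r^2); the monopole gives R, and degree
powers are `|u_l|^2 = (2l+1)^{-1} sum_m u_lm^2`.  Mesh vertices are
irregular, so least squares replaces quadrature; the cutoff must satisfy
`(lmax+1)^2 <= 0.55 N`.  Synthetic-shape experiments (known spectra
sampled on real equilibrated mesh geometry, including unresolved degrees
up to the mesh cutoff) show per-degree estimator bias below ~5-10%,
dominated by aliasing at the highest fitted degrees.  Non-star-shaped
(overhanging) configurations are detected by signed solid angles,
excluded and counted.

Ensemble spectra are fitted in log space with the pressurized-shell form

    <|u_l|^2> = kBT / (2 A_l),
    A_l = 1/2 [ gamma R^2 (l-1)(l+2)
              + Y R^2 (l-1)(l+2) / (l(l+1))
              + kappa (l-1)^2 (l+2)^2 ]

with parameters (gamma, log Y, log kappa) and R fixed at the measured
ensemble radius.  The exact sub-leading l-dependence of the stretching
term varies across the shell-theory literature; this transcription is
fixed by its limits — the shallow-shell form `kappa q^4 + gamma q^2 +
Y/R^2` at large l, and the classic fluid-membrane (Helfrich) spectrum
with tension polynomial (l-1)(l+2) at Y = 0 — both asserted in tests.
Fits with reduced chi-square above 10 are flagged: far from equilibrium
the equilibrium shell form describes the data poorly and the effective
parameters lose meaning.

Fit windows matter at coarse resolution.  The mesh cutoff is
`l_mesh ~ pi R / l0`; degrees above ~0.5 l_mesh carry lattice and
aliasing contamination that biases kappa downward.  Defaults used by the
analyses: fit `l in [2, 9]` at R0 ~ 6.6 (642 vertices) and `l in [2, 12]`
at R0 ~ 13 (2562 vertices).  At 642 vertices the recovered equilibrium
rigidity is ~20% below the input (the known fluid-membrane softening of
coarse dynamically triangulated meshes); at 2562 vertices it is
consistent with the input within the fit CI, which is why the
rigidity-recovery checks run at full mesh resolution.

## Buckling thresholds

Zero-temperature shell theory gives `P_c0 = 4 sqrt(kappa Y)/R^2` and
`gamma_c0 = -2 sqrt(kappa Y)/R`.  Thermal softening multiplies the
threshold by a scaling function `Psi(ET)` of the elastothermal number
`ET = (kBT/kappa) sqrt(Y R^2/kappa)`.  Psi is pluggable (zero-T, user
table, or the default); the default `Psi(x) = (1+x)^(-2/5)` is an
explicit *synthetic stand-in* with the qualitative properties reported
for the renormalization-group curve (Psi(0)=1, monotone decreasing,
~25% reduction at ET ~ 1) — it is not a transcription of a published
table, and every prediction carries its Psi provenance.  Classification
uses kappa and Y from the same spectrum fit as the measured tension.

## Stochastic thermodynamics

Net fluxes `J = (dN, dV)` at horizon tau give currents `j = J/tau`,
covariance Xi (unbiased), diffusivity `D = Xi/(2 tau)`, TUR bounds
`dS >= 2 kB <J>^T Xi^{-1} <J>` (monotone in the observable set), inferred
forces `f = kBT D^{-1} j` with bootstrap CIs, and the growth law
`(Ndot, Vdot) = D f / kBT` with an exact inverse (design mode).  The
relative-entropy correction eps_diss to the direct entropy estimate is a
pluggable interface defaulting to zero; every estimate records whether it
was included.  The near/far-equilibrium split defaults to `dmu = 5 kBT`.
The Heaviside convention in the hinge force law is `Theta(x) = 1 for
x >= 0, else 0`.

Both `j(tau)` and `D(tau)` depend on the horizon: the vesicle grows away
from the calibration point and shape modes relax slowly, so
fluctuation-dissipation (`j_N ≈ D_N dmu/kBT`) is checked at matched,
short horizons (tau = 400 sweeps at R0 ~ 3.3) inside the quasi-stationary
window.  At mismatched horizons the ratio moves by tens of percent, which
is visible structure, not noise.

## Study conditions and reduction

The reference conditions are kappa = 20 kBT, R0 = 15 l0 (~2562 vertices
at unit edge), pexchange in {1, 0.01}, pflip = 1, tau = 5000 sweeps and
500-sample ensembles.  Tests and the acceptance script reduce this to
desk scale: R0 ~ 3.3 l0 (162 vertices) for flux statistics, R0 ~ 6.6 l0
(642 vertices) for driven spectra, R0 ~ 13 l0 (2562 vertices) for
rigidity recovery; 8-24 samples; horizons 400-2400 sweeps.  Known
residual size effects, measured and accepted rather than tuned away:

* the near-equilibrium tension-renormalization slope `c_gamma` steepens
  at small R (measured ~ -2 to -3 at R0 ~ 3-7 l0 versus -0.98 at full
  scale), so printed-constant comparisons for c_gamma at reduced scale
  fail honestly;
* the buckling margin `|gamma_c| ~ 1/R` grows at small R, pushing the
  morphological transition to stronger driving; at R0 ~ 6.6 with
  pexchange = 1 the measured tension tracks and crosses the finite-T
  threshold near dmu ~ 3-5 while staying clearly above the zero-T
  threshold — the vesicle self-regulates by shedding excess area into
  wrinkle modes (interior spectral peaks at l* >= 3), which also means
  l* saturates at small values and the wrinkle wavelength resolves only
  coarsely;
* equilibrium effective tension at reduced scale is near zero with
  ~±1 kBT/l0^2 fit uncertainty, so tension-magnitude ratios are
  low-precision quantities.

Monte Carlo sweeps are the only clock; no mapping to physical time is
attempted.

## What the synthetic generators do and do not emulate

`generate_synthetic_trajectories` produces correlated Gaussian random
walks with exact drift/diffusion ground truth: the oracle for flux
statistics, TUR bounds and force inference.  It does not emulate the
tau-dependence, growth-induced nonstationarity or non-Gaussian tails of
real vesicle fluxes, so passing those tests validates the estimators,
not the membrane physics.  `generate_synthetic_spectrum` evaluates the
shell spectrum exactly with multiplicative lognormal noise: the
round-trip oracle for the fitter; it does not emulate finite-mesh
aliasing (that is probed separately on real mesh geometry).

## Numerical choices

* Energies are maintained incrementally by the compiled kernels
  (per-vertex bending cache, running totals); agreement with from-scratch
  recomputation is ~1e-12 relative after hundreds of sweeps and is
  asserted in tests.  Degenerate (near-zero-area) faces return a
  rejecting sentinel inside moves and raise errors in analysis code.
* Kernels are numba-compiled with fastmath; trajectories are bitwise
  reproducible for a fixed (seed, parameters) on a fixed platform.
  Per-sample seeds derive from the master seed via numpy SeedSequence.
* The spectrum fit optimizes (gamma, log Y, log kappa), enforcing
  positivity of Y and kappa; parameter errors use the Jacobian at the
  optimum scaled by reduced chi-square when above 1.
* Hinge (piecewise-linear) force-law fits share one slope zeta across
  pressures with a per-pressure threshold mu*(dp); thresholds outside
  the scanned window are flagged open rather than reported.

## Known limitations

* No self-avoidance beyond the tether bounds: strongly wrinkled shapes
  can self-intersect; analyses exclude non-star-shaped configurations
  but the sampler does not forbid them.
* Fitted elastic constants at coarse resolution carry systematic
  softening; only the full-resolution rigidity recovery is quantitative.
* The default Psi curve is an approximate stand-in; quantitative
  threshold work should supply a tabulated curve via
  `PsiModel.from_table`.
* eps_diss defaults to zero; direct entropy estimates are therefore
  upper-bound-flavoured for growing systems.
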