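# Methods

`hybridrd` simulates spatial models of cell biology in which a
"deterministic" subsystem — concentration fields large enough in copy
number to obey PDEs — is coupled to a genuinely stochastic subsystem of
discrete particles (ion channels, receptors, macromolecules).  The
composite object is a piecewise-deterministic Markov process: between
jump events the fields evolve by reaction–diffusion PDEs whose source
terms depend on the particle configuration, and the particles jump
between states at rates that may depend on the local field values.

## Model and discretization

**Fields.**  A volume field U(r,t) (μM) obeys

    ∂U/∂t = ∇·(D∇U) + Σ_i J·Ξ_i(r,t) − V_p (U − U₀),

with no-flux, fixed-value, or membrane-flux-coupled boundary conditions;
a surface field S(r,t) (molecules/μm²) obeys the analogous equation with
the Laplace–Beltrami operator on the membrane.  Space is partitioned
into regular finite-volume subvolumes ω_j (cells), ordered
lexicographically with x fastest; cells are half-open ([low, high) per
axis, with the global upper box boundary closed) so that every point has
exactly one owner.  Membranes are closed triangulated surfaces (sphere
meshes by refined-icosahedron subdivision); surface unknowns live on
triangle elements, and transport between adjacent elements uses
two-point fluxes weighted by edge length over centroid distance, which
conserves surface mass by construction.

**Particles.**  Each particle carries a position (volume coordinates, or
exact (triangle, barycentric) coordinates on the membrane) and one
discrete state.  Binning a particle set into the grid gives number
densities n_j/|ω_j| on the same mesh as the fields; this one shared
discretization is what couples the two subsystems: particle sources
enter the PDE as J·n_j/|ω_j| in the particle's cell (piecewise-constant,
no smoothing kernel — which also sets the known point-particle
resolution limit near steep gradients), and field-dependent rates read
the field value of the particle's cell or element (no interpolation, for
consistency with the source discretization).

**Time stepping.**  A fixed step Δt (stiffness is the user's
responsibility; a runtime tripwire aborts when any particle's total
outgoing rate times Δt reaches 0.5).  Each step executes:

1. *(PDE)* semi-implicit update: the diffusion operator applies to the
   unknown field at t+Δt while reactions, particle sources, and membrane
   fluxes are evaluated from the state at t, i.e. solve
   (I − Δt·D·L)·U(t+Δt) = U(t) + Δt·src(t).  The scheme is first-order
   in Δt, unconditionally stable, and exactly mass-conserving under
   no-flux conditions (the discrete operator has zero row sums).
2. *(particles)* state transitions by acceptance–rejection with the
   exact one-step waiting probability 1 − exp(−k_tot Δt) at frozen rates
   (one uniform per particle; multi-destination transitions partition
   that uniform proportionally to the individual rates), then Brownian
   displacement of mobile particles by the exact free propagator
   (Gaussian, variance 2DΔt per axis), reflected at box walls; surface
   particles take a tangent-plane step and are reprojected to the mesh.
3. *(rates)* field-dependent transition rates are refreshed from the new
   fields at the new positions, and
4. *(binning)* particle densities are re-binned.

The order is part of the contract; the (1)/(2) asynchrony is O(Δt) and
is bounded empirically by the Δt-refinement tests.  Within step (2),
transitions are sampled before diffusion; the alternative order differs
at O(Δt) as well.

**Units.**  μm, s, μM for volume concentrations, molecules/μm² for
surface densities; 1 μM = 602 molecules/μm³.  Volume–surface exchange
converts through this constant so that the molecules removed from the
volume per element per step equal the molecules added to the membrane
exactly (local mass conservation; verified to ~1e−14 relative in the
polarization model).

**Linear solves.**  Sparse direct factorization (SuperLU) up to 1e5
cells, preconditioned CG above; operators with ≤300 cells use a dense
inverse so that ensemble-batched right-hand sides become one BLAS-3
multiply.  Factorization residuals are at machine precision; the CG
tolerance is 1e−10 relative.  Negative concentrations produced by
explicit sinks are reported with a warning, never clipped (clipping
would silently break conservation).

## Randomness and ensembles

Realization r of an ensemble with base seed s draws from
`numpy.random.default_rng([s, r])`.  The per-step draw order is fixed
(per species: one uniform per particle, then normal blocks for mobile
species), so a trajectory is bit-identical regardless of how
realizations are scheduled.  When every particle species is immobile and
lives on the volume grid, `run_ensemble` steps all realizations
simultaneously (fields become (cells × realizations) matrices sharing
one factorization); the batched path consumes the same per-realization
streams in the same order and reproduces the serial loop exactly (this
equivalence is a test).  Models with diffusing particles (the
polarization model) run serially.

## Reference solvers (the validation battery)

* **Separable closed form.**  When transition rates do not depend on the
  fields, the channel marginals are analytic and the expected spatial
  average of U follows a linear ODE driven by the mean open probability;
  the closed-form solution (plateau U₀ + J·N_ch·p∞/(V_p|Ω|)) is checked
  against brute-force ODE integration to 1e−9 before being used as the
  oracle for the error-scaling study.
* **Gibson–Bruck next-reaction SSA** for well-mixed references:
  absolute next-firing times per reaction, reuse of unfired times under
  propensity changes as t + (a_old/a_new)(t_next − t), and a dependency
  graph so only affected propensities are recomputed.  With ≤6 reaction
  channels the priority structure is an argmin.  The fully stochastic
  well-mixed twin of the release-site model treats calcium as a copy
  number (production V_p·U₀·|Ω|, first-order removal V_p, influx J per
  open channel, all converted at 602 molecules/μm³/μM).
* **Direct Chapman–Kolmogorov/Fokker–Planck solves** for the
  nondimensionalized single-channel problem (ρ = (U−U₀)/U₀, τ = t·V_p,
  α = k_off/V_p, β = k_on/k_off, a = J/(U₀V_p|Ω|)).  In the
  fast-diffusion limit the two density components advect with drifts −ρ
  and a−ρ and exchange at rates αβ(ρ+1) and α.  At finite diffusion the
  functional Fokker–Planck equation is discretized on the same spatial
  grid as the hybrid model: each node i contributes one coordinate ρ_i
  with drift d·(Lρ)_i − ρ_i + (a/Δx)·δ_{i0}·ξ (the point source is a/Δx
  in node 0, mirroring the engine's binning exactly).  Transport is
  donor-cell upwind with explicit Euler at CFL 0.5 — chosen for
  positivity and exact probability conservation over formal order — and
  ρ ranges are set automatically to 1.2× the all-open steady state of
  the binned deterministic system (the drift field keeps that box
  invariant).  Richardson extrapolation in Δρ (least-squares polynomial
  of order ≤2) sharpens reference curves where memory bounds Δρ.

## Built-in models and conventions

* **Release sites ("sparks")**: 24 immobile two-state channels in a
  quasi-2D box [0,10.1]×[0,2.1]×[0,0.5] μm³ with J=10 μM·μm³/s, U₀=0.1
  μM, k_on=1/s, k_off=5/s, V_p=1/s, D=1 μm²/s; the coupled variant
  replaces k_on by k_on·U/U₀ (k_on=0.1/s, D=1000 μm²/s, Δt=0.2 ms).
  The packaged channel layout is a synthetic regular 8×3 grid (the
  original arrangement is published only graphically; the separable
  statistics are position-independent).
* **Stochastically gated binding**: immobile three-state macromolecules
  (inert ⇄ active → complex → active) in a ligand bath with Dirichlet
  boundary L = L₀ = 1 μM; r_c = (0.3/4πL₀)^{1/3} ≈ 0.0341 μm,
  τ_D = r_c²/D ≈ 1.163 ms, a = b = 1/τ_D, κ_f = 4πDr_c ≈ 0.429 μm³/s,
  κ_r = κ_f L₀ ≈ 258/s, N = 20000 in [0,10]³ (≈ 3.32×10⁻² μM), half
  inert and half reactive at t = 0.  The ligand field is stored in μM;
  the binding rate coefficient and the release source carry the
  602 molecules/μm³ conversion explicitly.
* **Spontaneous polarization**: cytosolic protein U (volume), recruited
  protein S (membrane), and N_r two-state receptors on a sphere of
  radius R = 4 μm; inactive receptors diffuse (D_Γ = 0.1 μm²/s), active
  receptors are immobile and recruit U through the conservative membrane
  flux k₁UΓ − k₂S; activation at k₃·S (+ pre-activation pulse
  k₀e^{−t/τ} on the inactive→active transition only).  The printed unit
  of k₃ (per-area per-time) is dimensionally inconsistent with k₃·S
  being a rate; here k₃ multiplies the surface density S (μm⁻²) and
  carries μm²·s⁻¹.  The sphere's volume is the set of grid cells whose
  centers fall inside (pixelated geometry); each surface element
  exchanges mass with the active cell found a short distance along its
  inward normal.
* **Histograms and L² differences**: 20 bins over a stated range,
  frequencies divided by bin width (density integrates to 1 exactly);
  two binned densities are compared as sqrt(Σ(Δp_k)²·w_k), also
  expressed as a percentage of the reference maximum.  Both forms are
  reported because the published convention is not fully specified.
* **Cluster counting** (polarization diagnostics): DBSCAN on Cartesian
  (chordal) distances of active-receptor positions, radius 0.4 μm on the
  scaled sphere, isolated points counted as clusters.  A diagnostic
  only; no acceptance threshold depends on the radius.

## Validation scales

The shipped battery (`hybridrd.validation`, also driven by
`scripts/acceptance.py`) runs at sizes that complete in minutes on one
core; the package's own choices are:

* error scaling: coarse 0.5 μm mesh on a [0,10]×[0,2]×[0,0.5] box (the
  0.5 μm spacing does not divide the 10.1×2.1 reference box, and the
  grid builder refuses to round silently), Δt = 2 ms, T = 5 s, ensembles
  up to n = 10⁴ with ε(n) averaged over disjoint sub-ensembles;
* well-mixed comparison: n = 500 per solver at t = 1 s on a coarsened
  (0.505, 0.525, 0.5) μm mesh — legitimate because the fast-diffusion
  limit is mesh-insensitive — judged against the bootstrap RMS L²
  fluctuation of the reference histogram;
* fast-diffusion FP cross-check: n = 2000 hybrid realizations on a
  0.25³ mesh vs the direct solve (stationary means);
* finite-diffusion functional FP: 12,500 hybrid realizations (2 cells)
  vs solves at Δρ ∈ {1.125e−2, 7.5e−3, 5e−3};
* gated binding: scaled domain [0,2.5]³ μm³ at the reference particle
  density (N = 312), h = 0.25 μm, Δt = 2e−5 s, n = 200, run to 115·τ_D
  with C_eq estimated as C at 110·τ_D;
* polarization: R = 2 μm sphere, N_r = 200, n = 8, T = 60 s.

## What the battery does and does not show

The synthetic inputs are exactly the models above — parameter sets, not
measured data.  Passing tests demonstrate that the numerical scheme
reproduces the stochastic law of the modeled process (exact waiting
times, correct stationary distributions, convergence to closed forms and
to statistically exact references); they do not validate any biological
model against experiments, and they do not probe regimes the battery
does not reach (irregular geometries, particle–particle bimolecular
chemistry, strong stiffness).

Known limitations:

* Reaction terms are explicit; stiff reactions force small Δt (the
  rate·Δt < 0.5 guard aborts rather than degrade accuracy silently).
* Particles are points; when a continuous species is strongly depleted
  near a particle (gated binding at h approaching r_c), accuracy is
  limited by the point approximation, not by Δt or the mesh alone.
* At the scaled gated-binding size the power-law tail of the relaxation
  function lies close to the ensemble noise floor: with n·N ≈ 6.2×10⁴
  macromolecule trajectories the standard error of the relaxation value
  is ≈ 5×10⁻³ while the asymptote itself is below 10⁻² throughout the
  fitted window, so the recovered tail slope is noise-limited (see the
  acceptance output rather than this note for the measured value).
* The pixelated sphere interior under-resolves boundary-layer gradients
  of U; the polarization observables used here (spatial averages,
  cluster counts) are insensitive to this at the tested resolution.
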