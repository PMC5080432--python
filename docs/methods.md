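# Methods

`aucbind` implements a sedimentation-velocity (SV) analytical
ultracentrifugation workflow for quantifying non-specific protein binding
to colloidal nanoparticles (NPs): forward simulation of SV experiments,
extraction of sedimentation-coefficient distributions from radial scans,
fitting of a sedimentation-based binding isotherm, and a frictional-ratio
diagnostic of complex shape. This note records the models, their
assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Hydrodynamic model

All species are treated as Stokes-equivalent spheres in a Newtonian
solvent (default: water at 20 °C, η = 1.002 mPa·s, ρ_s = 0.99823 g/cm³).
The closed-form layer consists of:

- **Sedimentation coefficient** of a sphere of hydrodynamic diameter d_H
  and density ρ_p:  s = d_H² (ρ_p − ρ_s) / (18 η).  s < 0 (flotation) is
  permitted mathematically and flagged by callers where relevant.
- **Stokes–Einstein diffusion**:  D = k_B T / (3 π η d_H).
- **Sizing inversion** (s, D) → (d_H, ρ_p): d_H from D via
  Stokes–Einstein, then ρ_p = ρ_s + 18 η s / d_H².  This is an exact
  algebraic inverse; the round trip is tested to 1e-12 relative.
- **Complex density** of an NP carrying N_avg proteins (homogeneous
  aggregate approximation): the volume-weighted mean of ρ_NP and ρ_P.
- **Complex sedimentation coefficient**: the complex is replaced by a
  sphere of volume V_NP + N_avg·V_P with the complex density.  The sign
  of ds/dN_avg equals the sign of (ρ_P − ρ_s) − (ρ_cx − ρ_s)/3; for dense
  metal cores coated by light protein this is negative, i.e. protein
  adsorption *slows* sedimentation (friction gain beats buoyant-mass
  gain).  A property test checks this sign criterion against numerical
  derivatives on randomized specs.
- **Hill adsorption isotherm**: N_avg([P]) = N_max [P]ⁿ / (K_Dⁿ + [P]ⁿ).
  K_D (mol/L) is the free-protein concentration at half coverage, N_max
  the saturation stoichiometry (real-valued ensemble average), n the
  cooperativity.  [P] is the *total* protein concentration, valid when
  protein is in large excess over NP binding sites — the same assumption
  that sets the ~0.01 µM lower bound on measurable K_D for
  absorbance-detected AuNPs (the fitter warns when a fit violates it,
  and when saturating concentrations would exceed ~10 mM, where solution
  viscosity invalidates the sedimentation analysis).
- **Frictional ratio** from a measured (s, D) pair at an assumed analyte
  density:  f/f₀ = [k_B T/(3πηD) · √((ρ_p − ρ_s)/(18ηs))]^{2/3}.  Exactly
  1 for sphere-consistent pairs; > 1 when friction is elevated
  (elongation).  Requires ρ_p > ρ_s — there is no real equivalent sphere
  otherwise, and such rows are flagged rather than computed.

The binding model fitted to data is the composition
s̄([P]) = complex_s(N_avg([P])): three free parameters (K_D, N_max, n)
with the particle, protein and solvent held at independently measured
values. BSA is packaged with the triangular-prism hydrodynamic volume
(equilateral 8.4 nm edge, 3.2 nm thickness → 97.8 nm³) and ρ_P = 1.3
g/cm³; both are configuration, not constants baked into the math.

Internally everything is SI; Svedberg (1 S = 1e-13 s), g/cm³, nm and µM
appear only at the I/O boundary. Back-conversions use division by the
same literals so conventional config values round-trip bit-exactly.

## Lamm-equation solver

The SV forward model is the Lamm equation in a sector cell,
∂c/∂t = (1/r) ∂/∂r [r D ∂c/∂r − s ω² r² c], with no-flux boundaries at
the meniscus and base, uniform (well-mixed) initial loading, and an
instantaneous rotor start (the acceleration ramp is neglected; for the
6,000–12,000 r.p.m. speeds relevant here the ramp is a small fraction of
run time).

Discretization is a conservative finite volume on a uniform radial grid
(default 400 cells). Face fluxes are central-differenced where the cell
Péclet number |Pe| < 2 (second-order) and Scharfetter–Gummel
exponentially fitted where advection dominates; the scheme therefore
stays monotone down to D = 0 exactly (pure upwind limit), which the
diffusion-free boundary test exploits. Time stepping is Crank–Nicolson
with sub-steps capped by a Courant number of 0.4 on the advective speed
at the base and 2 h²/D on diffusion. Because the face fluxes telescope
and both end fluxes vanish, the sector-weighted mass Σ cᵢ rᵢ h is
conserved to linear-solver round-off at every step — the mass test
asserts 1e-6 but machine precision is observed.

Verified analytic limits: the diffusion-free boundary midpoint tracks
r_m·exp(s ω² t) to <0.01%; the plateau obeys the square dilution law
c₀·exp(−2 s ω² t) to <0.1%; halving spatial and temporal steps changes
scans by <0.1% of loading at 800→1600 cells over the radial analysis
window (1 mm inside each end). The back-diffusion pellet layer at the
base (thickness ~D/(sω²r_b), often below one cell) is deliberately left
under-resolved: it is excluded from every analysis window, mirroring how
c(s) software masks the optically unreliable base region in real data.

The optical model folds concentration, path length and extinction into a
single per-species signal amplitude (OD). Detection at the AuNP plasmon
wavelength (520 nm) is represented by giving free protein zero signal.
Gaussian i.i.d. noise per (time, radius) point with configurable σ
(default 0.005 OD — a choice, not a measured value) and an explicit seed
models photometer noise; time-invariant and radial-invariant systematic
noise of real absorbance optics is *not* modelled, so ingestion of real
scan files is best-effort.

## c(s)-style inversion

Scans are fitted as a nonnegative superposition of noise-free Lamm
solutions on a sedimentation-coefficient grid, each basis function
carrying the diffusion coefficient implied by the f/f₀ scaling law at a
single assumed frictional ratio. Nonnegative least squares with Tikhonov
regularization on the second difference (strength scaled by the mean
basis column norm) stabilizes the inversion; regularization strength 0
is the interpolation limit, and the refit RMSD is non-decreasing in the
strength (tested). The basis discretization defaults to the data's
radial sampling so numerical diffusion is comparable between basis and
simulated data.

A one-dimensional line search over f/f₀ candidates replaces the full
two-dimensional c(s, f/f₀) optimization of dedicated AUC software: the
downstream isotherm analysis consumes only the signal-weighted average
s̄ and an effective D. When the refit RMSD is flat across candidates
(<2% relative spread) the data do not constrain diffusion — typically a
species that pellets too fast at the chosen rotor speed — and f/f₀ is
reported with an "unresolved" warning. The closed-loop tests slow the
rotor for fast species exactly as an experimentalist would, keeping
boundary diffusion observable; with that design, single-species s is
recovered within 1% and D within 10% at 0.005 OD noise on 0.8 OD
loading. Meniscus and base are taken as known from metadata, never
fitted.

## Isotherm fitting

Weighted nonlinear least squares in (log₁₀ K_D, N_max, n): weights are
1/s_sd² from the replicate SDs (with a 1e-3·median floor against
near-zero triplicate sample SDs), unit weights when SDs are absent.
Because Hill fits are multi-modal along a curved (K_D, N_max, n) ridge,
the optimizer multi-starts a bounded trust-region solver from an 8-point
log-spaced K_D grid (1e-8 to 1e-3 M) crossed with n ∈ {0.6, 1.0, 1.6},
then polishes the winner; truth-started refits on synthetic data no
longer beat this schedule. Bounds: K_D ∈ [1e-9, 1e-1] M, N_max ∈
[0, 10× a geometric shell-packing estimate], n ∈ [0.2, 5]. N_max is
fitted as continuous and reported with its SE (integer-rounded only for
display). Standard errors come from the Jacobian at the optimum
(delta-method back-transform for K_D); a seeded parametric bootstrap is
available as a cross-check and its nominal 68% intervals calibrate to
55–80% empirical coverage on synthetic replicates.

Degenerate inputs are handled explicitly: concentration-independent s
returns a "no binding detected" outcome with N_max pinned at zero rather
than a spurious fit; fewer than 5 points is an error; a missing
zero/low-concentration anchor is warned. Adsorption is assumed
reversible and equilibrated (the Hill formalism requires it); the
dilution-shift operation forward-predicts the classic reversibility
check — re-equilibration after an N-fold dilution shifts s̄ *up* in the
protein-coat-slows regime — but no kinetics are modelled.

### Known limitation: median bias at tight tolerances

At the standard synthetic protocol (2% relative noise per replicate,
triplicates, 12 log-spaced concentrations over [K_D/30, 100 K_D] plus
zero), the least-squares estimator's sampling distribution is
right-skewed along the model ridge: K_D and N_max fluctuate upward
together more easily than downward, because s̄(c) flattens near
saturation. For the MUS(m)/BSA parameter set (K_D = 1.1 µM, N_max = 10,
n = 1.3) the 30-replicate median K_D lands near 1.25–1.3 µM (+15–20%),
shrinking to +3.5% at 0.5% noise — a consistency, not correctness,
issue. Systems with broader published uncertainties (MUA, citrate) are
unaffected at their tolerances. This is a property of the estimator
under these conditions, not of the implementation; the conditions are
deliberately not adjusted to mask it.

## Shape analysis

Given a converged fit and measured (s, D) pairs per concentration, the
coverage N_avg follows by direct Hill back-calculation (no refitting),
the complex density by the volume-weighted mean, and f/f₀ from the
measured pair at that density. Error bars propagate replicate SDs to
first order (∂ln f/f₀ = −⅔ ∂ln D − ⅓ ∂ln s); the series is not
smoothed. Rows whose model density does not exceed the solvent density
are flagged and carry no f/f₀. The output records the standing caveat
that the thermodynamic parameters were obtained under a near-spherical
assumption, so the f/f₀ series is a post-hoc qualitative diagnostic —
sufficient to distinguish "stays spherical" from "transient elongation
at low coverage", not a quantitative axial-ratio reconstruction.

## Synthetic data and what the tests show

The generator emulates the study conditions of the reference
characterizations packaged in `FIXTURES` (four DGU-fractionated AuNP
preparations with BSA, one with HSA; hydrodynamic diameters 5.6–13.6 nm,
densities 2.4–17.7 g/cm³, K_D 0.57–13.6 µM). Noisy isotherms use
multiplicative Gaussian noise of 2% relative SD per replicate draw with
triplicate means and sample SDs — matching the visual magnitude of
typical triplicate error bars, a choice never asserted as measured.
Scan-set experiments compose Hill coverage → complex hydrodynamics →
Lamm simulation at 0.8 OD loading, 45 scans to 90% of pelleting time,
with an optional imposed f/f₀ to emulate shape anisotropy. All
randomness flows through explicit seeds; there is no global random
state.

Passing closed-loop tests therefore demonstrate internal consistency of
simulation + inversion + fitting under idealized conditions — single
monodisperse species per run, exactly Gaussian noise, known meniscus and
density, no systematic optical offsets, no polydispersity (the
published preparations have 10–16% PDI, carried as metadata only). They
do not certify accuracy on real AUC data, where those effects dominate.

Problem sizes used by the default test suite and acceptance script —
400-cell grids (800/1600 for the convergence check), 40–50 scans, 40–60
point s-grids, 30 isotherm replicates per system — were chosen as
comfortable desk-scale settings for the closed-loop checks.
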