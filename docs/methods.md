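# Model and methods

## The physical model

A filament is a planar chain of `n` identical spheres of radius `R`
(monomer spacing `d = 2R`).  Sphere `i` carries a position `(x_i, y_i)` and
an orientation angle `theta_i`; its longitudinal axis points along
`u(theta) = (-sin theta, cos theta)`, with *interaction sites* at the two
poles, `center ± R u`.  Two harmonic potentials act at every joint:

* **Bending:** `W = (b/2) (Δθ - θ0)^2`, with `Δθ = theta_{i+1} - theta_i`
  wrapped to `(-π, π]`.  `b` is the flexural rigidity of the joint
  (kT/rad², kT at the 295.15 K reference temperature) and `θ0` the
  equilibrium bend per joint (`0.2 rad` for the tubulin presets — an
  assumption consistent with the ~23°-per-dimer curvature of relaxed
  protofilament curls; `0` for generic polymers).
* **Stretching/shear:** `U = (k/2) r^2`, where `r` is the distance between
  monomer `i`'s plus site and monomer `i+1`'s minus site.  Because the
  sites ride on the orientation axes, this bond penalises both separation
  and shear of the longitudinal interface and couples positions to angles.
  The sites' placement at the sphere poles is this package's choice; it is
  the simplest geometry in which the bond energy is a function of a single
  inter-site distance.

The continuum bending modulus is `B = b·d`.  The soft mode of a joint is
rotation about the shared site (energy `b` only); the marginal equilibrium
distribution of each joint angle is exactly `Normal(θ0, kB T / b)` when the
bonds are stiff, which is the analytic anchor for most tests.

Default bond stiffness is `k = 100 kT/nm²` for the tubulin presets
(rms site separation `sqrt(2kT/k) ≈ 0.14 nm ≪ 4 nm`), and `25 kT/nm²` for
the soft-polymer preset (rms `≈ 0.28 nm ≪ 2.4 nm`) whose smaller sphere
radius would otherwise force an impractically small stable time step.  `k`
is a regularisation of the model, not a measured quantity; the shape
statistics studied here are insensitive to it (they live in the angles).

### Species presets

| preset | n | R (nm) | b (kT/rad²) | θ0 (rad) | clamped |
|---|---|---|---|---|---|
| `floppy_pf` | 16 | 2.0 | 58 | 0.2 | 2 (one dimer) |
| `rigid_pf` | 16 | 2.0 | 300 | 0.2 | 2 |
| `soft_polymer` | 16 | 1.2 | 3.3 kcal/mol/rad² at 310 K (= 5.36 kT₍₃₁₀₎) | 0 | 1 |

Clamped monomers are frozen in position *and* orientation (the
protofilament's minus-end dimer stands in for the microtubule lattice).
The soft polymer anchors a single sphere — just enough to fix the frame.

## Environment: cooling and viscosity

Temperature falls linearly, `T(t) = T0 - v t`, clamped at a stop
temperature `T_stop = Ts + 0.5 K`.  Water viscosity follows the
supercooled-water power law `η(T) = η0 (T/Ts - 1)^(-γ)` with the
atmospheric-pressure parameters (η0 = 1.38e-4 Pa·s, Ts = 225.6 K,
γ = 1.64) for plunge freezing and the 200 MPa fit (η0 = 2.2e-4 Pa·s,
Ts = 205.4 K, γ = 1.84) for high-pressure freezing.  Runs end just above
the singularity, where mobility is negligible; "immobilization" is an
emergent, reported quantity, not a stopping rule (below).

## Dynamics

Monomers obey overdamped Langevin dynamics with Stokes drags
`γ_t = 6πRη(T)` and `γ_r = 8πR³η(T)`.  Internal units are nm, µs, and kT
at 295.15 K.  (In the printed form of these update equations the
orientation update must read `∂U/∂θ`; the rotational drag makes any other
reading dimensionally impossible.)

Two propagation schemes share the same drift and noise budget:

* **`lm` (default):** the Leimkuhler–Matthews splitting, whose noise
  increment is the *average* of the current and previous step's N(0,1)
  draws.  For harmonic forces it samples the exact Boltzmann
  configurational distribution at any stable time step.  This property is
  what lets the adaptive step ride near the stability bound without
  biasing equilibrium shape statistics — with plain Euler the stationary
  variance of the stiffest (bond) mode would be ~20% high at the default
  step.
* **`euler`:** textbook Euler–Maruyama, kept for validation; the test
  suite shows it reproduces the same equilibrium statistics once its step
  is reduced (safety 0.02).

**Adaptive time step:** `dt = safety · min(γ_t/k, γ_r/(b + 2kR²))` with
`safety = 0.1`; `b + 2kR²` is the largest angular stiffness a monomer sees
(bending plus the bond's shear coupling).  dt therefore grows in
proportion to η during cooling, which is what makes slow protocols
tractable; near `T_stop` one extra cap prevents a single step from
overshooting the viscosity singularity.  A fixed-dt mode exists for
validation (free-diffusion oracles, rescaling tests).  Halving the step
leaves frozen-shape ensembles unchanged within Monte Carlo error
(tested).

**Reproducibility contract:** one seeded SFC64 generator per replicate;
exactly three N(0,1) draws per free monomer per step, consumed in a fixed
order (x, y, θ triplets, monomers ascending).  Identical inputs give
bit-identical trajectories; replicate `i` of an experiment uses
`base_seed + i`.

**Equilibrium initialisation:** joint angles drawn independently from
`Normal(θ0, kB T/b)` with bonds built at zero extension — the exact
equilibrium ensemble of the bending degrees of freedom for stiff bonds.
This sampler replaces long dynamical warm-ups (e.g. "relax for 0.1 s")
wherever an equilibrated starting ensemble is needed; a dynamical
`relax_then_freeze` mode exists and is cross-validated against it.

**Quasi-static cold start for 10⁴ K/s:** at this rate the filament
relaxation time stays orders of magnitude below the remaining cooling time
until ~1–2 K above Ts, so the shape ensemble is the equilibrium ensemble
during essentially the whole descent.  The `HPF_1e4` preset therefore
samples equilibrium at 210 K and integrates the dynamics only from there.
Simulating from ambient temperature would cost ~10¹⁰ steps per replicate
at ambient viscosity and would change nothing about the frozen shapes.

**Immobilization temperature:** the first time the free tip stays within
0.5 nm of itself over a window spanning 1 K of cooling (window = 1/v
seconds, recorded on a fixed real-time grid).  The 0.5 nm / 1 K choice was
set from the tip-fluctuation amplitude (a few nm) and the requirement that
the window see an essentially arrested shape; a step-count-based window is
unusable here because under the adaptive step the displacement per step is
scale-free.  For 10⁶ K/s plunge runs the criterion fires at ≈ −45 °C.
Under the high-pressure law the singularity sits 20 K lower and the
criterion does not fire above `T_stop`; the summary then reports NaN.

## Shape statistics

Traces are monomer-centre chains, tip first; simulation ensembles trim the
clamped monomers (their joints are artificially straight).

* **Curvature profile:** unsigned turning angle between successive chords
  of length `segment_len` (default 8 nm — one tubulin dimer), divided by
  `segment_len`, attributed to the chord-shared point at arc distance
  `s = (j+m)·d` from the tip, averaged across replicates per bin with
  s.e.m. across replicates.  On constructed shapes the estimator is exact
  for arcs and recovers linear curvature ramps to <3%.
* **Curvature gradient:** weighted least-squares slope (weights 1/sem²) of
  mean curvature vs distance from tip.  Bins are strongly correlated
  across replicates (each replicate contributes to every bin and
  neighbouring bins share chords), so the slope's error is estimated by a
  leave-one-replicate-out jackknife; on equilibrium ensembles the slope is
  then consistent with zero within ~1 se, as it must be.
* **Mean-cosine decay and persistence length:** `⟨cos(φ(s) − φ(tip))⟩`
  versus arc separation, fitted with a single-parameter exponential.
  **Convention:** by default the quoted persistence length `P` is the bare
  e-folding length of this decay (`⟨cos⟩ = exp(-s/P)`), which for planar
  equilibrium chains equals `2B/kBT`.  This is the convention under which
  the tubulin presets map onto their published persistence lengths
  (58 kT/rad² · 4 nm → ~0.5 µm; 300 → ~2.5 µm).  The strict planar
  worm-like-chain convention (`⟨cos⟩ = exp(-s/2P)`, `P = B/kBT`) is
  available via `convention="planar"`.  The choice is isolated behind this
  one flag because published 2D analyses are split between the two; it is
  the main interpretive degree of freedom in comparisons with published
  numbers.

### Known discrepancy for the soft polymer

Under the decay convention the soft-polymer preset's equilibrium
persistence length at 310 K is `2·b·d/kT = 25.7 nm` (measured:
~27 nm; the chord-based tangent estimator on a 16-mer adds a few
percent).  The published description of this polymer calls it a "20 nm"
polymer, a value that does not follow from `b = 3.3 kcal/mol/rad²` and
`d = 2.4 nm` under either convention (planar gives 12.9 nm).  The package
keeps the stated mechanical parameters and reports what they imply.  The
*relative* freezing-induced stiffening is insensitive to this offset: the
apparent persistence length rises by ×1.2–1.6 depending on protocol, in
line with the published ×1.3–1.45 (28/29/26 nm over a 20 nm baseline).
Note also that the tip-referenced decay fit is a high-variance statistic
on 16-mers: its sampling standard deviation is ≈3 nm (equilibrium) to
≈5 nm (frozen ensembles) at 100 replicates — differences between the
three freezing protocols are at the edge of resolution at the published
ensemble size.

## Experiments

`freeze_experiment` runs replicated trajectories through a protocol and
reduces final shapes to a curvature profile, its gradient, and the mean
immobilisation temperature.  `persistence_shift_experiment` equilibrates
the soft polymer at 310 K, freezes it under each protocol (cooling starts
at 310 K for the fast rates; quasi-static cold start for 10⁴ K/s), and
refits the persistence length of the immobilised shapes.
`required_rate_scan` walks a log-spaced rate grid downward per rigidity
until the ensemble gradient magnitude falls below the target (default
0.03 deg/nm²) and brackets the crossing; unreachable targets are reported
censored.  `length_independence_check` compares gradients across filament
lengths at fixed rate and rigidity.

Default replicate counts follow the published figure captions (40 at
10⁴ K/s, 100 at 10⁶/10⁷ and for polymer ensembles, 20 per scan point);
tests and the acceptance script use documented reductions (16–50) chosen
for desk-scale runtimes, with the statistical criteria evaluated at the
correspondingly wider standard errors.

## What the model does and does not capture

The synthetic data generator *is* the model: ensembles differ from real
cryo-ET observations in that there is no imaging noise, no tracing error,
no 3D-to-2D projection, no lateral neighbour interactions, no
hydrodynamic coupling between beads, and no temperature dependence of the
intrinsic stiffness `b` or curvature `θ0`.  Passing tests therefore
validate the mechanics/statistics pipeline, not the fidelity of any of
those excluded effects.  Known limitations worth keeping in mind:

* Results at 10⁶ K/s for the floppy protofilament show a small residual
  gradient (≈ −0.016 deg/nm², significant at high replicate count): with
  these parameters the slowest bending mode does not quite finish
  relaxing from the straight start before freeze-out.  This is below the
  0.03 deg/nm² threshold used for the rate-requirement scan but not
  strictly zero.
* Freeze-induced gradients are length-dependent at the short end: the
  slowest-mode relaxation time scales as L⁴, so at 1.28×10⁷ K/s a 56 nm
  filament of 2.1 µm persistence relaxes markedly further (gradient
  ≈0.013 deg/nm²) than 88 or 120 nm filaments (≈0.031–0.034, which agree
  with each other).  `length_independence_check` therefore compares
  gradients over a common near-tip fit window (the usable range of the
  shortest filament) so the comparison is not confounded by fit span.
* The Stokes drags treat each sphere independently; hydrodynamic
  screening along the chain would shorten relaxation times somewhat.
* The immobilisation temperature is operational (threshold + window) and
  stated as such; different thresholds move it within a couple of
  kelvins.
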