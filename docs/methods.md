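# Methods

## The model

`carueq` simulates calcium cycling in a voltage-clamped rabbit ventricular
myocyte as a three-dimensional lattice of calcium release units (CaRUs) and
predicts the cell's homeostatic steady state with a two-variable
general-equilibrium (nullcline) construction built from single-beat flux
measurements.

### Lattice and compartments

The cell is a rectangular array of `nx × ny × nz` CaRUs (full model
25 × 25 × 50; the reduced 8 × 8 × 16 lattice is used for routine analysis —
the model is spatially homogeneous on average, so intensive quantities are
insensitive to lattice size, a property the test suite asserts rather than
assumes).  Each CaRU spans 0.5 × 0.5 × 2 μm³ and contains five well-mixed
compartments: dyadic junction (d), subsarcolemmal shell (s), bulk cytosol
(i), junctional SR (jsr) and network SR (nsr), with volumes
v_d = 10⁻⁴, v_s = 0.04, v_i = 0.25, v_jsr = v_nsr = 0.01 μm³.  The cytosol
is half the geometric volume (mitochondria occupy the rest and are not
modelled).  The SR-to-cytosol referral ratio (v_jsr + v_nsr)/v_i = 0.08
converts a uniform local free SR concentration of 500 μM into 40 μmol per
litre of cytosol (μmol/Lcyt), the whole-cell bookkeeping unit.

Per CaRU, free calcium in each compartment follows mass-action rate
equations coupled by

* intra-CaRU diffusion, j_ds = (c_d − c_s)/τ_d, j_si = (c_s − c_i)/τ_s,
  j_tr = (c_nsr − c_jsr)/τ_tr;
* inter-CaRU diffusion of c_i, c_s and c_nsr by discrete anisotropic
  Laplacians with no-flux boundaries (the subsarcolemmal shell does not
  exist across z-planes, so its z-coupling is zero);
* membrane and SR fluxes: LCC entry into the dyad, RyR release jsr → dyad,
  SERCA uptake cytosol → nsr, and NCX exchange across the subsarcolemmal
  membrane.

SERCA follows the thermodynamically limited form
j = ν_up [(c_i/K_i)² − (c_nsr/K_sr)²] / [1 + (c_i/K_i)² + (c_nsr/K_sr)²]
with ν_up = 0.5 μM/ms in the reference cell.  NCX uses the standard
saturating electrogenic 3Na⁺:1Ca²⁺ closed form with fixed [Na]_i = 10,
[Na]_o = 136, [Ca]_o = 1.8 mM.  The LCC unitary current uses a GHK-type
driving force with the same divalent activity coefficient (0.341) on both
membrane faces; the removable singularity at V = 0 is evaluated by series.
RyR release is j_RyR = g_rel · O_RyR · (c_jsr − c_d).

### Buffers

Cytosolic buffers (troponin C, calmodulin, SR-membrane sites, with
Shannon-family site densities and kinetics) are integrated dynamically —
the global rapid-buffering approximation is deliberately avoided because it
breaks exact mass accounting.  Calsequestrin in the jSR is the one
exception: it is fast enough that the jSR state variable is *total* calcium
c_jsr_tot, split into free and bound through the rapid-buffer quadratic
c_jsr = ½[c_tot − (K+B) + √((K+B−c_tot)² + 4K c_tot)]
with B_CSQ = 3300 μM and K_CSQ = 600 μM, chosen so that 40 μmol/Lcyt of
free SR calcium corresponds to ≈100 μmol/Lcyt of total SR calcium.

### Channel gating

Channels are Markov chains sampled stochastically per time step; everything
else is deterministic.

* **LCC, 5 states (O, C1, C2, I1, I2).**  Voltage-dependent activation
  C2↔C1↔O with bounded sigmoidal rates; calcium-dependent inactivation
  O→I1 driven by dyadic calcium through a saturating Hill term; slow
  I1→I2 and I2→C2 recovery that is gated to hyperpolarized potentials
  (recovery from inactivation requires repolarization), so the channel
  group delivers a trigger pulse early in the action potential and stays
  unavailable for the rest of the plateau.  Barium-sensitive states of the
  parent scheme are omitted.
* **RyR, 4 states (O, C, I1, I2).**  The CICR trigger C→O is a Hill
  function of dyadic calcium (exponent 3, half-saturation 12.5 μM — zero
  at zero trigger calcium) multiplied by a steep luminal activation factor
  c_jsr⁴/(c_jsr⁴ + K_lum⁴), K_lum = 485 μM; inactivation O→I1 grows with
  dyadic calcium and accelerates as the jSR depletes.  The I1→I2→C path
  sets a ≈100 ms recovery time at diastolic calcium.  Release therefore
  terminates primarily by luminal depletion — which is what makes the
  per-beat release integral a steep function of SR load, the feedback the
  equilibrium analysis revolves around.

All rates have finite worst cases, so a step bound can be enforced at
construction: every per-substep exit probability must stay below 0.2.

### Pacing

The membrane potential is an imposed periodic clamp: period T = 500 ms
(2 Hz), APD = 200 ms, a 2 ms upstroke from −85 to +20 mV, a linearly
drooping plateau (30 mV over the plateau), and a 10 ms repolarization.
The equilibrium analysis is insensitive to the precise clamp shape.

## Numerical scheme

One step performs: (a) stochastic channel updates at frozen voltage and
calcium, (b) an exact exponential substep of the dyadic compartment, and
(c) explicit/semi-implicit updates of everything else.

* **Channel sampling.**  Channels within a CaRU are exchangeable, so the
  kernel stores per-state *counts* and samples transition numbers with
  exact binomial draws (conditional binomials between competing exits of
  the same state).  This is distributionally identical to per-channel
  first-order sampling with p = rate·dt, the scheme exposed by
  `channels.step_markov`.  The first-order kernel preserves the chain's
  exact stationary distribution, and a matrix-exponential oracle test
  bounds its transient error.  The time step is split so the 0.2 exit-
  probability bound holds per substep even during diastolic sparks.
* **Dyad.**  The dyadic balance dc_d/dt = A − λc_d (λ combines release
  conductance, GHK outflow and τ_d) is stiff; it is advanced exactly over
  each step with frozen coefficients, and the *integrated* fluxes
  ∫j_RyR dt, ∫j_LCC dt, ∫j_ds dt are evaluated in closed form and applied
  with opposite signs (after volume referral) to the partner compartments.
  The subsarcolemmal shell gets the same treatment (NCX and the cs↔ci
  relaxation are linear in c_s).  Mass accounting is therefore exact to
  rounding regardless of the step size.
* **Buffers.**  The bound-calcium update is backward-Euler against the
  post-transport free concentration, solved by a scalar Newton iteration
  per compartment; the resulting increment is applied with equal and
  opposite sign to the free pool, so the exchange conserves mass exactly
  even at finite Newton residual.
* **Everything else** (SERCA, j_tr, inter-CaRU Laplacians) is explicit
  Euler.
* **Step plan.**  Fine step dt = 0.1 ms during the systolic/release window
  (first 210 ms of each beat), 0.25 ms with triple Markov sub-stepping
  afterwards.  Frozen-channel dt-halving changes single-beat ΔQ integrals
  by < 10⁻⁴ relative; with stochastic channels the Markov discretization
  contributes a comparable-to-noise O(rate·dt) transient bias that does not
  affect the stationary behavior.
* **Per-beat integrals.**  ΔQ_in, ΔQ_out, ΔQ_rel, ΔQ_up are accumulated
  step-by-step inside the kernel as exactly the sums that entered the
  concentration updates, so the whole-cell and SR mass identities
  ΔQ_T = ΔQ_in − ΔQ_out and ΔQ_SR = ΔQ_up − ΔQ_rel close to ~10⁻¹²
  μmol/Lcyt per beat (the test suite enforces ≤10⁻⁵ over 10-beat runs).
  The stored traces are for plotting; the integrals never come from
  quadrature over subsampled traces, which could not close the mass
  audit.

## The equilibrium method

For a grid of diastolic initial conditions (c_i, c_sr) — defaults 9 × 9
points over 50–400 nM × 10–80 μmol/Lcyt — the lattice is initialized
uniformly with all fast variables at their equilibria (buffers at binding
equilibrium, channel states sampled from the stationary distribution at
resting potential) and integrated for exactly one beat, R = 8 independent
replicates per point.  The four per-beat flux integrals define four
surfaces over the grid.  The f-nullcline is the zero contour of
ΔQ_in − ΔQ_out, the g-nullcline of ΔQ_up − ΔQ_rel, both extracted by
marching squares on the bilinear interpolant; their crossing — located by a
hybrid root solve on the pair of interpolants, seeded from the contour
intersection and verified to a 10⁻⁹ relative residual — is the predicted
homeostatic steady state.  Multiple crossings are reported, never silently
resolved.  `validate_crossing` checks the prediction against a long paced
run (100 beats by default, evolved diastolic values averaged over the final
10 beats).

A parameter *shock* (`shock_sweep`) rebuilds the four surfaces per
parameter value, reports the moved crossing, the steady-state transient
amplitude (beat maximum of lattice-averaged c_i minus its pre-systolic
value, normalized to 100% at the reference configuration), and classifies
the shock as single- or double-nullcline from the signed displacement of
each nullcline along the c_sr axis at matched c_i.

## Parameter provenance and calibration

The lattice geometry, cluster sizes (40 RyR, 5 LCC), pacing, ν_up = 0.5
μM/ms and the mass-balance design are fixed by the model description.
Buffer tables, the NCX closed form and the channel-scheme topology follow
the cited model families.  The remaining free scalars — g_rel, g_lcc,
v_ncx, K_i, the τ's and diffusion constants — were calibrated once so that
the wildtype 2 Hz fixed point lands near the reference diastolic point
(c_i ≈ 150 nM, free SR ≈ 40 μmol/Lcyt, total SR ≈ 100 μmol/Lcyt) and the
cell reproduces the qualitative shock phenomenology: SERCA enhancement in
the wildtype raises SR load, lowers diastolic cytosolic calcium and
*increases* the transient, while the same enhancement in the reduced-RyR
cell raises diastolic calcium and *shrinks* the transient.  Every field of
`ModelParams` carries a provenance tag ("paper", "cited-source",
"calibrated").  `carueq calibrate` (and `carueq.calibrate_balance`) ships
the final balance-tuning step: it measures the four single-beat integrals
at the target point and adjusts v_ncx (efflux scale) and K_i (uptake scale)
multiplicatively until both residuals vanish.

Design choices that shape the phenomenology (all exposed as parameters):

* Release must be pulse-like and steeply load-dependent (steep luminal
  gating, slow jSR refill τ_tr = 30 ms, absorbing LCC inactivation during
  the plateau).  A slow, weakly load-sensitive release — the reduced-RyR
  preset, unitary conductance × 0.03 — flips the sweep response to the
  therapy-failure regime.
* NCX export must track bulk cytosolic calcium rather than local release
  spikes (tight subsarcolemma–cytosol coupling, τ_s = 0.25 ms), so that a
  SERCA shock forces a large SR-load adjustment instead of being absorbed
  by the release-driven subsarcolemmal transient.
* K_sr = 4000 μM keeps the SERCA thermodynamic stall point below the
  diastolic operating range at every SR load reached in the sweeps.

## What the simulations do and do not show

All experiments are simulation-driven; there is no external biological
data.  The generator's defaults are the study conditions: 2 Hz pacing of a
calibrated wildtype rabbit cell and its documented variants.  Passing tests
demonstrate internal consistency (exact mass balance, kernel-vs-oracle
agreement, fixed-point prediction matching long-run evolution, and the
qualitative shock structure) at reduced lattice sizes; they do not
demonstrate quantitative agreement with any particular experimental myocyte
beyond the calibration anchors, and the calcium-transient amplitude of the
calibrated cell (≈0.15 μM above a 150 nM diastole) is at the low end of the
physiological range — a consequence of calibrating the diastolic anchors
and flux balances rather than the transient itself.

## Problem sizes

Routine analysis uses the 8 × 8 × 16 lattice (9 × 9 grid, R = 8,
100-beat validation); the test suite's shock sweeps use 6 × 6 × 12 (steady
states by direct paced settling) and 4 × 4 × 8 (double-nullcline
classification) with 5 × 5 grids.  These are the package's own default
problem sizes; the full 25 × 25 × 50 lattice is property-equivalent and
available through the same API.

## Known limitations

* Mitochondrial calcium, pH/Mg competition, SR leak pathways beyond the
  RyR, and free-running membrane potential are out of scope; sodium and
  potassium are clamped.
* Only the stable-fixed-point regime is analyzed; alternans or chaotic
  regimes surface as multiple/missing crossings or validation failure, and
  no eigenvalue stability analysis is attempted.
* The two-phase step plan assumes release is over ~210 ms into the beat;
  radically different pacing protocols should shrink `t_fine`/`dt_diastole`
  accordingly.
* The nullcline machinery assumes the residual fields change sign on the
  analysis grid; shocks that push the steady state outside the default grid
  (e.g. heavy SR overload in the reduced-RyR preset) need a wider
  configured grid.
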