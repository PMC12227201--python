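# Methods

## Model

### Neurons and network

Both populations are current-based leaky integrate-and-fire point neurons:
between synaptic events the membrane relaxes exponentially toward
`V_rest + I·τ_m/C_mem` with τ_m = 20 ms and C_mem = 250 pF (input
resistance 80 MΩ); a crossing of V_th = 20 mV emits a spike, resets the
membrane to V_reset = 10 mV and starts a 2 ms absolute refractory period
during which the neuron is clamped at the reset potential and discards all
input.  Synapses are delta jumps: a presynaptic spike adds its weight (mV)
to the postsynaptic membrane after a transmission delay.

The reference network has 10 000 excitatory (E) and 2 500 inhibitory (I)
neurons.  The I-related blocks (E→I, I→E, I→I) are hard-wired before the
run as independent Bernoulli draws per directed pair (10% by default,
autapses excluded) with weights J_E = 0.1 mV and J_I = −0.8 mV; the E→E
block starts empty and is owned by the structural engine.  Every neuron
receives an independent 30 kHz external Poisson train with weight J_E,
putting the external mean drive at 60 mV — twice threshold — so the network
operates in the inhibition-dominated, fluctuation-driven regime.

Conventions the data sources leave open, fixed here once:

* integration step dt = 0.1 ms with the *exact* per-step decay factor (not
  forward Euler), jumps applied at step boundaries — for pure decay and
  constant current the integrator is exact to rounding, which the tests
  assert at 1e-12;
* synaptic delay 1.0 ms, uniform, configurable;
* inputs arriving during refractoriness are discarded, not queued;
* the facilitating current (below) is applied to all excitatory neurons
  from the start of growth.

### Calcium trace

Each neuron low-pass filters its own spike train,
`dC/dt = −C/τ_Ca + β_Ca·S(t)`, with τ_Ca = 10 s and β_Ca = 1e-4.  The
trace decays by the exact factor every membrane step and gains β_Ca after
the decay on spiking steps (the ordering matters only at O(dt); fixing it
makes runs bit-reproducible).  In steady state the time-averaged trace is
`rate·β_Ca·τ_Ca`, so concentration setpoints translate to rate setpoints at
0.001 per Hz: ε = 0.0079 ↔ 7.9 Hz, η = 0.0007 ↔ 0.7 Hz.

### Growth rules

Element counts z (axonal and dendritic separately) follow dz/dt = f(C):

* linear: `f(C) = ν(1 − C/ε)` — outgrowth below the setpoint, retraction
  above it; ν = 0.00395 s⁻¹ at the reference parameter scale;
* Gaussian: `f(C) = ν(2·exp(−((C−ξ)/ζ)²) − 1)` with ξ = (η+ε)/2 and
  ζ = (ε−η)/(2√ln2).  This is the unique smooth curve of this family with
  zeros exactly at η and ε, peak +ν midway between them, and retraction
  saturating at −ν for high calcium.  (The width is sometimes written as
  (η−ε)/(2√ln(1/2)), which is imaginary; the form above is the
  real-valued width with the same intent.)  η = 0 gives the zero-Gaussian
  rule, under which silent neurons freeze; η > 0 the biphasic rule, under
  which they retract.

### Structural engine

Synaptic elements are connection ports; a synapse binds one axonal element
of the presynaptic neuron to one dendritic element of the postsynaptic
neuron.  Every 100 ms (configurable; long against dt, short against growth,
ν·interval ≪ 1 element):

1. element counts take one Euler step from the calcium sampled at the
   boundary, clamped at zero;
2. any neuron whose bound elements of a type exceed ⌊z⌋ breaks the surplus,
   choosing uniformly (multiplicity-weighted) among its bound synapses of
   that type; axonal surpluses are processed first, then dendritic
   surpluses are recomputed.  The partner of a broken synapse keeps its
   element — it returns to the free pool, which is what turns deprivation
   into *rewiring* rather than pure loss;
3. all free axonal and free dendritic elements are pooled globally,
   shuffled, and paired; autapse pairs are rejected with one re-shuffle
   round, leftovers stay free.  New synapses carry the unit weight J_EE.
   Multapses (multiple synapses per ordered pair) are allowed and tracked
   as multiplicities; per-pair weights are pooled, so deleting one synapse
   of a pair removes the average share.

The engine maintains the exact invariant Σ connected_axonal =
Σ connected_dendritic = total multiplicity, checked in the tests at every
boundary and against a naive loop-based reference implementation
state-for-state over 100 cycles.

### Homeostatic synaptic scaling

Weights of E→E synapses onto neuron j follow `dw/dt = ρ·w·(ε − C_j)` —
multiplicative and cell-autonomous (all inputs of a neuron scale by one
factor, preserving their ratios).  This rule is sometimes written with the
drive term reversed (C − ε), but the behavior it is meant to produce —
upscaling under deprivation, downscaling under over-excitation — requires
ε − C; we implement that and expose `sign="calcium_minus_setpoint"` for the reversed
convention.  Scaling is
applied at the structural cadence, the discrete factor is floored at zero,
weights are floored at w_min = 0, and newly formed synapses always start at
J_EE regardless of scaling history.  With ρ = 0 the weight matrix equals
J_EE times the count matrix exactly, so structural and effective
connectivity coincide — a test asserts this identity through a live run.

## Desk-scale preset

Full-scale runs need a cluster; all quantitative results here use a
1000 E + 250 I preset engineered to reproduce the full-scale operating
point.  Three choices matter, each made once and frozen:

* **Static indegrees, not probabilities, are preserved.**  With wiring
  probabilities held at 10%, a tenfold smaller network delivers one tenth
  of the inhibition per neuron and loses inhibition dominance (mean-field
  excitatory rates ≈ 70 Hz with an empty E→E block — far above the
  setpoint, so the growth rules would never grow).  The preset instead
  wires the static blocks all-to-all (p = 1), which at these sizes
  reproduces the full-scale indegrees exactly: 1000 E and ~250 I inputs per
  I neuron, 250 I inputs per E neuron, with unchanged weights.
* **Plastic unit weight J_EE = 0.8 mV.**  The equilibrium the growth rules
  seek is "whatever E-E drive brings the mean excitatory rate to 7.9 Hz";
  at desk scale that drive is ≈ 79 mV·synapse-units.  Pure mean-field
  matching (J_EE = 1.0 mV) parks the connection probability at 7.9%
  because the coarser-grained weights make the network slightly more
  excitable per unit of mean drive.  The unit weight is therefore
  calibrated once, on the linear rule, so that equilibrium lands at the
  full-scale 10% connection probability (~100 input synapses per neuron);
  0.8 mV gives Γ = 10.1% at 7.94 Hz.  The biphasic protocol reuses the
  value untouched.
* **Plasticity rates are accelerated; durations shortened.**  Growth rates
  are 100× the reference per-second values (0.395 s⁻¹ linear, 0.4 s⁻¹
  Gaussian), which preserves the dimensionless loop gain — elements added
  per calcium time constant relative to the equilibrium indegree — and
  keeps growth stable and overshoot-free.  Scaling strengths are 25 times the
  reference values: rescue after silencing is a race between input
  up-scaling (time scale ∝ 1/(ρ·ε)) and element retraction (complete,
  irreversible disconnection after z_eq/(0.26·ν) ≈ 10³ s at desk scale),
  and the factor 25 places the reference pair {0.01, 0.02} on opposite sides
  of that boundary, as it is at full scale.  Growth runs 1000 s (linear) or
  1600 s (biphasic, facilitating current decaying over the first 1200 s);
  equilibria are read as means over the final 150 s after a plateau check.

### Facilitating current

The biphasic rule cannot grow an empty network unaided: neurons below the
lower setpoint retract.  A somatic current injected into all excitatory
neurons, starting at 750 pA (+60 mV equivalent) and decaying linearly to
zero over the growth phase, carries the network through; connectivity
forms late in the decay, once calcium falls back into the growth zone, and
persists after the current vanishes.

### Perturbation protocols

All perturbations target a seeded random 10% of the excitatory population
and start from the grown biphasic network.  The external drive of the
subpopulation is multiplied by FOI ("fold of original intensity"):
110% prunes the subnetwork's synapses while its rate returns to the
setpoint; 95% adds synapses with the same rate recovery; 0% (silencing)
with ρ = 0 leads to complete, irreversible disconnection, and with
sufficient scaling to reactivation and synapse regeneration.  Recovery in
the growth-rate × scaling-strength sweeps is scored by the signed
trapezoidal area between a trace (subpopulation connectivity or rate) and
its target from silencing to the end of the run.

## Numerics

* External Poisson counts are sampled by exact CDF inversion: the unit
  interval is split into 2¹⁶ buckets mapping straight to counts, and the
  ~14 buckets per rate that straddle a CDF boundary fall back to a
  full-precision CDF walk.  Uniforms come from an inline xorshift64*
  generator.  The sampled law is the exact Poisson distribution; the
  choice is purely a speed matter (~3 ns per draw).
* All randomness in a run — static wiring, kernel stream, structural
  pairing — derives from one seed sequence; identical seed and
  configuration give bit-identical spike trains, wiring and traces, which
  a test asserts.
* Degenerate inputs are defined: p = 0 wires nothing, rate 0 never fires,
  empty element pools form nothing, a store/element bookkeeping mismatch
  raises immediately, and non-finite membrane potentials abort with a
  diagnostic.

## What the desk runs do and do not show

The preset reproduces the full-scale mean drive and total input variance
per neuron, and with them the homeostatic equilibria and the qualitative
perturbation outcomes.  It does not reproduce the full-scale *correlation*
structure: with only 250 inhibitory neurons wired all-to-all, the common
component of the inhibitory fluctuation is about three times larger than
at full scale, which makes near-threshold transfer steeper and population
activity burstier.  Desk-scale equilibria are therefore calibrated (the
J_EE choice above), and magnitudes of transient responses should not be
read as full-scale predictions; signs, orderings and setpoint convergence
are the meaningful outputs.  Absolute synapse counts scale with N_E (~100
per neuron here versus ~1000 at full scale); connection probabilities and
rates are scale-free.  Full-scale runs are supported by the same code
(~2 GB for the dense weight matrix) but are not exercised by the test
suite.

## Known limitations

* Only the E→E block is plastic; inhibitory structural plasticity and
  scaling of external or inhibitory synapses are out of scope.
* Partner selection is uniform; no distance- or topology-dependent wiring.
* Per-pair synapse weights are pooled (deleting one synapse of a multapse
  removes the average weight share), which is exact under pure scaling but
  coarser than per-synapse identity if future rules individualized weights
  within a pair.
* Calcium influx is per postsynaptic spike only; no NMDA/voltage-dependent
  terms, no compartmental structure.
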