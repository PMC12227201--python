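# plastinet

Spiking-network simulation of **homeostatic structural plasticity** and
**homeostatic synaptic scaling** — two calcium-driven mechanisms by which
cortical and hippocampal neurons hold their activity at a setpoint, one by
growing, pruning and rewiring synapses, the other by multiplicatively
adjusting synaptic weights.  The package is for computational
neuroscientists who want to study how the two mechanisms interact: how a
network wires itself up from nothing, how it responds to stimulation,
deprivation or complete silencing of a subpopulation, and when synaptic
scaling can rescue a silenced subnetwork from irreversible disconnection.

## Model

An inhibition-dominated random network of current-based leaky
integrate-and-fire neurons (10 000 E + 2 500 I at reference scale; a
calibrated 1000 E + 250 I desk preset for workstation runs).  Every neuron
filters its own spike train into a calcium trace

    dC/dt = −C/τ_Ca + β_Ca · S(t),        τ_Ca = 10 s, β_Ca = 1e-4,

whose steady-state mean is rate·β_Ca·τ_Ca, so the concentration setpoint
ε = 0.0079 corresponds to 7.9 Hz.  Excitatory-to-excitatory connectivity is
built at run time from axonal and dendritic *synaptic elements* whose
counts z follow a growth rule dz/dt = f(C):

* **linear**   f(C) = ν(1 − C/ε)
* **Gaussian** f(C) = ν(2·exp(−((C−ξ)/ζ)²) − 1),  ξ = (η+ε)/2,
  ζ = (ε−η)/(2√ln2) — zeros at η and ε, peak +ν between them.  η = 0:
  silent neurons freeze ("zero-Gaussian"); η > 0: silent neurons retract
  ("biphasic").

Free elements are paired at random into synapses at every structural
update; surplus elements break synapses, freeing the partner's element for
rewiring.  In parallel, each E→E weight onto neuron j follows the scaling
rule

    dw/dt = ρ · w · (ε − C_j),

multiplicative and cell-autonomous.  Protocol drivers reproduce the study
designs: network growth under each rule (the biphasic rule with a 750 pA
facilitating current decaying over the growth phase), perturbation of a 10%
excitatory subpopulation by a fold-of-original-intensity (FOI) factor on
its external Poisson drive, silencing-plus-scaling rescue, and growth-rate
× scaling-strength sweeps scored by deviation-from-setpoint areas.

## Worked example

Grow the desk-scale network from an empty E-E block under the linear rule
and read off its equilibrium:

```python
from plastinet.protocols import desk_config, desk_clock, grow_network, equilibrium_value

sim = grow_network(desk_clock("linear"), t_grow=1000.0, config=desk_config(seed=1))
tr = sim.traces
print(f"connection probability: {equilibrium_value(tr, 'gamma_ee'):.4f}")
print(f"mean excitatory rate:   {equilibrium_value(tr, 'rate_e'):.2f} Hz")
print(f"input synapses/neuron:  {sim.structural_matrix().sum(axis=1).mean():.1f}")
```

prints (about two minutes on one core):

```
connection probability: 0.1012
mean excitatory rate:   7.87 Hz
input synapses/neuron:  101.2
```

The network wires itself to ~10% connection probability — every excitatory
neuron ends up with ~100 input synapses (~1000 at reference scale) — and
the population rate settles at the 7.9 Hz setpoint encoded by ε.  The same
drivers are available from the shell:

```bash
plastinet grow --rule biphasic --seed 1 --outdir runs/biphasic   # facilitating current, 750 pA
plastinet perturb --foi 0.0 --seed 1 --outdir runs/silencing     # silence a 10% subpopulation
plastinet rescue --rho 0.02 --seed 1 --outdir runs/rescue        # silencing + synaptic scaling
plastinet sweep --rhos 0,0.01,0.02 --outdir runs/sweep           # recovery-score grid
```

Every run writes a manifest (config + seeds + version), a TSV trace table,
and Matrix Market snapshots of the synapse-count and weight matrices.

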