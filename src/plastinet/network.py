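"""Network and neuron parameters, static wiring, external drive.

The network is an inhibition-dominated random network of current-based
leaky integrate-and-fire neurons.  Synapses are delta jumps: a presynaptic
spike adds its weight (mV) to the postsynaptic membrane after a fixed
transmission delay.  Inhibitory neurons are hard-wired before the simulation
(I-I, I-E and E-I blocks drawn as independent Bernoulli per directed pair);
the E-E block starts empty and is built at run time by the structural
engine.  Every neuron additionally receives an independent external Poisson
spike train of rate ``r_ext`` with excitatory weight ``j_e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "CurrentSchedule",
    "build_static_weights",
    "step_membrane",
    "poisson_drive",
    "facilitating_current",
]


@dataclass(frozen=True)
class NeuronParams:
    """Point-neuron parameters (defaults are the reference values).

    tau_m : membrane time constant (ms)
    t_ref : absolute refractory period (ms)
    v_rest : resting / initial potential (mV)
    v_reset : post-spike reset potential (mV)
    v_th : spike threshold (mV)
    c_mem : membrane capacitance (pF)
    """

    tau_m: float = 20.0
    t_ref: float = 2.0
    v_rest: float = 0.0
    v_reset: float = 10.0
    v_th: float = 20.0
    c_mem: float = 250.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be non-negative, got {self.t_ref}")
        if not self.v_reset < self.v_th:
            raise ValueError("v_reset must lie below v_th")
        if self.c_mem <= 0:
            raise ValueError(f"c_mem must be positive, got {self.c_mem}")

    @property
    def resistance_mohm(self) -> float:
        """Membrane resistance tau_m / c_mem in MOhm (80 with defaults)."""
        return self.tau_m / self.c_mem * 1e3


@dataclass(frozen=True)
class NetworkConfig:
    """Network sizes, static wiring and external drive.

    n_e, n_i : excitatory / inhibitory population sizes
    p_static : Bernoulli wiring probability of the I-I, I-E and E-I blocks
    p_e_to_i, p_i_to_e, p_i_to_i : optional per-block overrides of
        ``p_static`` (scaled-down presets use these to hold per-neuron
        indegrees at their full-scale values)
    j_e : excitatory PSP jump (mV); used for E->I wiring and external drive
    j_i : inhibitory PSP jump (mV, negative)
    j_ee : unit weight of plastic E-E synapses (mV); defaults to ``j_e``
    r_ext : external Poisson rate per neuron (Hz)
    delay : synaptic transmission delay (ms)
    seed : master random seed of the run
    """

    n_e: int = 10000
    n_i: int = 2500
    p_static: float = 0.1
    j_e: float = 0.1
    j_i: float = -0.8
    j_ee: float | None = None
    r_ext: float = 30000.0
    delay: float = 1.0
    seed: int = 0
    p_e_to_i: float | None = None
    p_i_to_e: float | None = None
    p_i_to_i: float | None = None

    def __post_init__(self) -> None:
        if self.n_e <= 0 or self.n_i <= 0:
            raise ValueError("population sizes must be positive")
        for p in (self.p_static, self.p_e_to_i, self.p_i_to_e, self.p_i_to_i):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"wiring probabilities must be in [0, 1], got {p}")
        if self.j_e <= 0:
            raise ValueError(f"j_e must be positive, got {self.j_e}")
        if self.j_i >= 0:
            raise ValueError(f"j_i must be negative, got {self.j_i}")
        if self.r_ext < 0:
            raise ValueError(f"r_ext must be non-negative, got {self.r_ext}")
        if self.delay <= 0:
            raise ValueError(f"delay must be positive, got {self.delay}")

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @property
    def j_ee_eff(self) -> float:
        """Unit weight of newly formed E-E synapses (mV)."""
        return self.j_e if self.j_ee is None else self.j_ee


@dataclass(frozen=True)
class CurrentSchedule:
    """Linearly decaying facilitating current injected into excitatory somata.

    i0 : initial amplitude (pA)
    t_end_decay : time (s) at which the current reaches zero
    targets : population selector (only "excitatory" is supported)
    """

    i0: float = 750.0
    t_end_decay: float = 4000.0
    targets: str = "excitatory"

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise ValueError("i0 must be non-negative")
        if self.t_end_decay <= 0:
            raise ValueError("t_end_decay must be positive")
        if self.targets != "excitatory":
            raise ValueError("only excitatory targets are supported")

    def amplitude(self, t: float) -> float:
        """Current (pA) at time ``t`` (s): i0 * max(0, 1 - t / t_end_decay)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        return self.i0 * max(0.0, 1.0 - t / self.t_end_decay)


def facilitating_current(schedule: CurrentSchedule, t: float) -> float:
    """Per-target-neuron injected current (pA) at time ``t`` (s)."""
    return schedule.amplitude(t)


def build_static_weights(config: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    """Dense (n_total, n_total) weight matrix [presynaptic, postsynaptic] in mV.

    Wires the I-I, I-E and E-I blocks with independent Bernoulli(p_static)
    draws per directed pair (autapses excluded); the E-E block is left empty
    for the structural engine.  Neuron ids 0..n_e-1 are excitatory,
    n_e..n_e+n_i-1 inhibitory.
    """
    ne, ni, n = config.n_e, config.n_i, config.n_total
    w = np.zeros((n, n), dtype=np.float64)

    def p_of(block_p):
        return config.p_static if block_p is None else block_p

    # E -> I
    w[:ne, ne:] = np.where(
        rng.random((ne, ni)) < p_of(config.p_e_to_i), config.j_e, 0.0
    )
    # I -> E
    w[ne:, :ne] = np.where(
        rng.random((ni, ne)) < p_of(config.p_i_to_e), config.j_i, 0.0
    )
    # I -> I, no autapses
    wii = np.where(rng.random((ni, ni)) < p_of(config.p_i_to_i), config.j_i, 0.0)
    np.fill_diagonal(wii, 0.0)
    w[ne:, ne:] = wii
    return w


def step_membrane(
    V: np.ndarray,
    ref_remaining: np.ndarray,
    params: NeuronParams,
    dt: float,
    external_jumps=0.0,
    recurrent_jumps=0.0,
    injected_current: float = 0.0,
):
    """One membrane step for an array of neurons; returns (V, ref, spiked).

    Reference single-step semantics (the numba kernel implements the same
    update en bloc): refractory neurons count down, stay clamped at
    ``v_reset`` and discard all input; the rest relax exponentially toward
    ``v_rest + I*tau_m/c_mem`` over ``dt`` seconds, receive their synaptic
    jumps (mV, already delayed by the transmission delay), and spike on
    reaching threshold, resetting and starting the refractory clock.

    ``ref_remaining`` is in seconds and is updated in place semantics-free:
    new arrays are returned.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = np.asarray(V, dtype=float)
    ref = np.asarray(ref_remaining, dtype=float)
    mu = params.v_rest + injected_current * params.tau_m / params.c_mem
    decay = math.exp(-dt * 1e3 / params.tau_m)
    active = ref <= 0.0
    v_new = np.where(
        active,
        mu + (V - mu) * decay + np.asarray(external_jumps) + np.asarray(recurrent_jumps),
        params.v_reset,
    )
    spiked = active & (v_new >= params.v_th)
    v_new = np.where(spiked, params.v_reset, v_new)
    ref_new = np.where(
        spiked, params.t_ref * 1e-3, np.maximum(ref - np.where(active, 0.0, dt), 0.0)
    )
    if not np.isfinite(v_new).all():
        raise FloatingPointError("non-finite membrane potential")
    return v_new, ref_new, spiked


def poisson_drive(
    rate: float,
    n_neurons: int,
    dt: float,
    rng: np.random.Generator,
    n_steps: int = 1,
) -> np.ndarray:
    """External spike counts per neuron and step, ~ Poisson(rate * dt).

    ``rate`` in Hz, ``dt`` in seconds.  Returns shape (n_neurons,) for
    ``n_steps == 1``, else (n_steps, n_neurons).  Each external spike
    contributes one excitatory jump of ``j_e`` to the membrane.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    shape = (n_neurons,) if n_steps == 1 else (n_steps, n_neurons)
    return rng.poisson(rate * dt, size=shape)
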