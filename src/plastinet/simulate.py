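"""Closed-loop simulation: membrane dynamics + structural plasticity + scaling.

A :class:`Simulation` owns the full network state (membrane potentials,
refractory clocks, calcium traces, the dense weight matrix with its plastic
E-E block, and the synaptic-element bookkeeping) and advances it in blocks
of one structural-update interval (default 100 ms of biological time, 1000
membrane steps at dt = 0.1 ms):

1. the numba kernel integrates membranes, delivers delayed spikes, draws the
   external Poisson drive and updates calcium for the whole block;
2. at the block boundary the structural engine integrates element counts,
   breaks surplus synapses and forms new ones from the free-element pools;
3. the scaling rule, when enabled, multiplies each neuron's E-E input
   weights toward its calcium setpoint;
4. at recording boundaries population rates and block connectivities are
   appended to the trace table.

All randomness derives from ``config.seed``: the static wiring, the kernel's
Poisson stream and the structural engine's pairing draws use independent
children of one seed sequence, so identical seed and configuration give
bit-identical runs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import _kernel
from .calcium import CalciumParams
from .elements import ElementState, StructuralClock, SynapseStore, structural_update
from .metrics import block_connectivity, effective_connectivity
from .network import (
    CurrentSchedule,
    NetworkConfig,
    NeuronParams,
    build_static_weights,
)
from .scaling import ScalingParams, scale_weights

__all__ = ["Simulation", "build_network"]


class Simulation:
    """Spiking network with optional structural plasticity and scaling.

    Parameters
    ----------
    config : NetworkConfig
    neuron : NeuronParams
    calcium : CalciumParams
    clock : StructuralClock or None — growth rules and structural cadence;
        None freezes the E-E block (pure membrane simulation).
    scaling : ScalingParams or None — E-E weight scaling.
    current : CurrentSchedule or None — facilitating somatic current for
        excitatory neurons.
    subpop : array of excitatory ids subject to external-drive perturbation.
    dt : membrane step (s)
    chunk_interval : block length (s) when ``clock`` is None
    record_interval : trace cadence (s); must be a multiple of the block
    record_spikes : keep a spike raster (meant for small networks)
    """

    def __init__(
        self,
        config: NetworkConfig,
        neuron: NeuronParams | None = None,
        calcium: CalciumParams | None = None,
        clock: StructuralClock | None = None,
        scaling: ScalingParams | None = None,
        current: CurrentSchedule | None = None,
        subpop: np.ndarray | None = None,
        dt: float = 1e-4,
        chunk_interval: float = 0.1,
        record_interval: float = 5.0,
        record_spikes: bool = False,
    ):
        self.config = config
        self.neuron = neuron or NeuronParams()
        self.calcium_params = calcium or CalciumParams()
        self.clock = clock
        self.scaling = scaling
        self.current = current
        self.dt = float(dt)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        interval = clock.update_interval if clock is not None else chunk_interval
        self._block_steps = int(round(interval / self.dt))
        if self._block_steps < 1:
            raise ValueError("block interval shorter than one membrane step")
        self.block_interval = self._block_steps * self.dt
        self._record_blocks = max(1, int(round(record_interval / self.block_interval)))
        self.record_interval = self._record_blocks * self.block_interval

        n = config.n_total
        ne = config.n_e
        ss = np.random.SeedSequence(config.seed)
        s_wire, s_kernel, s_struct = ss.spawn(3)
        self._rng_struct = np.random.default_rng(s_struct)
        state = np.uint64(s_kernel.generate_state(1, dtype=np.uint64)[0])
        if state == 0:
            state = np.uint64(0x9E3779B97F4A7C15)
        self._rng_state = np.array([state], dtype=np.uint64)

        self.W = build_static_weights(config, np.random.default_rng(s_wire))
        self.store = SynapseStore(ne, config.j_ee_eff, weights=self.W[:ne, :ne])
        self.elements = ElementState.zeros(ne)

        self.V = np.full(n, self.neuron.v_rest)
        self.ref = np.zeros(n, dtype=np.int64)
        self.Ca = np.zeros(n)
        delay_steps = int(round(config.delay * 1e-3 / self.dt))
        if delay_steps < 1:
            raise ValueError("delay must be at least one membrane step")
        self._buf = np.zeros((delay_steps, n))
        self._slot = 0
        self._mu = np.full(n, self.neuron.v_rest)
        self._decay = math.exp(-self.dt * 1e3 / self.neuron.tau_m)
        self._ca_decay = math.exp(-self.dt / self.calcium_params.tau_ca)
        self._ref_steps = int(round(self.neuron.t_ref * 1e-3 / self.dt))

        self._ext_rate = np.full(n, float(config.r_ext))
        self._rebuild_tables()

        self.subpop = None if subpop is None else np.asarray(subpop, dtype=np.int64)
        self._steps_done = 0
        self._win_counts = np.zeros(n, dtype=np.int64)
        self._blocks_done = 0
        self._rows: list[dict] = []
        self.record_spikes = record_spikes
        self._spike_steps: list[np.ndarray] = []
        self._spike_ids: list[np.ndarray] = []
        self._rec_cap = min(2_000_000, n * self._block_steps) if record_spikes else 1
        self._rec_step = np.zeros(self._rec_cap, dtype=np.int64)
        self._rec_id = np.zeros(self._rec_cap, dtype=np.int64)
        self.dropped_spikes = 0

    def __deepcopy__(self, memo):
        """Deep copy that preserves the store-weights view into ``W``.

        A naive deepcopy would materialize ``store.weights`` as an array
        detached from the membrane kernel's weight matrix, silently freezing
        the synaptic drive at branch time.
        """
        import copy as _copy

        new = object.__new__(Simulation)
        memo[id(self)] = new
        for key, value in self.__dict__.items():
            if key in ("W", "store"):
                continue
            setattr(new, key, _copy.deepcopy(value, memo))
        new.W = self.W.copy()
        ne = self.config.n_e
        store = SynapseStore(
            ne, self.store.j_e, weights=new.W[:ne, :ne],
            log_events=self.store.log_events,
        )
        store.counts = self.store.counts.copy()
        store.events = list(self.store.events)
        store.total_formed = self.store.total_formed
        store.total_deleted = self.store.total_deleted
        new.store = store
        return new

    # -- configuration ------------------------------------------------------

    def _rebuild_tables(self) -> None:
        rates = np.round(self._ext_rate, 9)
        uniq, idx = np.unique(rates, return_inverse=True)
        self._cdf, self._qtab = _kernel.poisson_tables(uniq * self.dt)
        self._table_idx = idx.astype(np.int64)

    def set_subpopulation(self, ids) -> None:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= self.config.n_e):
            raise ValueError("subpopulation must consist of excitatory ids")
        self.subpop = ids

    def set_foi(self, foi: float, subpop=None) -> None:
        """Multiply the external rate of the subpopulation by ``foi`` (of the base rate)."""
        if foi < 0:
            raise ValueError("FOI must be non-negative")
        if subpop is not None:
            self.set_subpopulation(subpop)
        if self.subpop is None:
            raise ValueError("no subpopulation selected")
        self._ext_rate[self.subpop] = self.config.r_ext * foi
        self._rebuild_tables()

    def enable_scaling(self, scaling: ScalingParams) -> None:
        self.scaling = scaling

    # -- state views --------------------------------------------------------

    @property
    def t(self) -> float:
        """Elapsed biological time (s)."""
        return self._steps_done * self.dt

    @property
    def n_e(self) -> int:
        return self.config.n_e

    def structural_matrix(self) -> np.ndarray:
        """E-E synapse-count matrix, rows postsynaptic, columns presynaptic."""
        return self.store.counts.T.copy()

    def weight_matrix(self) -> np.ndarray:
        """E-E summed-weight matrix (mV), rows postsynaptic, columns presynaptic."""
        return self.store.weights.T.copy()

    def spikes(self) -> tuple[np.ndarray, np.ndarray]:
        """Recorded raster as (times_s, neuron_ids)."""
        if not self._spike_steps:
            return np.empty(0), np.empty(0, dtype=np.int64)
        return (
            np.concatenate(self._spike_steps) * self.dt,
            np.concatenate(self._spike_ids),
        )

    @property
    def traces(self) -> pd.DataFrame:
        """Recorded population traces (one row per recording window)."""
        return pd.DataFrame(self._rows)

    # -- dynamics -----------------------------------------------------------

    def run_steps(self, n_steps: int) -> np.ndarray:
        """Advance the membrane/calcium kernel only; returns per-neuron spike counts."""
        counts = np.zeros(self.config.n_total, dtype=np.int64)
        self._slot, n_rec = _kernel.run_block(
            n_steps,
            self.V,
            self.ref,
            self.Ca,
            self._buf,
            self._slot,
            self.W,
            self._mu,
            self._decay,
            self._ca_decay,
            self.calcium_params.beta_ca,
            self.neuron.v_th,
            self.neuron.v_reset,
            self._ref_steps,
            counts,
            self.record_spikes,
            self._rec_step,
            self._rec_id,
            self._steps_done,
            self._cdf,
            self._qtab,
            self._table_idx,
            self.config.j_e,
            self._rng_state,
        )
        if self.record_spikes:
            total = int(counts.sum())
            if n_rec < total:
                self.dropped_spikes += total - n_rec
            self._spike_steps.append(self._rec_step[:n_rec].copy())
            self._spike_ids.append(self._rec_id[:n_rec].copy())
        self._steps_done += n_steps
        if not np.isfinite(self.V).all():
            raise FloatingPointError(
                f"non-finite membrane potential at t={self.t:.3f} s"
            )
        return counts

    def _update_current(self) -> None:
        if self.current is None:
            return
        t_mid = self.t + 0.5 * self.block_interval
        amp = self.current.amplitude(t_mid)
        dv = amp * self.neuron.tau_m / self.neuron.c_mem  # pA * ms / pF = mV
        self._mu[: self.config.n_e] = self.neuron.v_rest + dv
        self._mu[self.config.n_e :] = self.neuron.v_rest

    def _record(self) -> None:
        ne, ni = self.config.n_e, self.config.n_i
        win = self.record_interval
        rates = self._win_counts / win
        row = {
            "t": self.t,
            "rate_e": float(rates[:ne].mean()),
            "rate_e_sd": float(rates[:ne].std()),
            "rate_i": float(rates[ne:].mean()),
            "mean_ca_e": float(self.Ca[:ne].mean()),
            "gamma_ee": block_connectivity(self.store.counts, np.arange(ne), np.arange(ne)),
            "gamma_eff_ee": effective_connectivity(
                self.store.weights,
                np.arange(ne),
                np.arange(ne),
                unit_weight=self.config.j_ee_eff,
            ),
            "mean_z_a": float(self.elements.z_a.mean()),
            "synapses": self.store.total_synapses(),
        }
        if self.subpop is not None and self.subpop.size:
            sub = self.subpop
            rest = np.setdiff1d(np.arange(ne), sub, assume_unique=False)
            A = self.store.counts
            row["rate_sub"] = float(rates[sub].mean())
            row["gamma_ss"] = block_connectivity(A, sub, sub)
            row["gamma_se"] = block_connectivity(A, sub, rest)
            row["gamma_es"] = block_connectivity(A, rest, sub)
            self._check_block_symmetry(row["gamma_se"], row["gamma_es"])
            row["gamma_eff_ss"] = effective_connectivity(
                self.store.weights, sub, sub, unit_weight=self.config.j_ee_eff
            )
        self._rows.append(row)
        self._win_counts[:] = 0

    def _check_block_symmetry(self, gamma_se: float, gamma_es: float) -> None:
        """Warn once if sub->rest and rest->sub connectivity diverge although
        the axonal and dendritic growth rules are symmetric (they are expected
        to stay statistically equal in that case)."""
        if self.clock is None or getattr(self, "_symmetry_warned", False):
            return
        if self.clock.growth_rule_a != self.clock.growth_rule_d:
            return
        if abs(gamma_se - gamma_es) > 0.02 + 0.5 * max(gamma_se, gamma_es):
            import warnings

            warnings.warn(
                f"sub->rest and rest->sub connectivities diverged "
                f"({gamma_se:.4f} vs {gamma_es:.4f}) despite symmetric growth "
                f"rules at t={self.t:.1f} s",
                RuntimeWarning,
                stacklevel=2,
            )
            self._symmetry_warned = True

    def run(self, duration: float) -> "Simulation":
        """Advance the closed loop by ``duration`` seconds (whole blocks)."""
        n_blocks = int(round(duration / self.block_interval))
        ne = self.config.n_e
        if not np.shares_memory(self.store.weights, self.W):
            raise RuntimeError(
                "synapse store decoupled from the kernel weight matrix"
            )
        for _ in range(n_blocks):
            self._update_current()
            counts = self.run_steps(self._block_steps)
            self._win_counts += counts
            if self.clock is not None:
                structural_update(
                    self.elements,
                    self.store,
                    self.Ca[:ne],
                    self.clock,
                    self._rng_struct,
                    t=self.t,
                )
            if (
                self.scaling is not None
                and self.scaling.rho > 0.0
                and self.t >= self.scaling.enabled_from
            ):
                scale_weights(
                    self.store, self.Ca[:ne], self.block_interval, self.scaling
                )
            self._blocks_done += 1
            if self._blocks_done % self._record_blocks == 0:
                self._record()
        return self


def build_network(
    config: NetworkConfig, neuron: NeuronParams | None = None, **kwargs
) -> Simulation:
    """Build an initialized network (static wiring drawn, E-E block empty)."""
    return Simulation(config, neuron=neuron, **kwargs)
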