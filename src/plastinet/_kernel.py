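"""Numba inner loop of the membrane/calcium simulation.

One call advances the whole network by a block of fixed-size time steps
between two structural-plasticity boundaries.  Semantics per step:

* refractory neurons count down, stay clamped at ``v_reset`` and discard
  all synaptic input arriving during refractoriness;
* non-refractory neurons relax exponentially (exact decay factor) toward
  their per-neuron steady state ``mu`` (rest + injected current), then
  receive the delayed recurrent jumps and the external Poisson jumps;
* threshold crossing emits a spike, resets to ``v_reset`` and starts the
  refractory clock;
* the calcium trace decays every step and gains ``beta_ca`` per spike.

The external Poisson counts are sampled by exact CDF inversion.  For speed
the unit interval is split into 2^16 buckets: a bucket entirely inside one
CDF segment maps straight to its count through a precomputed table, and the
few buckets containing a CDF boundary (~a dozen per table) fall back to a
linear walk on the full-precision CDF, so the sampled law is the exact
Poisson distribution.  Uniforms come from an inline xorshift64* generator
whose state lives in the caller; one draw is consumed per neuron per step
regardless of refractory state, so the stream alignment does not depend on
spiking history.
"""

import numpy as np
from numba import njit

__all__ = ["run_block"]

#: 2^-53, converts a 53-bit integer to a uniform in [0, 1)
_U53 = 1.1102230246251565e-16
_XS_MULT = np.uint64(2685821657736338717)  # xorshift64* output multiplier


@njit(cache=True)
def run_block(
    n_steps,
    V,
    ref,
    Ca,
    buf,
    slot,
    W,
    mu,
    decay,
    ca_decay,
    beta_ca,
    v_th,
    v_reset,
    ref_steps,
    spike_counts,
    record,
    rec_step,
    rec_id,
    step_offset,
    cdf,
    qtab,
    table_idx,
    j_ext,
    rng_state,
):
    """Advance ``n_steps`` steps; returns (new_slot, n_recorded_spikes).

    buf : (delay_steps, n) ring buffer of future synaptic jumps (mV); the
        row consumed at the current slot is re-filled by this step's spikes
        and read again ``delay_steps`` steps later.
    W : (n, n) weight matrix [pre, post] in mV (static + plastic blocks).
    cdf / qtab / table_idx : per-external-rate Poisson tables (full CDF,
        condensed 16-bit inversion table with -1 marking fallback buckets)
        and the neuron -> table map.
    rng_state : (1,) uint64 xorshift64* state, updated in place.
    """
    n = V.shape[0]
    depth = buf.shape[0]
    max_rec = rec_step.shape[0]
    n_rec = 0
    x = rng_state[0]
    spikers = np.empty(n, np.int64)
    for s in range(n_steps):
        arrive = buf[slot]
        nsp = 0
        for i in range(n):
            x ^= x >> np.uint64(12)
            x ^= x << np.uint64(25)
            x ^= x >> np.uint64(27)
            r = (x * _XS_MULT) >> np.uint64(11)
            ti = table_idx[i]
            k = np.int64(qtab[ti, r >> np.uint64(37)])
            if k < 0:
                u = np.float64(r) * _U53
                row = cdf[ti]
                k = 0
                while u > row[k]:
                    k += 1
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = v_reset
                Ca[i] *= ca_decay
            else:
                v = mu[i] + (V[i] - mu[i]) * decay
                v += arrive[i] + j_ext * k
                Ca[i] *= ca_decay
                if v >= v_th:
                    spikers[nsp] = i
                    nsp += 1
                    spike_counts[i] += 1
                    Ca[i] += beta_ca
                    v = v_reset
                    ref[i] = ref_steps
                V[i] = v
            arrive[i] = 0.0
        if nsp > 0:
            out = buf[slot]
            for q in range(nsp):
                i = spikers[q]
                wrow = W[i]
                for j in range(n):
                    out[j] += wrow[j]
                if record and n_rec < max_rec:
                    rec_step[n_rec] = step_offset + s
                    rec_id[n_rec] = i
                    n_rec += 1
        slot = (slot + 1) % depth
    rng_state[0] = x
    return slot, n_rec


def poisson_tables(lams: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full CDFs and condensed 16-bit inversion tables for the given means.

    Returns (cdf, qtab): cdf has one 64-wide padded row per mean; qtab maps
    the top 16 bits of a uniform to the Poisson count, with -1 marking the
    buckets that straddle a CDF boundary and need the exact fallback walk.
    """
    width = 64
    cdf = np.full((len(lams), width), 1.1)
    qtab = np.empty((len(lams), 1 << 16), dtype=np.int8)
    for t, lam in enumerate(lams):
        if lam < 0:
            raise ValueError("Poisson mean must be non-negative")
        p = np.exp(-lam)
        c = p
        cdf[t, 0] = c
        k_max = 0
        for k in range(1, width - 1):
            # stop once the remaining tail is below float resolution (the
            # cumulative sum can stall a few ulp short of 1.0)
            if 1.0 - c < 1e-15 or (k > lam and p < 1e-18):
                break
            p *= lam / k
            c += p
            cdf[t, k] = c
            k_max = k
        else:
            raise ValueError(f"external rate too high for the sampling table (lam={lam})")
        row = cdf[t, : k_max + 1]
        lo = np.arange(1 << 16) / float(1 << 16)
        hi = (np.arange(1, (1 << 16) + 1) / float(1 << 16)) - _U53
        klo = np.searchsorted(row, lo, side="left")
        khi = np.searchsorted(row, hi, side="left")
        qtab[t] = np.where(klo == khi, klo, -1).astype(np.int8)
    return cdf, qtab
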