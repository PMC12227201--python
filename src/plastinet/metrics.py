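"""Quantification of firing rates, connectivity, synapse numbers and recovery.

Connectivity matrices follow the analysis convention: rows are postsynaptic,
columns presynaptic, entries are synapse counts (structural) or summed
weights divided by the unit weight (effective, "equivalent unit synapses").
Block connectivity Gamma is the mean entry over a (rows, cols) block, with
the diagonal excluded whenever the two populations overlap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "firing_rates",
    "block_connectivity",
    "effective_connectivity",
    "synapse_counts",
    "deviation_area",
    "activity_synapse_heatmap",
]


def firing_rates(
    spike_ids: np.ndarray,
    n_neurons: int,
    t_start: float,
    t_stop: float,
    spike_times: np.ndarray | None = None,
    population: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of per-neuron firing rates (Hz) over [t_start, t_stop).

    ``spike_ids`` (and optional ``spike_times`` in s, for windowing) describe
    a raster; ``population`` restricts to a subset of neuron ids.  Returns
    (mean, sd, per_neuron_rates) where per_neuron_rates covers the selected
    population in id order.
    """
    window = t_stop - t_start
    if window <= 0:
        raise ValueError("t_stop must exceed t_start")
    spike_ids = np.asarray(spike_ids)
    if spike_times is not None:
        spike_times = np.asarray(spike_times)
        keep = (spike_times >= t_start) & (spike_times < t_stop)
        spike_ids = spike_ids[keep]
    counts = np.bincount(spike_ids, minlength=n_neurons)[:n_neurons]
    rates = counts / window
    if population is not None:
        rates = rates[np.asarray(population)]
    return float(rates.mean()), float(rates.std()), rates


def _block_mean(matrix: np.ndarray, rows, cols) -> float:
    """Mean block entry with diagonal (autaptic) cells fully excluded."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("populations must be non-empty")
    sub = matrix[np.ix_(rows, cols)]
    shared = np.intersect1d(rows, cols)
    total = sub.sum() - matrix[shared, shared].sum()
    n_pairs = sub.size - shared.size
    if n_pairs <= 0:
        raise ValueError("block contains no off-diagonal pairs")
    return float(total / n_pairs)


def block_connectivity(counts: np.ndarray, rows_pop, cols_pop) -> float:
    """Mean synapse count per directed pair over the (rows, cols) block.

    Diagonal (autaptic) cells are excluded from both the sum and the pair
    count when the row and column populations overlap.
    """
    return _block_mean(np.asarray(counts), rows_pop, cols_pop)


def effective_connectivity(
    weights: np.ndarray, rows_pop, cols_pop, unit_weight: float = 0.1
) -> float:
    """Block-averaged equivalent unit synapses: mean(weights) / unit_weight."""
    if unit_weight <= 0:
        raise ValueError("unit_weight must be positive")
    return _block_mean(np.asarray(weights), rows_pop, cols_pop) / unit_weight


def synapse_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(indegree, outdegree) per neuron from a [post, pre] count matrix."""
    counts = np.asarray(counts)
    return counts.sum(axis=1), counts.sum(axis=0)


def deviation_area(
    t: np.ndarray,
    trace: np.ndarray,
    target: float,
    t_from: float,
    t_to: float,
) -> float:
    """Signed trapezoidal integral of (trace - target) over [t_from, t_to].

    The trace is interpolated linearly at the interval endpoints, so the
    area is exactly additive over adjacent intervals.
    """
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if not t_from < t_to:
        raise ValueError("t_from must be below t_to")
    if t_from < t[0] or t_to > t[-1]:
        raise ValueError("integration bounds outside trace span")
    inside = (t > t_from) & (t < t_to)
    tt = np.concatenate([[t_from], t[inside], [t_to]])
    yy = np.concatenate(
        [[np.interp(t_from, t, trace)], trace[inside], [np.interp(t_to, t, trace)]]
    )
    return float(np.trapezoid(yy - target, tt))


def activity_synapse_heatmap(
    rates: np.ndarray,
    indegrees: np.ndarray,
    rate_bins=20,
    indegree_bins=20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint histogram of per-neuron firing rate vs input synapse number.

    Returns (hist, rate_edges, indegree_edges).  Under the unstabilized
    biphasic rule this is bimodal: a silent-and-isolated cluster near
    (0 Hz, 0 synapses) and an active cluster near the setpoint rate.
    """
    rates = np.asarray(rates, dtype=float)
    indegrees = np.asarray(indegrees, dtype=float)
    if rates.shape != indegrees.shape:
        raise ValueError("rates and indegrees must align per neuron")
    hist, re, ie = np.histogram2d(rates, indegrees, bins=[rate_bins, indegree_bins])
    return hist, re, ie
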