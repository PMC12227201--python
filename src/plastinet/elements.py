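"""Synaptic-element bookkeeping and E-E synapse formation/deletion/rewiring.

Each excitatory neuron carries a continuous count of axonal elements
(boutons, presynaptic ports) and dendritic elements (spines, postsynaptic
ports).  The growth rules move these counts up or down as a function of the
neuron's calcium trace; at every structural boundary the discrete synapse
population is reconciled with the element counts:

1. ``integrate_elements`` — Euler step of the element counts, clamped at 0;
2. ``delete_surplus`` — a neuron whose bound elements exceed ``floor(z)``
   breaks randomly chosen synapses of that type; the partner's element is
   freed but survives (its count ``z`` is untouched), which is what allows
   rewiring rather than pure loss;
3. ``form_synapses`` — all free axonal and free dendritic elements in the
   network are pooled, shuffled and paired at random; autapse pairs are
   rejected with one re-draw round.  Multiple synapses between an ordered
   pair (multapses) are allowed and tracked as multiplicities.

New synapses are created at the unit weight ``j_e``; weights of existing
synapses are owned by the scaling rule (see ``plastinet.scaling``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium import GrowthRule

__all__ = [
    "ElementState",
    "SynapseStore",
    "StructuralClock",
    "integrate_elements",
    "delete_surplus",
    "form_synapses",
    "structural_update",
]


@dataclass
class ElementState:
    """Per-excitatory-neuron element counts.

    z_a, z_d : continuous axonal / dendritic element counts (>= 0)
    connected_a, connected_d : integer counts currently bound in synapses
    """

    z_a: np.ndarray
    z_d: np.ndarray
    connected_a: np.ndarray
    connected_d: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ElementState":
        return cls(
            z_a=np.zeros(n),
            z_d=np.zeros(n),
            connected_a=np.zeros(n, dtype=np.int64),
            connected_d=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return self.z_a.shape[0]

    def free_axonal(self) -> np.ndarray:
        """Unbound axonal elements per neuron: floor(z_a) - connected_a, >= 0."""
        return np.maximum(np.floor(self.z_a).astype(np.int64) - self.connected_a, 0)

    def free_dendritic(self) -> np.ndarray:
        return np.maximum(np.floor(self.z_d).astype(np.int64) - self.connected_d, 0)


class SynapseStore:
    """Directed E->E synapse multiset with per-pair multiplicity and weight.

    counts[pre, post] is the number of synapses from ``pre`` to ``post``;
    weights[pre, post] the summed weight (mV) of those synapses.  ``weights``
    may be a view into the full network weight matrix so the membrane kernel
    sees structural changes immediately.
    """

    def __init__(
        self,
        n: int,
        j_e: float,
        weights: np.ndarray | None = None,
        log_events: bool = False,
    ):
        self.n = n
        self.j_e = j_e
        self.counts = np.zeros((n, n), dtype=np.int64)
        self.weights = np.zeros((n, n)) if weights is None else weights
        if self.weights.shape != (n, n):
            raise ValueError("weights shape must match (n, n)")
        self.log_events = log_events
        self.events: list[tuple[float, str, int, int]] = []
        self.total_formed = 0
        self.total_deleted = 0

    def total_synapses(self) -> int:
        return int(self.counts.sum())

    def add_one(self, pre: int, post: int, t: float = 0.0) -> None:
        if pre == post:
            raise ValueError("autapses are forbidden")
        self.counts[pre, post] += 1
        self.weights[pre, post] += self.j_e
        self.total_formed += 1
        if self.log_events:
            self.events.append((t, "form", pre, post))

    def remove_one(self, pre: int, post: int, t: float = 0.0) -> None:
        m = self.counts[pre, post]
        if m <= 0:
            raise RuntimeError(
                f"bookkeeping mismatch: no synapse {pre}->{post} to delete"
            )
        if m == 1:
            self.weights[pre, post] = 0.0
        else:
            # per-pair weights are tracked as a pooled total; removing one
            # synapse removes the average share
            self.weights[pre, post] -= self.weights[pre, post] / m
        self.counts[pre, post] = m - 1
        self.total_deleted += 1
        if self.log_events:
            self.events.append((t, "delete", pre, post))

    def validate(self, elements: ElementState) -> None:
        """Raise on any violated store/element invariant."""
        if (self.counts < 0).any():
            raise RuntimeError("negative synapse count")
        if np.diagonal(self.counts).any():
            raise RuntimeError("autapse present in store")
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        if not np.array_equal(row, elements.connected_a):
            raise RuntimeError("connected_a inconsistent with store")
        if not np.array_equal(col, elements.connected_d):
            raise RuntimeError("connected_d inconsistent with store")


@dataclass(frozen=True)
class StructuralClock:
    """Cadence and growth rules of the structural update.

    update_interval : time between structural updates (s)
    growth_rule_a / growth_rule_d : rules for axonal and dendritic elements
        (they may differ, e.g. in eta, to model asymmetric bouton/spine
        regulation)
    """

    growth_rule_a: GrowthRule
    growth_rule_d: GrowthRule
    update_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.update_interval <= 0:
            raise ValueError("update_interval must be positive")


def integrate_elements(
    elements: ElementState, C: np.ndarray, dt: float, clock: StructuralClock
) -> ElementState:
    """Euler step of the element counts from the calcium sampled at the boundary."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    np.maximum(elements.z_a + dt * clock.growth_rule_a.rate(C), 0.0, out=elements.z_a)
    np.maximum(elements.z_d + dt * clock.growth_rule_d.rate(C), 0.0, out=elements.z_d)
    return elements


def _delete_side(
    elements: ElementState,
    store: SynapseStore,
    rng: np.random.Generator,
    axonal: bool,
    t: float,
) -> int:
    """Delete surplus bound elements on one side; returns deletion count."""
    if axonal:
        surplus = elements.connected_a - np.floor(elements.z_a).astype(np.int64)
    else:
        surplus = elements.connected_d - np.floor(elements.z_d).astype(np.int64)
    deleted = 0
    for i in np.nonzero(surplus > 0)[0]:
        k = int(surplus[i])
        row = store.counts[i] if axonal else store.counts[:, i]
        partners = np.nonzero(row)[0]
        instances = np.repeat(partners, row[partners])
        picked = rng.choice(instances, size=k, replace=False)
        for j in picked:
            if axonal:
                store.remove_one(i, int(j), t)
                elements.connected_a[i] -= 1
                elements.connected_d[j] -= 1
            else:
                store.remove_one(int(j), i, t)
                elements.connected_a[j] -= 1
                elements.connected_d[i] -= 1
        deleted += k
    return deleted


def delete_surplus(
    elements: ElementState,
    store: SynapseStore,
    rng: np.random.Generator,
    t: float = 0.0,
) -> int:
    """Break synapses wherever bound elements exceed floor(z).

    Axonal surpluses are processed first (in neuron-id order), then
    dendritic surpluses are recomputed — an axonal deletion frees the
    partner's dendritic element and may already resolve its surplus.
    Deleted partners keep their element counts; the freed elements re-enter
    the free pool at the next formation step.
    """
    deleted = _delete_side(elements, store, rng, axonal=True, t=t)
    deleted += _delete_side(elements, store, rng, axonal=False, t=t)
    return deleted


def form_synapses(
    elements: ElementState,
    store: SynapseStore,
    rng: np.random.Generator,
    t: float = 0.0,
) -> int:
    """Randomly pair free axonal with free dendritic elements.

    Both free pools are shuffled uniformly and paired sequentially; autapse
    pairs are rejected, their elements re-shuffled for one more round, and
    any still-colliding elements stay free until the next cycle.
    """
    ids = np.arange(elements.n)
    pool_a = np.repeat(ids, elements.free_axonal())
    pool_d = np.repeat(ids, elements.free_dendritic())
    formed = 0
    for _round in range(2):
        m = min(pool_a.shape[0], pool_d.shape[0])
        if m == 0:
            break
        pool_a = rng.permutation(pool_a)
        pool_d = rng.permutation(pool_d)
        pre, post = pool_a[:m], pool_d[:m]
        ok = pre != post
        for i, j in zip(pre[ok], post[ok]):
            store.add_one(int(i), int(j), t)
        np.add.at(elements.connected_a, pre[ok], 1)
        np.add.at(elements.connected_d, post[ok], 1)
        formed += int(ok.sum())
        # rejected autapse elements get one re-draw; surplus pool elements
        # beyond m stay in play for the re-draw as well
        pool_a = np.concatenate([pre[~ok], pool_a[m:]])
        pool_d = np.concatenate([post[~ok], pool_d[m:]])
        if not (~ok).any():
            break
    return formed


def structural_update(
    elements: ElementState,
    store: SynapseStore,
    C: np.ndarray,
    clock: StructuralClock,
    rng: np.random.Generator,
    t: float = 0.0,
) -> dict:
    """One full structural cycle: integrate -> delete surplus -> form synapses."""
    integrate_elements(elements, C, clock.update_interval, clock)
    deleted = delete_surplus(elements, store, rng, t)
    formed = form_synapses(elements, store, rng, t)
    return {"t": t, "formed": formed, "deleted": deleted}
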