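"""Structural engine: element integration, deletion, formation, rewiring.

Includes a naive brute-force reference implementation (explicit loops over
neurons and element instances, same RNG stream) checked state-for-state
against the engine over many cycles.
"""

import math

import numpy as np
import pytest
import scipy.stats

from plastinet.calcium import GrowthRule, biphasic_gaussian_rule
from plastinet.elements import (
    ElementState,
    StructuralClock,
    SynapseStore,
    delete_surplus,
    form_synapses,
    integrate_elements,
    structural_update,
)

BI = biphasic_gaussian_rule()


def make_state(n, z_a=None, z_d=None):
    el = ElementState.zeros(n)
    if z_a is not None:
        el.z_a[:] = z_a
    if z_d is not None:
        el.z_d[:] = z_d
    return el


def clock(rule_a=BI, rule_d=None, interval=0.1):
    return StructuralClock(rule_a, rule_d or rule_a, interval)


class TestIntegrateElements:
    def test_no_change_at_setpoint(self):
        el = make_state(3, z_a=5.0, z_d=5.0)
        C = np.full(3, BI.epsilon)
        for _ in range(1000):
            integrate_elements(el, C, 0.1, clock())
        assert el.z_a == pytest.approx(5.0, abs=1e-12)

    def test_peak_growth_accumulates_nu_t(self):
        el = make_state(2)
        C = np.full(2, BI.xi)
        for _ in range(1000):  # 100 s at 0.1 s steps
            integrate_elements(el, C, 0.1, clock())
        assert el.z_a == pytest.approx(BI.nu * 100.0, rel=1e-9)

    def test_retraction_clamps_at_zero(self):
        el = make_state(2, z_a=0.01, z_d=0.01)
        C = np.full(2, 10 * BI.epsilon)  # strong retraction
        for _ in range(200):
            integrate_elements(el, C, 1.0, clock())
        assert (el.z_a == 0.0).all() and (el.z_d == 0.0).all()


def wire(el, store, pairs):
    for pre, post in pairs:
        store.add_one(pre, post)
        el.connected_a[pre] += 1
        el.connected_d[post] += 1


class TestDeleteSurplus:
    def test_floor_rule_deletes_exact_surplus(self):
        el = make_state(3, z_a=[2.7, 3.0, 3.0], z_d=[4.0, 3.0, 2.0])
        store = SynapseStore(3, j_e=0.1)
        wire(el, store, [(0, 1), (0, 2), (0, 1), (1, 0), (1, 2), (1, 0), (2, 0), (2, 1), (2, 0)])
        deleted = delete_surplus(el, store, np.random.default_rng(0))
        assert deleted == 1  # 3 - floor(2.7) on neuron 0's axonal side
        assert el.connected_a[0] == 2
        store.validate(el)

    def test_no_deletion_at_integer_boundary(self):
        el = make_state(2, z_a=[1.0, 1.0], z_d=[1.0, 1.0])
        store = SynapseStore(2, j_e=0.1)
        wire(el, store, [(0, 1), (1, 0)])
        assert delete_surplus(el, store, np.random.default_rng(0)) == 0

    def test_deletion_frees_partner_element(self):
        # pre-side deletion leaves the partner's z untouched, so the
        # partner gains one free dendritic element
        el = make_state(3, z_a=[0.0, 1.0, 1.0], z_d=[2.0, 1.0, 0.0])
        store = SynapseStore(3, j_e=0.1)
        wire(el, store, [(1, 0), (2, 0)])
        el.z_a[1] = 0.0  # neuron 1 retracts its axonal element
        free_d_before = el.free_dendritic()[0]
        deleted = delete_surplus(el, store, np.random.default_rng(1))
        assert deleted == 1
        assert el.free_dendritic()[0] == free_d_before + 1
        assert el.z_d[0] == 2.0
        store.validate(el)


class TestFormSynapses:
    def test_pairs_limited_by_smaller_pool(self):
        el = make_state(4, z_a=[3.0, 0, 0, 0], z_d=[0, 1.0, 1.0, 0])
        store = SynapseStore(4, j_e=0.1)
        formed = form_synapses(el, store, np.random.default_rng(0))
        assert formed == 2
        assert store.total_synapses() == 2
        store.validate(el)

    def test_empty_pools_leave_store_unchanged(self):
        el = make_state(3)
        store = SynapseStore(3, j_e=0.1)
        assert form_synapses(el, store, np.random.default_rng(0)) == 0
        assert store.total_synapses() == 0

    def test_autapse_only_pairing_is_rejected(self):
        el = make_state(2, z_a=[1.0, 0.0], z_d=[1.0, 0.0])
        store = SynapseStore(2, j_e=0.1)
        assert form_synapses(el, store, np.random.default_rng(0)) == 0
        assert el.free_axonal()[0] == 1  # element stays free

    def test_new_weights_equal_unit_weight(self):
        el = make_state(5, z_a=2.0, z_d=2.0)
        store = SynapseStore(5, j_e=0.8)
        form_synapses(el, store, np.random.default_rng(2))
        assert np.array_equal(store.weights, 0.8 * store.counts)

    def test_partner_choice_uniform_chi_square(self):
        # neuron 0 offers one axonal element; 1..3 offer one dendritic each
        hits = np.zeros(4)
        rng = np.random.default_rng(42)
        for _ in range(10000):
            el = make_state(4, z_a=[1.0, 0, 0, 0], z_d=[0, 1.0, 1.0, 1.0])
            store = SynapseStore(4, j_e=0.1)
            form_synapses(el, store, rng)
            hits += store.counts[0]
        assert hits[0] == 0
        chi2, p = scipy.stats.chisquare(hits[1:])
        assert p > 1e-3


class TestStructuralUpdate:
    def test_noop_cycle_at_setpoint(self):
        el = make_state(3, z_a=1.0, z_d=1.0)
        store = SynapseStore(3, j_e=0.1)
        wire(el, store, [(0, 1), (1, 2), (2, 0)])
        before = store.counts.copy()
        out = structural_update(
            el, store, np.full(3, BI.epsilon), clock(), np.random.default_rng(0)
        )
        assert out["formed"] == 0 and out["deleted"] == 0
        assert np.array_equal(store.counts, before)

    def test_silenced_neuron_disconnects_monotonically(self):
        # biphasic rule: a silent neuron's elements retract and its synapses
        # disappear over cycles, never to return while it stays silent
        rng = np.random.default_rng(3)
        n = 6
        el = make_state(n, z_a=3.0, z_d=3.0)
        store = SynapseStore(n, j_e=0.1)
        # fully connected ring: everyone starts with 3 in / 3 out, no free ports
        for i in range(n):
            for shift in (1, 2, 3):
                store.add_one(i, (i + shift) % n)
                el.connected_a[i] += 1
                el.connected_d[(i + shift) % n] += 1
        fast = GrowthRule("gaussian", 5.0, BI.epsilon, BI.eta)
        ck = clock(fast, fast)
        C = np.full(n, BI.epsilon)
        C[0] = 0.0  # silenced
        degrees = []
        for _ in range(40):
            structural_update(el, store, C, ck, rng)
            degrees.append(int(store.counts[0].sum() + store.counts[:, 0].sum()))
            store.validate(el)
        assert degrees[-1] == 0
        assert all(a >= b for a, b in zip(degrees, degrees[1:]))

    def test_conservation_and_floor_invariants_under_random_drive(self):
        rng = np.random.default_rng(7)
        drive = np.random.default_rng(8)
        n = 12
        el = make_state(n)
        store = SynapseStore(n, j_e=0.1)
        fast = GrowthRule("gaussian", 1.0, BI.epsilon, BI.eta)
        ck = clock(fast, fast)
        for _ in range(150):
            C = drive.uniform(0.0, 2 * BI.epsilon, size=n)
            structural_update(el, store, C, ck, rng)
            store.validate(el)  # sum(connected_a) == sum(connected_d) == multiplicity
            assert (np.floor(el.z_a).astype(int) >= el.connected_a).all()
            assert (np.floor(el.z_d).astype(int) >= el.connected_d).all()
            assert (store.counts.sum(axis=1) == el.connected_a).all()

    def test_event_log_deterministic_across_seeds(self):
        def run():
            rng = np.random.default_rng(5)
            el = make_state(5, z_a=2.0, z_d=2.0)
            store = SynapseStore(5, j_e=0.1, log_events=True)
            fast = GrowthRule("gaussian", 1.0, BI.epsilon, BI.eta)
            drive = np.random.default_rng(6)
            for k in range(50):
                C = drive.uniform(0.0, 2 * BI.epsilon, size=5)
                structural_update(el, store, C, clock(fast, fast), rng, t=0.1 * k)
            return store.events

        assert run() == run()


# -- brute-force reference engine -------------------------------------------

def naive_cycle(el, counts, weights, j_e, C, rule_a, rule_d, dt, rng):
    """Naive loop-based structural cycle consuming the same RNG stream."""
    n = len(C)
    for i in range(n):
        el.z_a[i] = max(0.0, el.z_a[i] + dt * rule_a.rate(C[i]))
        el.z_d[i] = max(0.0, el.z_d[i] + dt * rule_d.rate(C[i]))

    def remove(pre, post):
        m = counts[pre][post]
        weights[pre][post] = 0.0 if m == 1 else weights[pre][post] * (m - 1) / m
        counts[pre][post] = m - 1
        el.connected_a[pre] -= 1
        el.connected_d[post] -= 1

    for axonal in (True, False):
        surplus = [
            (el.connected_a[i] if axonal else el.connected_d[i])
            - math.floor(el.z_a[i] if axonal else el.z_d[i])
            for i in range(n)
        ]
        for i in range(n):
            if surplus[i] <= 0:
                continue
            instances = []
            for j in range(n):
                m = counts[i][j] if axonal else counts[j][i]
                instances.extend([j] * m)
            picked = rng.choice(np.array(instances, dtype=np.int64),
                                size=int(surplus[i]), replace=False)
            for j in picked:
                remove(i, int(j)) if axonal else remove(int(j), i)

    pool_a, pool_d = [], []
    for i in range(n):
        pool_a.extend([i] * (math.floor(el.z_a[i]) - el.connected_a[i]))
        pool_d.extend([i] * (math.floor(el.z_d[i]) - el.connected_d[i]))
    pool_a = np.array(pool_a, dtype=np.int64)
    pool_d = np.array(pool_d, dtype=np.int64)
    for _round in range(2):
        m = min(len(pool_a), len(pool_d))
        if m == 0:
            break
        pool_a = rng.permutation(pool_a)
        pool_d = rng.permutation(pool_d)
        rej_a, rej_d = [], []
        for q in range(m):
            pre, post = int(pool_a[q]), int(pool_d[q])
            if pre == post:
                rej_a.append(pre)
                rej_d.append(post)
            else:
                counts[pre][post] += 1
                weights[pre][post] += j_e
                el.connected_a[pre] += 1
                el.connected_d[post] += 1
        pool_a = np.array(rej_a + list(pool_a[m:]), dtype=np.int64)
        pool_d = np.array(rej_d + list(pool_d[m:]), dtype=np.int64)
        if not rej_a:
            break


def test_engine_matches_brute_force_reference_over_100_cycles():
    n = 3
    rule = GrowthRule("gaussian", 2.0, BI.epsilon, BI.eta)
    ck = clock(rule, rule)
    rng_engine = np.random.default_rng(123)
    rng_naive = np.random.default_rng(123)
    drive = np.random.default_rng(99)

    el_e = ElementState.zeros(n)
    store = SynapseStore(n, j_e=0.1)
    el_n = ElementState.zeros(n)
    counts_n = [[0] * n for _ in range(n)]
    weights_n = [[0.0] * n for _ in range(n)]

    for cycle in range(100):
        C = drive.uniform(0.0, 2.0 * BI.epsilon, size=n)
        structural_update(el_e, store, C, ck, rng_engine)
        naive_cycle(el_n, counts_n, weights_n, 0.1, C, rule, rule, ck.update_interval,
                    rng_naive)
        assert np.array_equal(store.counts, np.array(counts_n)), f"cycle {cycle}"
        assert store.weights == pytest.approx(np.array(weights_n), abs=1e-12)
        assert el_e.z_a == pytest.approx(el_n.z_a, abs=1e-12)
        assert el_e.z_d == pytest.approx(el_n.z_d, abs=1e-12)
        assert np.array_equal(el_e.connected_a, el_n.connected_a)
        assert np.array_equal(el_e.connected_d, el_n.connected_d)
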