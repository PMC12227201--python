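"""Shared fixtures: desk-scale grown networks and miniature test networks.

The two grown networks (linear rule; biphasic rule with facilitating
current) are expensive, so they are built once per session and perturbation
tests branch off deep copies.
"""

import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plastinet.network import CurrentSchedule, NetworkConfig
from plastinet.protocols import (
    DESK_T_DECAY,
    DESK_T_GROW_BIPHASIC,
    DESK_T_GROW_LINEAR,
    FACILITATING_I0,
    choose_subpop,
    desk_clock,
    desk_config,
    grow_network,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

LINEAR_SEED = 11
BIPHASIC_SEED = 12


def micro_config(seed: int = 0, **overrides) -> NetworkConfig:
    """A 60 E + 15 I network for fast plumbing tests.

    The inhibitory weight is scaled so the 15 I neurons deliver the same
    total inhibition as 250 at -0.8 mV, keeping the miniature network
    inhibition-dominated (rates below the calcium setpoint rate, so growth
    rules actually grow).
    """
    kw = dict(
        n_e=60, n_i=15, p_static=1.0, j_e=0.1, j_i=-13.0, j_ee=0.8, seed=seed
    )
    kw.update(overrides)
    return NetworkConfig(**kw)


@pytest.fixture(scope="session")
def grown_linear():
    """Desk network grown to equilibrium under the linear rule."""
    sub = choose_subpop(1000, LINEAR_SEED)
    return grow_network(
        desk_clock("linear"),
        t_grow=DESK_T_GROW_LINEAR,
        config=desk_config(LINEAR_SEED),
        subpop=sub,
    )


@pytest.fixture(scope="session")
def grown_biphasic():
    """Desk network grown under the biphasic rule with the facilitating current."""
    sub = choose_subpop(1000, BIPHASIC_SEED)
    return grow_network(
        desk_clock("biphasic"),
        current=CurrentSchedule(FACILITATING_I0, DESK_T_DECAY),
        t_grow=DESK_T_GROW_BIPHASIC,
        config=desk_config(BIPHASIC_SEED),
        subpop=sub,
    )


@pytest.fixture
def branch():
    """Deep-copy helper so perturbation tests can reuse a grown network."""

    def _branch(sim):
        clone = copy.deepcopy(sim)
        clone.current = None
        return clone

    return _branch
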