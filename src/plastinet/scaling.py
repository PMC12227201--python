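"""Homeostatic synaptic scaling of E-E weights.

Every E->E synapse onto postsynaptic neuron ``j`` follows

    dw/dt = rho * w * (epsilon - C_j),

a multiplicative, cell-autonomous update: all inputs of a neuron scale by
the same factor, so weight ratios within a neuron's input set are
preserved.  A neuron whose calcium sits below the setpoint (deprived) scales
its inputs up; one above the setpoint scales them down.  The rule is
sometimes written with the drive term reversed, ``(C - epsilon)``; the
homeostatic behavior it is meant to produce (upscaling under deprivation,
downscaling under over-excitation) requires ``(epsilon - C)``, which is the
default here, with ``sign="calcium_minus_setpoint"`` selecting the reversed convention.

Scaling acts on the plastic E-E block only; static inhibitory wiring and
the external drive weight are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import SynapseStore

__all__ = ["ScalingParams", "scale_weights", "effective_weight_matrix"]


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the scaling rule.

    rho : scaling factor (s^-1 per concentration unit); 0 disables scaling
    epsilon : target calcium (same setpoint as the growth rules)
    w_min : weight floor per synapse (mV)
    enabled_from : simulation time (s) at which scaling switches on
    sign : "setpoint_minus_calcium" (default) or "calcium_minus_setpoint"
    """

    rho: float = 0.0
    epsilon: float = 0.0079
    w_min: float = 0.0
    enabled_from: float = 0.0
    sign: str = "setpoint_minus_calcium"

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be non-negative, got {self.rho}")
        if self.w_min < 0:
            raise ValueError(f"w_min must be non-negative, got {self.w_min}")
        if self.sign not in ("setpoint_minus_calcium", "calcium_minus_setpoint"):
            raise ValueError(f"unknown sign convention {self.sign!r}")


def scale_weights(
    store: SynapseStore,
    C_post: np.ndarray,
    dt: float,
    params: ScalingParams,
) -> None:
    """Apply one discrete scaling step of length ``dt`` seconds in place.

    w <- w * (1 + rho * dt * (epsilon - C_post)), clamped at ``w_min`` per
    synapse.  The multiplicative factor is floored at zero so a single large
    step cannot flip weight signs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.rho == 0.0:
        return
    drive = params.epsilon - np.asarray(C_post)
    if params.sign == "calcium_minus_setpoint":
        drive = -drive
    factor = np.maximum(1.0 + params.rho * dt * drive, 0.0)
    store.weights *= factor[np.newaxis, :]
    floor = params.w_min * store.counts
    np.maximum(store.weights, floor, out=store.weights)


def effective_weight_matrix(store: SynapseStore) -> np.ndarray:
    """Summed-weight matrix in the analysis convention [postsynaptic, presynaptic]."""
    return store.weights.T.copy()
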