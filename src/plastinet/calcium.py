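"""Calcium traces and structural-plasticity growth curves.

Each neuron carries a calcium-like trace ``C(t)`` that low-pass filters its
own spike train,

    dC/dt = -C / tau_Ca + beta_Ca * S(t),

where ``S(t)`` is the spike train of the neuron.  In steady state the
time-averaged trace equals ``rate * beta_Ca * tau_Ca``, so with the default
``tau_Ca = 10 s`` and ``beta_Ca = 1e-4`` a calcium setpoint of 0.0079 maps to
a firing-rate setpoint of 7.9 Hz (and 0.0007 to 0.7 Hz).

The trace drives the growth and retraction of synaptic elements (axonal
boutons and dendritic spines).  Two growth-curve families are implemented:

``linear``
    dz/dt = nu * (1 - C / epsilon) — homeostatic outgrowth below the
    setpoint, retraction above it.

``gaussian``
    dz/dt = nu * (2 * exp(-((C - xi) / zeta)^2) - 1) with xi = (eta +
    epsilon) / 2 and zeta = (epsilon - eta) / (2 * sqrt(ln 2)), so the curve
    crosses zero exactly at ``eta`` and ``epsilon``, peaks at ``+nu`` midway
    between them, and saturates at ``-nu`` for large calcium.  ``eta = 0``
    gives the "zero-Gaussian" rule (silent neurons freeze); ``eta > 0`` the
    biphasic rule (silent neurons retract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalciumParams",
    "GrowthRule",
    "update_calcium",
    "linear_growth_rate",
    "gaussian_growth_rate",
    "growth_zone",
    "linear_rule",
    "zero_gaussian_rule",
    "biphasic_gaussian_rule",
]

#: steady-state conversion between firing rate (Hz) and mean calcium is
#: rate * beta_Ca * tau_Ca; with defaults the factor is 0.001 per Hz.
DEFAULT_TAU_CA = 10.0  # s
DEFAULT_BETA_CA = 1e-4


@dataclass(frozen=True)
class CalciumParams:
    """Parameters of the per-neuron calcium trace.

    tau_ca : decay time constant (s)
    beta_ca : per-spike calcium influx (concentration units)
    """

    tau_ca: float = DEFAULT_TAU_CA
    beta_ca: float = DEFAULT_BETA_CA

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ValueError(f"tau_ca must be positive, got {self.tau_ca}")
        if self.beta_ca <= 0:
            raise ValueError(f"beta_ca must be positive, got {self.beta_ca}")


def update_calcium(C, spikes_in_step, dt: float, params: CalciumParams):
    """Advance the calcium trace by one step of length ``dt`` seconds.

    Exact exponential decay over the step, then ``spikes_in_step * beta_ca``
    influx.  Works elementwise on arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt / params.tau_ca)
    return np.asarray(C) * decay + np.asarray(spikes_in_step) * params.beta_ca


@dataclass(frozen=True)
class GrowthRule:
    """A growth curve mapping calcium concentration to dz/dt.

    variant : "linear" or "gaussian"
    nu : growth rate (elements / s); peak magnitude of the curve
    epsilon : target (stable) calcium setpoint
    eta : lower setpoint of the gaussian variant; 0 gives the zero-Gaussian
        rule, >0 the biphasic rule.  Ignored by the linear variant.
    """

    variant: str
    nu: float
    epsilon: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in ("linear", "gaussian"):
            raise ValueError(f"unknown growth-rule variant {self.variant!r}")
        if self.nu <= 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.variant == "gaussian" and not 0.0 <= self.eta < self.epsilon:
            raise ValueError(
                f"gaussian rule requires 0 <= eta < epsilon, got eta={self.eta}, "
                f"epsilon={self.epsilon}"
            )

    @property
    def xi(self) -> float:
        """Midpoint of the two setpoints; location of the gaussian peak."""
        return 0.5 * (self.eta + self.epsilon)

    @property
    def zeta(self) -> float:
        """Width chosen so the gaussian curve has zeros exactly at eta and epsilon."""
        return (self.epsilon - self.eta) / (2.0 * math.sqrt(math.log(2.0)))

    def rate(self, C):
        """dz/dt (elements/s) at calcium concentration ``C`` (elementwise)."""
        C = np.asarray(C, dtype=float)
        if self.variant == "linear":
            out = self.nu * (1.0 - C / self.epsilon)
        else:
            out = self.nu * (2.0 * np.exp(-(((C - self.xi) / self.zeta) ** 2)) - 1.0)
        return out if out.ndim else float(out)

    def scaled(self, percent: float) -> "GrowthRule":
        """Return a copy with ``nu`` multiplied by ``percent/100`` (growth-rate presets)."""
        if percent <= 0:
            raise ValueError("percent must be positive")
        return GrowthRule(self.variant, self.nu * percent / 100.0, self.epsilon, self.eta)


def linear_growth_rate(C, rule: GrowthRule):
    """dz/dt of the linear rule; errors if ``rule`` is not linear."""
    if rule.variant != "linear":
        raise ValueError("linear_growth_rate requires a linear rule")
    return rule.rate(C)


def gaussian_growth_rate(C, rule: GrowthRule):
    """dz/dt of the gaussian rule; errors if ``rule`` is not gaussian."""
    if rule.variant != "gaussian":
        raise ValueError("gaussian_growth_rate requires a gaussian rule")
    return rule.rate(C)


def growth_zone(C, rule: GrowthRule, tol: float = 0.0):
    """Classify the growth-curve sign at ``C``: 'grow', 'retract' or 'stationary'.

    ``tol`` is a dead-band half-width on dz/dt around zero (default exact sign).
    Scalar in, scalar out; array in, array of strings out.
    """
    r = np.asarray(rule.rate(C))
    out = np.select([r > tol, r < -tol], ["grow", "retract"], default="stationary")
    return str(out) if out.ndim == 0 else out


# Parameter-table presets ---------------------------------------------------

def linear_rule(percent: float = 100.0) -> GrowthRule:
    """Linear rule with the reference parameters (nu=0.00395/s, epsilon=0.0079)."""
    return GrowthRule("linear", 0.00395, 0.0079).scaled(percent)


def zero_gaussian_rule(percent: float = 100.0) -> GrowthRule:
    """Gaussian rule with eta=0 (nu=0.004/s, epsilon=0.0079)."""
    return GrowthRule("gaussian", 0.004, 0.0079, 0.0).scaled(percent)


def biphasic_gaussian_rule(percent: float = 100.0) -> GrowthRule:
    """Gaussian rule with eta=0.0007 (nu=0.004/s, epsilon=0.0079)."""
    return GrowthRule("gaussian", 0.004, 0.0079, 0.0007).scaled(percent)
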