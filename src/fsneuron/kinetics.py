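"""Voltage-dependent gating kinetics and single-channel currents.

Every voltage-gated conductance in the model shares one first-order
formalism: a gating variable ``x`` (activation ``m`` or inactivation ``h``)
relaxes toward a sigmoidal steady state

    x_inf(V) = 1/2 + 1/2 * tanh((V - V_half) / V_slope)

with a bell-shaped voltage-dependent time constant

    tau_x(V) = (tau_max - tau_min) * (1 - tanh((V - V_tau_half)/V_tau_slope)**2)
               + tau_min

and the current carried by a channel with total conductance ``g`` is

    I = g * m**p * h * (E - V)

Units are fixed repo-wide: mV, ms, nS, pA (so nS * mV = pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GateKinetics",
    "ChannelSpec",
    "GateState",
    "steady_state",
    "time_constant",
    "gate_derivative",
    "channel_current",
]


@dataclass(frozen=True)
class GateKinetics:
    """Parameters of one gating variable (activation or inactivation).

    ``v_half``/``v_slope`` set the steady-state sigmoid; a negative
    ``v_slope`` yields a gate that closes with depolarization (used for
    inactivation and for inwardly rectifying currents).  ``tau_max`` is
    reached at ``v_tau_half``; the time constant falls to ``tau_min`` far
    from it.
    """

    v_half: float          # mV, sigmoid midpoint
    v_slope: float         # mV, sigmoid slope factor (sign = direction)
    tau_max: float         # ms
    tau_min: float         # ms
    v_tau_half: float      # mV, voltage of the tau maximum
    v_tau_slope: float     # mV

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError(f"tau_min must be > 0, got {self.tau_min}")
        if self.tau_max < self.tau_min:
            raise ValueError(
                f"tau_max ({self.tau_max}) must be >= tau_min ({self.tau_min})"
            )
        if self.v_slope == 0:
            raise ValueError("v_slope must be nonzero")
        if self.v_tau_slope == 0:
            raise ValueError("v_tau_slope must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v_half, self.v_slope, self.tau_max, self.tau_min,
             self.v_tau_half, self.v_tau_slope],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class ChannelSpec:
    """One conductance type: gating kinetics, exponent, reversal potential.

    ``p`` is the activation exponent (0 for the ungated leak).  Inactivation
    is either first-order (``inactivation`` set) or absent (``None``, the
    ``h`` variable is pinned at 1).
    """

    name: str
    p: int
    e_rev: float                              # mV
    activation: Optional[GateKinetics] = None
    inactivation: Optional[GateKinetics] = None

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError(f"activation exponent p must be >= 0, got {self.p}")
        if self.p > 0 and self.activation is None:
            raise ValueError(f"channel {self.name!r}: p > 0 requires activation kinetics")
        if self.p == 0 and self.inactivation is not None:
            raise ValueError(f"channel {self.name!r}: leak (p=0) cannot inactivate")


@dataclass
class GateState:
    """Instantaneous gating state; both variables live in [0, 1]."""

    m: float = 1.0
    h: float = 1.0  # pinned at 1 when inactivation is absent

    def __post_init__(self) -> None:
        for name, val in (("m", self.m), ("h", self.h)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"gate variable {name}={val} outside [0, 1]")


def steady_state(v, k: GateKinetics):
    """Sigmoidal steady-state open fraction x_inf(V); strictly in (0, 1)."""
    return 0.5 + 0.5 * np.tanh((np.asarray(v, dtype=float) - k.v_half) / k.v_slope)


def time_constant(v, k: GateKinetics):
    """Bell-shaped gating time constant; tau_max at v_tau_half, tau_min at ±inf."""
    t = np.tanh((np.asarray(v, dtype=float) - k.v_tau_half) / k.v_tau_slope)
    return (k.tau_max - k.tau_min) * (1.0 - t * t) + k.tau_min


def gate_derivative(x, v, k: GateKinetics):
    """dx/dt = (x_inf(V) - x) / tau_x(V), in 1/ms."""
    return (steady_state(v, k) - np.asarray(x, dtype=float)) / time_constant(v, k)


def channel_current(v, g_total: float, state: GateState, spec: ChannelSpec):
    """Ohmic channel current g * m^p * h * (E - V) in pA (g in nS, V in mV)."""
    if g_total < 0:
        raise ValueError(f"g_total must be >= 0, got {g_total}")
    return g_total * state.m ** spec.p * state.h * (spec.e_rev - np.asarray(v, dtype=float))
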