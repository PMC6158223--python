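"""Single-cell and synapse equations of motion.

Four model families cover the levels of biophysical detail the framework
supports:

* leaky integrate-and-fire (LIF) point neurons with threshold-and-reset
  spiking, optionally carrying a low-pass "activity" variable that tracks
  firing rate;
* single-compartment conductance-based cells in the Hodgkin-Huxley
  formalism — Boltzmann steady-state gates with voltage-independent time
  constants — plus a linear intracellular calcium pool fed by the calcium
  currents;
* chemical synapses, either spike-triggered (single-exponential conductance
  kicked by presynaptic spikes) or graded/analogue in the style of the
  stomatogastric pyloric-network models, where transmission is a sigmoidal
  function of presynaptic voltage with first-order kinetics — the better
  approximation for *C. elegans*, whose neurons mostly signal without
  classical action potentials;
* ohmic gap junctions.

Units are fixed throughout the package: mV, ms, nS, pA, pF, uM.  These are
self-consistent (nS x mV = pA, pA / pF = mV / ms), so no conversion factors
appear in any equation.

All functions here are scalar/array pure functions of the current state; the
:mod:`nemasim.simulator` module composes them into a synchronous
forward-Euler network update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams", "ActivityParams", "GateSpec", "ChannelSpec",
    "ConductanceCellParams", "GradedSynapseParams", "SpikeSynapseParams",
    "GapJunctionParams",
    "lif_step", "gate_inf_tau", "conductance_cell_derivatives",
    "graded_synapse_step", "synapse_current", "gap_junction_current",
    "activity_step",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire membrane: C_m dV/dt = -g_leak (V - E_leak) + I."""

    C_m: float = 3.0          # pF
    g_leak: float = 0.1       # nS
    E_leak: float = -60.0     # mV
    V_thresh: float = -40.0   # mV
    V_reset: float = -65.0    # mV
    t_refract: float = 2.0    # ms

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")
        if self.V_reset > self.V_thresh:
            raise ValueError("V_reset must not exceed V_thresh")


@dataclass(frozen=True)
class ActivityParams:
    """Low-pass firing-rate proxy: decays with tau_activity, bumps per spike."""

    tau_activity: float = 250.0     # ms
    increment_per_spike: float = 1.0

    def __post_init__(self):
        if self.tau_activity <= 0:
            raise ValueError("tau_activity must be > 0")


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gate: Boltzmann steady state, constant time constant.

    x_inf(V) = 1 / (1 + exp((V_half - V) / slope_k)); positive ``slope_k``
    gives activation (x_inf rises with V), negative gives inactivation.
    """

    V_half: float       # mV
    slope_k: float      # mV, signed
    tau: float          # ms
    exponent: int = 1

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("gate tau must be > 0")
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")
        if self.slope_k == 0:
            raise ValueError("slope_k must be nonzero")


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage-gated channel: I = gbar * act^exponent * inact * (V - E_rev)."""

    gbar: float                       # nS
    E_rev: float                      # mV
    activation: GateSpec
    inactivation: GateSpec | None = None
    is_calcium_carrier: bool = False

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")


@dataclass(frozen=True)
class ConductanceCellParams:
    """Single-compartment conductance-based cell with a linear calcium pool.

    The calcium pool integrates the summed current of calcium-carrying
    channels (inward current raises [Ca2+]) and decays with ``ca_tau``:
    d[Ca]/dt = -ca_rho * I_Ca - [Ca]/ca_tau.
    """

    C_m: float = 3.0                  # pF
    g_leak: float = 0.1               # nS
    E_leak: float = -60.0             # mV
    channels: tuple[ChannelSpec, ...] = ()
    ca_rho: float = 0.0               # uM / pA / ms
    ca_tau: float = 200.0             # ms
    spike_detect_threshold: float = 0.0  # mV

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.ca_tau <= 0:
            raise ValueError("ca_tau must be > 0")
        if self.ca_rho < 0:
            raise ValueError("ca_rho must be >= 0")
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class GradedSynapseParams:
    """Analogue synapse: s_inf is a sigmoid of presynaptic voltage,
    ds/dt = (s_inf - s) / tau_s, postsynaptic current = w s (E_syn - V_post)."""

    g_base: float = 1.0       # nS (scaled by the per-connection weight)
    E_syn: float = 0.0        # mV
    V_th_pre: float = -35.0   # mV
    delta: float = 4.0        # mV, signed slope
    tau_s: float = 50.0       # ms

    def __post_init__(self):
        if self.delta == 0:
            raise ValueError("delta must be nonzero")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.g_base < 0:
            raise ValueError("g_base must be >= 0")


@dataclass(frozen=True)
class SpikeSynapseParams:
    """Spike-triggered synapse: conductance jumps by the connection weight on
    each presynaptic spike and decays exponentially with tau_decay."""

    g_base: float = 1.0       # nS
    E_syn: float = 0.0        # mV
    tau_decay: float = 10.0   # ms

    def __post_init__(self):
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")


@dataclass(frozen=True)
class GapJunctionParams:
    """Ohmic electrical coupling; g_gap scales the per-connection weight."""

    g_gap: float = 1.0        # nS

    def __post_init__(self):
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")


# ---------------------------------------------------------------------------
# Update rules
# ---------------------------------------------------------------------------

def lif_step(V, I_total, p: LIFParams, dt, refract_until=-np.inf, t=0.0):
    """One forward-Euler LIF step.

    Returns ``(V', spiked, refract_until')``.  During the refractory window
    the membrane is clamped at ``V_reset`` and cannot spike.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t < refract_until:
        return p.V_reset, False, refract_until
    V_new = V + dt * (-p.g_leak * (V - p.E_leak) + I_total) / p.C_m
    if V_new >= p.V_thresh:
        return p.V_reset, True, t + p.t_refract
    return V_new, False, refract_until


def gate_inf_tau(V, g: GateSpec):
    """Steady state and time constant of a gate at voltage ``V`` (mV)."""
    x_inf = 1.0 / (1.0 + np.exp((g.V_half - V) / g.slope_k))
    return x_inf, g.tau


def conductance_cell_derivatives(state: dict, p: ConductanceCellParams, I_total=0.0):
    """Time derivatives of a conductance-based cell's state.

    ``state`` maps ``"V"`` -> mV, ``"Ca"`` -> uM, and ``("act", i)`` /
    ``("inact", i)`` -> gate values of channel ``i``.  Returns a dict with
    the same keys.  Gate values outside [0, 1] (beyond 1e-9) are a state
    error: they indicate a broken integrator, not a physical regime.
    """
    V = state["V"]
    Ca = state.get("Ca", 0.0)
    if Ca < 0:
        raise ValueError("Ca must be >= 0")
    deriv: dict = {}
    I_channels = 0.0
    I_ca = 0.0
    for i, ch in enumerate(p.channels):
        a = state[("act", i)]
        if not -1e-9 <= a <= 1 + 1e-9:
            raise ValueError(f"activation gate of channel {i} outside [0,1]: {a}")
        a_inf, a_tau = gate_inf_tau(V, ch.activation)
        deriv[("act", i)] = (a_inf - a) / a_tau
        open_frac = a ** ch.activation.exponent
        if ch.inactivation is not None:
            h = state[("inact", i)]
            if not -1e-9 <= h <= 1 + 1e-9:
                raise ValueError(f"inactivation gate of channel {i} outside [0,1]: {h}")
            h_inf, h_tau = gate_inf_tau(V, ch.inactivation)
            deriv[("inact", i)] = (h_inf - h) / h_tau
            open_frac = open_frac * h
        I_ch = ch.gbar * open_frac * (V - ch.E_rev)  # outward positive
        I_channels += I_ch
        if ch.is_calcium_carrier:
            I_ca += I_ch
    deriv["V"] = (-p.g_leak * (V - p.E_leak) - I_channels + I_total) / p.C_m
    deriv["Ca"] = -p.ca_rho * I_ca - Ca / p.ca_tau
    return deriv


def graded_synapse_step(s, V_pre, p: GradedSynapseParams, dt):
    """One Euler step of the graded-synapse gating variable, clamped to [0, 1]."""
    s_inf = 1.0 / (1.0 + np.exp((p.V_th_pre - V_pre) / p.delta))
    s_new = s + dt * (s_inf - s) / p.tau_s
    return float(np.clip(s_new, 0.0, 1.0))


def synapse_current(kind, gate_or_conductance, weight, V_post, E_syn):
    """Postsynaptic current in pA (positive = depolarising, into the cell).

    ``graded``: I = weight * s * (E_syn - V_post) with s the gating variable.
    ``spike``: I = g * (E_syn - V_post) with g the decaying conductance (nS),
    already scaled by the weight at each spike event.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if kind == "graded":
        return weight * gate_or_conductance * (E_syn - V_post)
    if kind == "spike":
        return gate_or_conductance * (E_syn - V_post)
    raise ValueError(f"unknown synapse kind {kind!r}")


def gap_junction_current(V_a, V_b, weight):
    """Ohmic gap-junction currents into each coupled cell; sums to zero."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    I_into_a = weight * (V_b - V_a)
    return I_into_a, -I_into_a


def activity_step(a, spiked, p: ActivityParams, dt):
    """One Euler step of the firing-rate proxy (readout only, no feedback)."""
    if a < 0:
        raise ValueError("activity must be >= 0")
    return a * (1.0 - dt / p.tau_activity) + (p.increment_per_spike if spiked else 0.0)
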