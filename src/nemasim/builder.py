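"""Instantiate runnable network models from a connectome and a parameter set.

A :class:`ParameterSet` fixes the level of biophysical detail:

====== ===================== ====================================== ==========
level  cells                 chemical synapses                      gap junctions
====== ===================== ====================================== ==========
A      LIF                   spike-triggered (for ALL connections)  converted to excitatory spike synapses
B      LIF + activity proxy  spike-triggered                        true electrical coupling
C      conductance-based     spike-triggered                        true electrical coupling
C1     conductance-based     graded (analogue)                      true electrical coupling
====== ===================== ====================================== ==========

Every chemical connection's conductance is ``baseline_chem x n_contacts``
and its polarity follows the presynaptic neurotransmitter (GABA inhibits,
everything else excites); individual weights can then be overridden to probe
how single connections shape network behaviour.

Shipped default constants for each level live in versioned JSON files under
``nemasim/data/parameters/``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .connectome import (
    UNKNOWN,
    CellClass,
    CellIdentity,
    Connectome,
    Polarity,
    classify_polarity,
    connection_weight,
    subset_connectome,
)
from .dynamics import (
    ActivityParams,
    ChannelSpec,
    ConductanceCellParams,
    GapJunctionParams,
    GateSpec,
    GradedSynapseParams,
    LIFParams,
    SpikeSynapseParams,
)

LEVELS = ("A", "B", "C", "C1")

#: Levels whose cells are LIF point neurons.
LIF_LEVELS = ("A", "B")

SYNAPSE_KINDS = ("chem_exc", "chem_inh", "gap")


class ConfigError(ValueError):
    """Invalid level tag or inconsistent parameter-set contents."""


class SynapseLookupError(KeyError):
    """No synapse matches the requested (pre, post, kind) triple."""


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

def _gate_from_dict(d: Mapping) -> GateSpec:
    return GateSpec(V_half=d["V_half"], slope_k=d["slope_k"], tau=d["tau"],
                    exponent=int(d.get("exponent", 1)))


def _channel_from_dict(d: Mapping) -> ChannelSpec:
    inact = d.get("inactivation")
    return ChannelSpec(
        gbar=d["gbar"],
        E_rev=d["E_rev"],
        activation=_gate_from_dict(d["activation"]),
        inactivation=_gate_from_dict(inact) if inact else None,
        is_calcium_carrier=bool(d.get("is_calcium_carrier", False)),
    )


def _cell_from_dict(d: Mapping):
    model = d.get("model", "lif")
    if model == "lif":
        return LIFParams(C_m=d["C_m"], g_leak=d["g_leak"], E_leak=d["E_leak"],
                         V_thresh=d["V_thresh"], V_reset=d["V_reset"],
                         t_refract=d["t_refract"])
    if model == "conductance":
        return ConductanceCellParams(
            C_m=d["C_m"], g_leak=d["g_leak"], E_leak=d["E_leak"],
            channels=tuple(_channel_from_dict(c) for c in d.get("channels", [])),
            ca_rho=d.get("ca_rho", 0.0), ca_tau=d.get("ca_tau", 200.0),
            spike_detect_threshold=d.get("spike_detect_threshold", 0.0),
        )
    raise ConfigError(f"unknown cell model {model!r}")


def _syn_from_dict(d: Mapping):
    model = d.get("model", "spike")
    if model == "spike":
        return SpikeSynapseParams(g_base=d.get("g_base", 1.0), E_syn=d["E_syn"],
                                  tau_decay=d["tau_decay"])
    if model == "graded":
        return GradedSynapseParams(g_base=d.get("g_base", 1.0), E_syn=d["E_syn"],
                                   V_th_pre=d["V_th_pre"], delta=d["delta"],
                                   tau_s=d["tau_s"])
    raise ConfigError(f"unknown synapse model {model!r}")


@dataclass(frozen=True)
class ParameterSet:
    """All constants needed to resolve the model equations at one level."""

    level: str
    neuron_params: LIFParams | ConductanceCellParams
    muscle_params: LIFParams | ConductanceCellParams
    exc_syn: SpikeSynapseParams | GradedSynapseParams
    inh_syn: SpikeSynapseParams | GradedSynapseParams
    gap: GapJunctionParams = GapJunctionParams()
    baseline_chem: float = 0.01   # nS per anatomical contact
    baseline_gap: float = 0.01    # nS per anatomical contact
    activity: ActivityParams | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ConfigError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        lif = self.level in LIF_LEVELS
        cell_type = LIFParams if lif else ConductanceCellParams
        for which, p in (("neuron", self.neuron_params), ("muscle", self.muscle_params)):
            if not isinstance(p, cell_type):
                raise ConfigError(
                    f"level {self.level} requires {cell_type.__name__} for {which} cells")
        syn_type = GradedSynapseParams if self.level == "C1" else SpikeSynapseParams
        for which, s in (("exc_syn", self.exc_syn), ("inh_syn", self.inh_syn)):
            if not isinstance(s, syn_type):
                raise ConfigError(
                    f"level {self.level} requires {syn_type.__name__} for {which}")
        if self.baseline_chem < 0 or self.baseline_gap < 0:
            raise ConfigError("baseline conductances must be >= 0")

    @property
    def uses_lif(self) -> bool:
        return self.level in LIF_LEVELS

    @property
    def uses_graded(self) -> bool:
        return self.level == "C1"

    @property
    def gaps_as_synapses(self) -> bool:
        """Level A represents every connection, gap junctions included,
        as a spike-triggered synapse."""
        return self.level == "A"

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        act = d.get("activity")
        return cls(
            level=d["level"],
            neuron_params=_cell_from_dict(d["neuron"]),
            muscle_params=_cell_from_dict(d["muscle"]),
            exc_syn=_syn_from_dict(d["exc_syn"]),
            inh_syn=_syn_from_dict(d["inh_syn"]),
            gap=GapJunctionParams(g_gap=d.get("gap", {}).get("g_gap", 1.0)),
            baseline_chem=d.get("baseline_chem", 0.01),
            baseline_gap=d.get("baseline_gap", 0.01),
            activity=ActivityParams(**act) if act else None,
        )

    @classmethod
    def from_level(cls, level: str) -> "ParameterSet":
        """Load one of the shipped parameter files (A, B, C or C1)."""
        if level not in LEVELS:
            raise ConfigError(f"unknown level {level!r}; expected one of {LEVELS}")
        ref = resources.files("nemasim.data.parameters").joinpath(f"{level}.json")
        return cls.from_dict(json.loads(ref.read_text()))

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Square current pulses injected into one cell.

    ``period=None`` means a single pulse; ``n_pulses=None`` means the pulse
    train continues for the whole simulation.
    """

    target: str
    amplitude: float            # pA
    onset: float = 0.0          # ms
    pulse_duration: float = 100.0  # ms
    period: float | None = None    # ms
    n_pulses: int | None = 1

    def __post_init__(self):
        if not math.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.period is not None and self.pulse_duration > self.period:
            raise ValueError("pulse_duration must not exceed period")


@dataclass(frozen=True)
class Synapse:
    """One resolved connection instance: kind and conductance fully decided."""

    pre: str
    post: str
    kind: str  # chem_exc | chem_inh | gap
    weight: float  # nS

    def __post_init__(self):
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("synapse weight must be >= 0")


@dataclass(frozen=True)
class NetworkCell:
    identity: CellIdentity
    model: str  # "lif" | "conductance"
    position: tuple[float, float, float]

    @property
    def name(self) -> str:
        return self.identity.name

    @property
    def is_muscle(self) -> bool:
        return self.identity.cell_class is CellClass.MUSCLE


@dataclass(frozen=True)
class NetworkModel:
    """A fully instantiated network, ready for simulation or export."""

    cells: tuple[NetworkCell, ...]
    synapses: tuple[Synapse, ...]
    stimuli: tuple[StimulusProtocol, ...]
    parameter_set: ParameterSet

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "synapses", tuple(self.synapses))
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        names = [c.name for c in self.cells]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell names in network")
        known = set(names)
        for s in self.synapses:
            if s.pre not in known or s.post not in known:
                raise ValueError(f"synapse {s.pre}->{s.post} references unknown cell")
        for st in self.stimuli:
            if st.target not in known:
                raise ValueError(f"stimulus targets unknown cell {st.target!r}")

    @property
    def cell_names(self) -> list[str]:
        return [c.name for c in self.cells]

    @property
    def neuron_names(self) -> list[str]:
        return [c.name for c in self.cells if not c.is_muscle]

    @property
    def muscle_names(self) -> list[str]:
        return [c.name for c in self.cells if c.is_muscle]

    def with_stimuli(self, stimuli: Iterable[StimulusProtocol]) -> "NetworkModel":
        return replace(self, stimuli=tuple(stimuli))

    def add_synapses(self, synapses: Iterable[Synapse]) -> "NetworkModel":
        return replace(self, synapses=self.synapses + tuple(synapses))

    def to_json_dict(self) -> dict:
        """Stable, diffable JSON representation of the network structure."""
        return {
            "parameter_level": self.parameter_set.level,
            "cells": [
                {
                    "name": c.name,
                    "class": c.identity.cell_class.value,
                    "neurotransmitter": c.identity.neurotransmitter,
                    "model": c.model,
                    "position": list(c.position),
                }
                for c in self.cells
            ],
            "synapses": [
                {"pre": s.pre, "post": s.post, "kind": s.kind, "weight": s.weight}
                for s in self.synapses
            ],
            "stimuli": [
                {
                    "target": st.target,
                    "amplitude": st.amplitude,
                    "onset": st.onset,
                    "pulse_duration": st.pulse_duration,
                    "period": st.period,
                    "n_pulses": st.n_pulses,
                }
                for st in self.stimuli
            ],
        }

    def dump_json(self, stream) -> None:
        json.dump(self.to_json_dict(), stream, indent=1, sort_keys=True)
        stream.write("\n")


# ---------------------------------------------------------------------------
# Muscle layout
# ---------------------------------------------------------------------------

#: Spacing between successive muscles along the anterior-posterior axis (um)
#: and the lateral offsets that keep the four rows visually separated from
#: the body axis.
_MUSCLE_SPACING = 40.0
_ROW_OFFSETS = {"MDL": (60.0, 30.0), "MDR": (60.0, -30.0),
                "MVL": (-60.0, 30.0), "MVR": (-60.0, -30.0)}


def layout_muscles() -> list[tuple[str, tuple[float, float, float]]]:
    """The 96 body-wall muscles in four rows of 24, anterior to posterior.

    Quadrants are dorsal/ventral x left/right (prefixes MDL, MDR, MVL, MVR),
    each with zero-padded indices 01-24 running head to tail.  Rows are
    offset from the body axis so connections stay legible in visualisations.
    """
    out = []
    for prefix in ("MDL", "MDR", "MVL", "MVR"):
        dy, dz = _ROW_OFFSETS[prefix]
        for idx in range(1, 25):
            out.append((f"{prefix}{idx:02d}", ((idx - 1) * _MUSCLE_SPACING, dy, dz)))
    return out


_MUSCLE_POSITIONS = {name: pos for name, pos in layout_muscles()}


def _muscle_position(name: str) -> tuple[float, float, float]:
    if name in _MUSCLE_POSITIONS:
        return _MUSCLE_POSITIONS[name]
    prefix, idx = name[:3], int(name[3:])
    dy, dz = _ROW_OFFSETS.get(prefix, (0.0, 0.0))
    return ((idx - 1) * _MUSCLE_SPACING, dy, dz)


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def _resolve_kind(conn, connectome: Connectome) -> str:
    nt = conn.neurotransmitter
    if nt == UNKNOWN:
        nt = connectome.cells[conn.pre].neurotransmitter
    return "chem_inh" if classify_polarity(nt) is Polarity.INHIBITORY else "chem_exc"


def build_network(
    connectome: Connectome,
    subset: Sequence[str] | None = None,
    parameter_set: ParameterSet | None = None,
) -> NetworkModel:
    """Instantiate a :class:`NetworkModel` from a connectome.

    ``subset=None`` selects every cell.  Soma positions come from the
    connectome when present; otherwise neurons are strung along the
    anterior-posterior axis in canonical name order and muscles take their
    quadrant-row positions.  Chemical weights follow the contact-count rule;
    polarity follows the presynaptic neurotransmitter.  Under level A every
    gap junction becomes a pair of excitatory spike-triggered synapses of
    equal conductance (one per direction).
    """
    p = parameter_set if parameter_set is not None else ParameterSet.from_level("C")
    c = connectome if subset is None else subset_connectome(connectome, subset)
    c.validate()

    cells: list[NetworkCell] = []
    neuron_names = sorted(n for n, ci in c.cells.items()
                          if ci.cell_class is not CellClass.MUSCLE)
    model = "lif" if p.uses_lif else "conductance"
    for i, name in enumerate(neuron_names):
        ci = c.cells[name]
        pos = ci.soma_position if ci.soma_position is not None else (i * 40.0, 0.0, 0.0)
        cells.append(NetworkCell(identity=ci, model=model, position=pos))
    for name in sorted(n for n, ci in c.cells.items()
                       if ci.cell_class is CellClass.MUSCLE):
        ci = c.cells[name]
        pos = ci.soma_position if ci.soma_position is not None else _muscle_position(name)
        cells.append(NetworkCell(identity=ci, model=model, position=pos))

    synapses: list[Synapse] = []
    for conn in c.chemical:
        synapses.append(Synapse(
            pre=conn.pre, post=conn.post, kind=_resolve_kind(conn, c),
            weight=connection_weight(conn.n_contacts, p.baseline_chem)))
    for conn in c.electrical:
        w = connection_weight(conn.n_contacts, p.baseline_gap)
        if p.gaps_as_synapses:
            synapses.append(Synapse(conn.cell_a, conn.cell_b, "chem_exc", w))
            synapses.append(Synapse(conn.cell_b, conn.cell_a, "chem_exc", w))
        else:
            synapses.append(Synapse(conn.cell_a, conn.cell_b, "gap", w))

    return NetworkModel(cells=tuple(cells), synapses=tuple(synapses),
                        stimuli=(), parameter_set=p)


def override_weight(net: NetworkModel, pre: str, post: str, kind: str,
                    new_weight: float) -> NetworkModel:
    """Return a copy of ``net`` with one synapse's weight replaced.

    Gap junctions match in either endpoint order.  Raises
    :class:`SynapseLookupError` when no synapse matches.
    """
    if kind not in SYNAPSE_KINDS:
        raise ValueError(f"unknown synapse kind {kind!r}")
    new_synapses = []
    hit = False
    for s in net.synapses:
        match = s.kind == kind and (
            (s.pre == pre and s.post == post)
            or (kind == "gap" and s.pre == post and s.post == pre)
        )
        if match and not hit:
            new_synapses.append(replace(s, weight=new_weight))
            hit = True
        else:
            new_synapses.append(s)
    if not hit:
        raise SynapseLookupError(f"no {kind} synapse {pre}->{post} in network")
    return replace(net, synapses=tuple(new_synapses))


# ---------------------------------------------------------------------------
# Demo network: four synaptically coupled pairs
# ---------------------------------------------------------------------------

#: Contact count used for each demo connection (weight = 10 x baseline).
_DEMO_CONTACTS = 10


def build_four_pair_demo(
    parameter_set: ParameterSet,
    stim_amplitude: float = 10.0,
    stim_onset: float = 200.0,
    stim_duration: float = 100.0,
    stim_period: float = 400.0,
) -> NetworkModel:
    """Eight single-compartment cells in four synaptically coupled pairs.

    Seven neurons and one muscle: an excitatory chemical pair, an inhibitory
    chemical pair (GABAergic presynaptic cell), a gap-junction pair, and an
    excitatory chemical connection onto a muscle.  Each presynaptic cell
    receives two square current pulses, so the postsynaptic responses show
    the signature of each connection class side by side.
    """
    cells = {
        "PREEXC": CellIdentity("PREEXC", CellClass.INTERNEURON, "Acetylcholine", (0.0, 0.0, 0.0)),
        "POSTEXC": CellIdentity("POSTEXC", CellClass.INTERNEURON, UNKNOWN, (40.0, 0.0, 0.0)),
        "PREINH": CellIdentity("PREINH", CellClass.INTERNEURON, "GABA", (0.0, 40.0, 0.0)),
        "POSTINH": CellIdentity("POSTINH", CellClass.INTERNEURON, UNKNOWN, (40.0, 40.0, 0.0)),
        "PREGAP": CellIdentity("PREGAP", CellClass.INTERNEURON, "Acetylcholine", (0.0, 80.0, 0.0)),
        "POSTGAP": CellIdentity("POSTGAP", CellClass.INTERNEURON, UNKNOWN, (40.0, 80.0, 0.0)),
        "PREMUS": CellIdentity("PREMUS", CellClass.MOTORNEURON, "Acetylcholine", (0.0, 120.0, 0.0)),
        "MDL01": CellIdentity("MDL01", CellClass.MUSCLE, UNKNOWN),
    }
    from .connectome import ChemicalConnection, ElectricalConnection

    c = Connectome(
        cells=cells,
        chemical=[
            ChemicalConnection("PREEXC", "POSTEXC", _DEMO_CONTACTS, "Acetylcholine"),
            ChemicalConnection("PREINH", "POSTINH", _DEMO_CONTACTS, "GABA"),
            ChemicalConnection("PREMUS", "MDL01", _DEMO_CONTACTS, "Acetylcholine"),
        ],
        electrical=[ElectricalConnection("PREGAP", "POSTGAP", _DEMO_CONTACTS)],
        source_tag="four_pair_demo",
    )
    net = build_network(c, parameter_set=parameter_set)
    stimuli = tuple(
        StimulusProtocol(target=pre, amplitude=stim_amplitude, onset=stim_onset,
                         pulse_duration=stim_duration, period=stim_period, n_pulses=2)
        for pre in ("PREEXC", "PREINH", "PREGAP", "PREMUS")
    )
    return net.with_stimuli(stimuli)
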