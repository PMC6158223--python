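"""The forward-locomotion circuit and traveling-wave analysis.

The circuit is the classic forward-crawling subnetwork of *C. elegans*: the
AVB command-interneuron pair, 18 excitatory (cholinergic) B-type motor
neurons (DB1-DB7 dorsal, VB1-VB11 ventral), 19 inhibitory (GABAergic)
D-type motor neurons (DD1-DD6, VD1-VD13), and the 96 body-wall muscles in
four quadrants.  Connectivity follows the hypothesised functional circuit:

* AVB makes gap junctions onto every B-type neuron; consecutive B neurons of
  each chain are gap-junction coupled;
* B neurons excite their block of ipsilateral-side muscles; D neurons
  inhibit theirs;
* DB excites VD and inhibits DD; VB excites DD and inhibits VD — so dorsal
  drive silences ventral muscles and vice versa;
* a feed-forward "proprioceptive" excitation from each B neuron to its
  posterior neighbour propagates activity toward the tail (a static graded
  stand-in for stretch-receptor signalling of anterior body bending).

Rhythm comes from a hypothetical central pattern generator approximated by
periodic current pulses into DB1 and VB1 (ventral delayed by half a period),
a tonic holding current into AVB, and synchronized pulses into the first
seven (head) muscles of each quadrant, whose presynaptic neurons are outside
the circuit.  All synaptic connections share one uniform weight.

:func:`wave_metrics` quantifies the resulting muscle-calcium pattern:
per-muscle activation peak times, the head-to-tail propagation slope of the
first-cycle peaks in each quadrant, the oscillation frequency, and the
dorsoventral and left-right phase relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .builder import (
    ConfigError,
    NetworkCell,
    NetworkModel,
    ParameterSet,
    StimulusProtocol,
    Synapse,
    layout_muscles,
)
from .connectome import CellClass, CellIdentity
from .simulator import SimulationResult

#: Neuron classes of the circuit, anterior to posterior within each chain.
DB_NEURONS = tuple(f"DB{i}" for i in range(1, 8))
VB_NEURONS = tuple(f"VB{i}" for i in range(1, 12))
DD_NEURONS = tuple(f"DD{i}" for i in range(1, 7))
VD_NEURONS = tuple(f"VD{i}" for i in range(1, 14))
AVB_NEURONS = ("AVBL", "AVBR")

#: Muscle index range innervated by motor neurons (head muscles 1-7 are
#: driven directly by the stimulus protocol instead).
INNERVATED_RANGE = (8, 24)

#: The one muscle left without any input, hence silent.
SILENT_MUSCLE = "MVL24"

QUADRANTS = ("MDL", "MDR", "MVL", "MVR")


class AnalysisError(RuntimeError):
    """Raised when a required trace yields no activation peaks."""


@dataclass(frozen=True)
class LocomotionConfig:
    """Drive and coupling constants for the forward-locomotion run.

    The connectome fixes who talks to whom; these constants fix how hard.
    None of them is reported in the source literature — the defaults were
    chosen so the circuit expresses a clean head-to-tail wave with antiphase
    dorsoventral alternation at the drive frequency (~0.8 Hz, four body
    waves in a 5 s run).
    """

    cpg_period: float = 1250.0          # ms between CPG pulses
    cpg_pulse_duration: float = 300.0   # ms
    cpg_amplitude: float = 25.0          # pA into DB1 / VB1
    dorsoventral_delay: float = 625.0   # ms; ventral drive lags dorsal
    head_stim_amplitude: float = 20.0   # pA into head muscles
    head_phase_offset: float = 0.0      # ms relative to the CPG pulses
    avb_amplitude: float = 5.0          # pA tonic into AVBL/AVBR
    proprio_gain: float = 0.7           # nS per B->B feed-forward connection
    uniform_weight: float = 0.1         # nS shared by every wired connection
    innervation_map: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self):
        if not 0 < self.cpg_pulse_duration < self.cpg_period:
            raise ValueError("need cpg_period > cpg_pulse_duration > 0")
        if self.proprio_gain < 0 or self.uniform_weight < 0:
            raise ValueError("gains must be >= 0")

    def resolved_innervation(self) -> dict[str, tuple[str, ...]]:
        if self.innervation_map is not None:
            return {k: tuple(v) for k, v in self.innervation_map.items()}
        return default_innervation_map()


@dataclass(frozen=True)
class WaveMetrics:
    """Quantitative summary of the muscle activation pattern."""

    peak_times: dict[str, np.ndarray]          # ms, per muscle
    propagation_slope: dict[str, float]        # ms per muscle index, per quadrant
    dorsoventral_phase: float                  # fraction of a period, [0, 1)
    left_right_phase: float                    # fraction of a period, [0, 1)
    frequency: float                           # Hz

    def to_json_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency,
            "propagation_slope_ms_per_index": dict(self.propagation_slope),
            "dorsoventral_phase": self.dorsoventral_phase,
            "left_right_phase": self.left_right_phase,
            "peak_times_ms": {k: list(map(float, v)) for k, v in self.peak_times.items()},
        }


# ---------------------------------------------------------------------------
# Innervation fixture
# ---------------------------------------------------------------------------

def _chain_blocks(n_neurons: int) -> list[tuple[int, int]]:
    """Split muscle indices 8..24 into n contiguous blocks overlapping by one."""
    lo, hi = INNERVATED_RANGE
    cuts = [lo + round((hi - lo) * i / n_neurons) for i in range(n_neurons + 1)]
    return [(cuts[i], cuts[i + 1]) for i in range(n_neurons)]


def default_innervation_map() -> dict[str, tuple[str, ...]]:
    """Anatomically ordered block innervation of the body muscles.

    Each motor neuron of a class innervates a contiguous run of muscle
    indices within 8-24, anterior neurons anterior blocks, with consecutive
    neurons sharing one boundary muscle.  Dorsal neurons (DB, DD) project to
    both dorsal rows (MDL and MDR), ventral neurons (VB, VD) to both ventral
    rows.  MVL24 is excluded, so of the 96 muscles exactly 95 receive input
    (head muscles 1-7 are driven by the stimulus protocol) and MVL24 stays
    silent.
    """
    out: dict[str, tuple[str, ...]] = {}
    for chain, rows in ((DB_NEURONS, ("MDL", "MDR")), (DD_NEURONS, ("MDL", "MDR")),
                        (VB_NEURONS, ("MVL", "MVR")), (VD_NEURONS, ("MVL", "MVR"))):
        blocks = _chain_blocks(len(chain))
        for neuron, (lo, hi) in zip(chain, blocks):
            muscles = [f"{row}{i:02d}" for row in rows for i in range(lo, hi + 1)]
            out[neuron] = tuple(m for m in muscles if m != SILENT_MUSCLE)
    return out


def load_innervation_csv(path) -> dict[str, tuple[str, ...]]:
    """Read a real innervation table (columns: neuron, muscle; one edge per row)."""
    import csv

    out: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.strip().lower(): c for c in reader.fieldnames or []}
        if "neuron" not in cols or "muscle" not in cols:
            raise ValueError("innervation CSV needs 'neuron' and 'muscle' columns")
        for row in reader:
            out.setdefault(row[cols["neuron"]].strip(), []).append(row[cols["muscle"]].strip())
    return {k: tuple(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Circuit construction
# ---------------------------------------------------------------------------

def _neuron_cell(name: str, x: float, nt: str) -> NetworkCell:
    ident = CellIdentity(name, CellClass.INTERNEURON if name.startswith("AVB")
                         else CellClass.MOTORNEURON, nt, (x, 0.0, 0.0))
    return NetworkCell(identity=ident, model="conductance", position=(x, 0.0, 0.0))


def _overlapping(blocks_a: list[tuple[int, int]], blocks_b: list[tuple[int, int]]):
    """Pairs (i, j) of block indices sharing at least one muscle index."""
    for i, (alo, ahi) in enumerate(blocks_a):
        for j, (blo, bhi) in enumerate(blocks_b):
            if alo <= bhi and blo <= ahi:
                yield i, j


def build_forward_locomotion(parameter_set: ParameterSet,
                             config: LocomotionConfig | None = None) -> NetworkModel:
    """Build the 39-neuron / 96-muscle forward-locomotion network.

    Requires a conductance-based parameter set (level C or C1); the original
    demonstration uses C1, i.e. graded chemical synapses.  All wired
    connections share ``config.uniform_weight``; when ``config.proprio_gain``
    is positive the feed-forward B-chain coupling is attached as well.
    """
    cfg = config if config is not None else LocomotionConfig()
    if parameter_set.level not in ("C", "C1"):
        raise ConfigError(
            f"forward locomotion needs conductance-based cells (level C or C1), "
            f"got level {parameter_set.level}")

    cells: list[NetworkCell] = []
    cells.append(_neuron_cell("AVBL", -80.0, "Acetylcholine"))
    cells.append(_neuron_cell("AVBR", -80.0, "Acetylcholine"))
    for chain, nt in ((DB_NEURONS, "Acetylcholine"), (VB_NEURONS, "Acetylcholine"),
                      (DD_NEURONS, "GABA"), (VD_NEURONS, "GABA")):
        blocks = _chain_blocks(len(chain))
        for name, (lo, hi) in zip(chain, blocks):
            cells.append(_neuron_cell(name, (lo + hi) / 2 * 40.0, nt))
    for name, pos in layout_muscles():
        ident = CellIdentity(name, CellClass.MUSCLE, soma_position=pos)
        cells.append(NetworkCell(identity=ident, model="conductance", position=pos))

    w = cfg.uniform_weight
    synapses: list[Synapse] = []
    # AVB gap junctions onto every B-type neuron
    for avb in AVB_NEURONS:
        for b in DB_NEURONS + VB_NEURONS:
            synapses.append(Synapse(avb, b, "gap", w))
    # chain gap junctions between consecutive B neurons
    for chain in (DB_NEURONS, VB_NEURONS):
        for a, b in zip(chain, chain[1:]):
            synapses.append(Synapse(a, b, "gap", w))
    # motor neuron -> muscle innervation
    innervation = cfg.resolved_innervation()
    for chain, kind in ((DB_NEURONS, "chem_exc"), (VB_NEURONS, "chem_exc"),
                        (DD_NEURONS, "chem_inh"), (VD_NEURONS, "chem_inh")):
        for neuron in chain:
            for muscle in innervation.get(neuron, ()):
                synapses.append(Synapse(neuron, muscle, kind, w))
    # B -> D cross-coupling: dorsal drive suppresses ventral muscles and
    # disinhibits dorsal ones, and vice versa
    db_blocks, vb_blocks = _chain_blocks(len(DB_NEURONS)), _chain_blocks(len(VB_NEURONS))
    dd_blocks, vd_blocks = _chain_blocks(len(DD_NEURONS)), _chain_blocks(len(VD_NEURONS))
    for i, j in _overlapping(db_blocks, vd_blocks):
        synapses.append(Synapse(DB_NEURONS[i], VD_NEURONS[j], "chem_exc", w))
    for i, j in _overlapping(db_blocks, dd_blocks):
        synapses.append(Synapse(DB_NEURONS[i], DD_NEURONS[j], "chem_inh", w))
    for i, j in _overlapping(vb_blocks, dd_blocks):
        synapses.append(Synapse(VB_NEURONS[i], DD_NEURONS[j], "chem_exc", w))
    for i, j in _overlapping(vb_blocks, vd_blocks):
        synapses.append(Synapse(VB_NEURONS[i], VD_NEURONS[j], "chem_inh", w))

    # stimulation: tonic AVB, phase-shifted CPG pulses, head-muscle drive
    stimuli: list[StimulusProtocol] = []
    for avb in AVB_NEURONS:
        stimuli.append(StimulusProtocol(target=avb, amplitude=cfg.avb_amplitude,
                                        onset=0.0, pulse_duration=1e9,
                                        period=None, n_pulses=1))
    stimuli.append(StimulusProtocol(target="DB1", amplitude=cfg.cpg_amplitude,
                                    onset=0.0, pulse_duration=cfg.cpg_pulse_duration,
                                    period=cfg.cpg_period, n_pulses=None))
    stimuli.append(StimulusProtocol(target="VB1", amplitude=cfg.cpg_amplitude,
                                    onset=cfg.dorsoventral_delay,
                                    pulse_duration=cfg.cpg_pulse_duration,
                                    period=cfg.cpg_period, n_pulses=None))
    for quadrant in QUADRANTS:
        onset = cfg.head_phase_offset
        if quadrant.startswith("MV"):
            onset += cfg.dorsoventral_delay
        for idx in range(1, 8):
            stimuli.append(StimulusProtocol(
                target=f"{quadrant}{idx:02d}", amplitude=cfg.head_stim_amplitude,
                onset=onset, pulse_duration=cfg.cpg_pulse_duration,
                period=cfg.cpg_period, n_pulses=None))

    net = NetworkModel(cells=tuple(cells), synapses=tuple(synapses),
                       stimuli=tuple(stimuli), parameter_set=parameter_set)
    if cfg.proprio_gain > 0:
        net = add_proprioceptive_coupling(net, cfg.proprio_gain)
    return net


def add_proprioceptive_coupling(net: NetworkModel, gain: float) -> NetworkModel:
    """Feed-forward excitation from each B neuron to its posterior neighbour.

    Adds one excitatory connection DBi -> DBi+1 and VBi -> VBi+1 (anterior to
    posterior only) with conductance ``gain``; this is the static stand-in
    for stretch-receptor proprioception that lets the anterior bend recruit
    the next body segment.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    names = set(net.cell_names)
    extra = []
    for chain in (DB_NEURONS, VB_NEURONS):
        present = [n for n in chain if n in names]
        for a, b in zip(present, present[1:]):
            extra.append(Synapse(a, b, "chem_exc", gain))
    return net.add_synapses(extra)


# ---------------------------------------------------------------------------
# Wave analysis
# ---------------------------------------------------------------------------

#: Peak prominence threshold, as a fraction of each trace's range.
PEAK_PROMINENCE_FRACTION = 0.2

#: Traces whose total range is below this (uM) are considered flat.
FLAT_RANGE = 1e-6


def default_muscle_order(include_silent: bool = False) -> dict[str, list[str]]:
    """Anterior-to-posterior muscle names per quadrant (MVL24 excluded by
    default: it receives no input in the fixture circuit)."""
    out = {}
    for q in QUADRANTS:
        names = [f"{q}{i:02d}" for i in range(1, 25)]
        if not include_silent:
            names = [n for n in names if n != SILENT_MUSCLE]
        out[q] = names
    return out


def _peak_times(trace: np.ndarray, times: np.ndarray, settle_time: float,
                name: str) -> np.ndarray:
    sel = times >= settle_time
    t, x = times[sel], np.asarray(trace)[sel]
    rng = float(x.max() - x.min()) if len(x) else 0.0
    if rng < FLAT_RANGE:
        raise AnalysisError(f"no activation peaks in trace for muscle {name!r}")
    idx, _ = find_peaks(x, prominence=PEAK_PROMINENCE_FRACTION * rng)
    if len(idx) == 0:
        raise AnalysisError(f"no activation peaks in trace for muscle {name!r}")
    return t[idx]


def _circular_phase(deltas_ms: Sequence[float], period_ms: float) -> float:
    """Circular mean of time offsets, as a phase fraction in [0, 1)."""
    if len(deltas_ms) == 0:
        return 0.0
    ang = 2.0 * np.pi * (np.asarray(deltas_ms, dtype=float) / period_ms)
    mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (mean / (2.0 * np.pi)) % 1.0


def wave_metrics(result: SimulationResult,
                 muscle_order: Mapping[str, Sequence[str]] | None = None,
                 settle_time: float = 1250.0) -> WaveMetrics:
    """Measure traveling-wave structure in the muscle calcium traces.

    For each listed muscle, activation peaks are local maxima of [Ca2+]
    after ``settle_time`` with prominence at least 20% of the trace range.
    The propagation slope per quadrant is the least-squares slope of the
    first post-settle peak time against muscle index (positive = head to
    tail).  Frequency comes from the median inter-peak interval of a
    reference muscle (the midpoint of the first quadrant list); phases are
    circular means of per-index first-peak offsets between paired quadrants
    (dorsal vs ventral, and left vs right within the dorsal pair).
    """
    order = {k: list(v) for k, v in (muscle_order or default_muscle_order()).items()}
    if result.Ca is None:
        raise AnalysisError("result contains no calcium traces")
    if settle_time >= result.times[-1]:
        raise ValueError("settle_time must be below the simulated duration")

    peaks: dict[str, np.ndarray] = {}
    for names in order.values():
        for name in names:
            peaks[name] = _peak_times(result.calcium(name), result.times,
                                      settle_time, name)

    slopes: dict[str, float] = {}
    for q, names in order.items():
        indices = np.array([int(n[3:]) for n in names], dtype=float)
        first = np.array([peaks[n][0] for n in names])
        slope, _ = np.polyfit(indices, first, 1)
        slopes[q] = float(slope)

    ref_names = order[next(iter(order))]
    ref = ref_names[len(ref_names) // 2]
    intervals = np.diff(peaks[ref])
    if len(intervals) == 0:
        raise AnalysisError(f"reference muscle {ref!r} has a single peak; "
                            "simulate longer to estimate frequency")
    period = float(np.median(intervals))
    frequency = 1000.0 / period

    def paired_deltas(quad_a: str, quad_b: str) -> list[float]:
        names_a = {int(n[3:]): n for n in order.get(quad_a, [])}
        names_b = {int(n[3:]): n for n in order.get(quad_b, [])}
        shared = sorted(set(names_a) & set(names_b))
        return [peaks[names_b[i]][0] - peaks[names_a[i]][0] for i in shared]

    dv = _circular_phase(paired_deltas("MDL", "MVL") + paired_deltas("MDR", "MVR"),
                         period)
    lr = _circular_phase(paired_deltas("MDL", "MDR"), period)

    return WaveMetrics(peak_times=peaks, propagation_slope=slopes,
                       dorsoventral_phase=dv, left_right_phase=lr,
                       frequency=frequency)
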