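"""Wiring diagrams of the *C. elegans* nervous system.

A :class:`Connectome` is the set of identified cells plus the chemical
synapses and gap junctions between them, each annotated with the number of
anatomical contacts observed in the electron-microscopy reconstructions.
Two public spreadsheet layouts are supported behind one reader: the
Varshney/WormAtlas layout (``Neuron 1, Neuron 2, Type, Nbr`` with type codes
``S/Sp/R/Rp/EJ/NMJ``) and the WormWiring layout (``Origin, Target, Type,
Number of Connections, Neurotransmitter`` with types ``Send``/``GapJunction``).

The module also houses the two rules that turn anatomy into physiology:

* **polarity** — a connection is inhibitory iff the presynaptic cell's
  neurotransmitter is GABA, excitatory otherwise (including unknown);
* **weight** — synaptic conductance is a per-contact baseline conductance
  multiplied by the anatomical contact count.

A seeded synthetic-connectome generator provides realistic wiring (geometric
contact counts, a GABAergic subpopulation, muscles strictly postsynaptic)
without any external download.
"""

from __future__ import annotations

import csv
import enum
import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

#: Name prefixes of the four body-wall muscle quadrants
#: (dorsal/ventral x left/right).
MUSCLE_PREFIXES = ("MDL", "MDR", "MVL", "MVR")


class CellClass(enum.Enum):
    SENSORY = "sensory"
    INTERNEURON = "interneuron"
    MOTORNEURON = "motorneuron"
    MUSCLE = "muscle"


class Polarity(enum.Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"


class ConnectomeFormatError(ValueError):
    """Raised when a wiring table lacks a required column."""


class RowError(ValueError):
    """Raised for a malformed wiring-table row; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class UnknownCellError(KeyError):
    """Raised when a requested cell name is absent from a connectome."""


@dataclass(frozen=True)
class CellIdentity:
    """One identified cell: a neuron or a body-wall muscle.

    ``soma_position`` is in micrometres; ``None`` means "no coordinates in
    the source", in which case the network builder places the soma along an
    abstract anterior-posterior axis.
    """

    name: str
    cell_class: CellClass = CellClass.INTERNEURON
    neurotransmitter: str = UNKNOWN
    soma_position: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("cell name must be non-empty")
        if self.soma_position is not None:
            pos = tuple(float(x) for x in self.soma_position)
            if not all(np.isfinite(pos)):
                raise ValueError(f"non-finite soma position for {self.name}")
            object.__setattr__(self, "soma_position", pos)


@dataclass(frozen=True)
class ChemicalConnection:
    """Directed chemical synapse class between one ordered cell pair."""

    pre: str
    post: str
    n_contacts: int
    neurotransmitter: str = UNKNOWN

    def __post_init__(self):
        if self.n_contacts < 1:
            raise ValueError(
                f"{self.pre}->{self.post}: contact count must be >= 1, "
                f"got {self.n_contacts}"
            )


@dataclass(frozen=True)
class ElectricalConnection:
    """Gap junction between an unordered cell pair (stored in sorted order)."""

    cell_a: str
    cell_b: str
    n_contacts: int

    def __post_init__(self):
        if self.n_contacts < 1:
            raise ValueError(
                f"{self.cell_a}--{self.cell_b}: contact count must be >= 1, "
                f"got {self.n_contacts}"
            )
        a, b = sorted((self.cell_a, self.cell_b))
        object.__setattr__(self, "cell_a", a)
        object.__setattr__(self, "cell_b", b)


@dataclass
class Connectome:
    """Cells plus chemical and electrical connection lists."""

    cells: dict[str, CellIdentity] = field(default_factory=dict)
    chemical: list[ChemicalConnection] = field(default_factory=list)
    electrical: list[ElectricalConnection] = field(default_factory=list)
    source_tag: str = ""

    def validate(self) -> None:
        """Check that every connection endpoint names a registered cell."""
        for c in self.chemical:
            for end in (c.pre, c.post):
                if end not in self.cells:
                    raise UnknownCellError(end)
        for e in self.electrical:
            for end in (e.cell_a, e.cell_b):
                if end not in self.cells:
                    raise UnknownCellError(end)

    @property
    def cell_names(self) -> list[str]:
        return sorted(self.cells)


# ---------------------------------------------------------------------------
# Polarity and weight rules
# ---------------------------------------------------------------------------

def classify_polarity(neurotransmitter: str) -> Polarity:
    """Inhibitory iff the (presynaptic) neurotransmitter is GABA.

    The comparison is case-insensitive; every other transmitter — including
    the UNKNOWN placeholder — is treated as excitatory, a first approximation
    that ignores receptor identity.
    """
    if str(neurotransmitter).strip().upper() == "GABA":
        return Polarity.INHIBITORY
    return Polarity.EXCITATORY


def connection_weight(n_contacts: int, baseline_conductance: float) -> float:
    """Synaptic conductance (nS) = anatomical contact count x per-contact baseline.

    With the default 0.01 nS baseline a 13-contact pair carries 0.13 nS and a
    single-contact pair 0.01 nS.
    """
    if baseline_conductance < 0:
        raise ValueError(f"baseline conductance must be >= 0, got {baseline_conductance}")
    if n_contacts < 1:
        raise ValueError(f"contact count must be >= 1, got {n_contacts}")
    return n_contacts * baseline_conductance


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    "varshney": {
        "pre": "neuron 1",
        "post": "neuron 2",
        "type": "type",
        "count": "nbr",
    },
    "wormwiring": {
        "pre": "origin",
        "post": "target",
        "type": "type",
        "count": "number of connections",
        "neurotransmitter": "neurotransmitter",
    },
}

_NT_CANONICAL = {"Gaba": "GABA", "Ach": "Acetylcholine"}


def _normalise_nt(raw: str | None) -> str:
    if raw is None or not raw.strip():
        return UNKNOWN
    if raw.strip().upper() == UNKNOWN:
        return UNKNOWN
    t = raw.strip().title()
    return _NT_CANONICAL.get(t, t)


def _infer_class(name: str) -> CellClass:
    if name.upper().startswith(MUSCLE_PREFIXES):
        return CellClass.MUSCLE
    return CellClass.INTERNEURON


def read_connectome_table(
    stream: TextIO | str,
    dialect: str = "wormwiring",
    cell_annotations: Mapping[str, tuple[CellClass, str]] | None = None,
) -> Connectome:
    """Parse a wiring-table CSV into a :class:`Connectome`.

    Parameters
    ----------
    stream
        Open text stream (or a string of CSV text) with a header row.
    dialect
        ``"varshney"`` or ``"wormwiring"`` (see module docstring for the
        expected columns of each).
    cell_annotations
        Optional per-cell ``name -> (CellClass, neurotransmitter)`` mapping,
        used when the table itself carries no per-cell information (the
        Varshney layout has no neurotransmitter column at all).

    Notes
    -----
    Reciprocal ``R``/``Rp`` rows of the Varshney layout are mirrored
    duplicates of ``S``/``Sp`` rows and are skipped.  Self-connections are
    dropped with a warning.  Duplicate rows for the same ordered pair (or
    unordered pair, for gap junctions) have their contact counts summed.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_COLUMNS)}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    cols = _DIALECT_COLUMNS[dialect]
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ConnectomeFormatError("empty stream: no header row") from None
    index = {h.strip().lower(): i for i, h in enumerate(header)}
    required = [cols["pre"], cols["post"], cols["type"], cols["count"]]
    for col in required:
        if col not in index:
            raise ConnectomeFormatError(f"missing required column {col!r}")
    nt_idx = index.get(cols.get("neurotransmitter", ""), None)

    chem: dict[tuple[str, str], list] = {}
    elec: dict[tuple[str, str], int] = {}
    cell_nt: dict[str, str] = {}
    cell_names: list[str] = []

    def register(name: str) -> None:
        if name not in cell_nt:
            cell_nt[name] = UNKNOWN
            cell_names.append(name)

    for lineno, row in enumerate(reader, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        try:
            pre = row[index[cols["pre"]]].strip()
            post = row[index[cols["post"]]].strip()
            ctype = row[index[cols["type"]]].strip()
            raw_count = row[index[cols["count"]]].strip()
        except IndexError:
            raise RowError(lineno, f"expected {len(header)} fields, got {len(row)}") from None
        try:
            count = int(raw_count)
        except ValueError:
            raise RowError(lineno, f"contact count {raw_count!r} is not an integer") from None
        if count < 1:
            raise RowError(lineno, f"contact count must be >= 1, got {count}")
        if not pre or not post:
            raise RowError(lineno, "empty cell name")

        if dialect == "varshney":
            code = ctype
            if code in ("R", "Rp"):
                continue  # mirrored duplicate of an S/Sp row elsewhere
            if code == "EJ":
                kind = "gap"
            elif code in ("S", "Sp", "NMJ"):
                kind = "chem"
            else:
                raise RowError(lineno, f"unknown connection type {code!r}")
            nt = UNKNOWN
        else:
            code = ctype.lower().replace(" ", "").replace("_", "")
            if code == "gapjunction":
                kind = "gap"
            elif code == "send":
                kind = "chem"
            else:
                raise RowError(lineno, f"unknown connection type {ctype!r}")
            nt = _normalise_nt(row[nt_idx] if nt_idx is not None and nt_idx < len(row) else None)

        if pre == post:
            logger.warning("line %d: dropping self-connection %s->%s", lineno, pre, post)
            continue
        register(pre)
        register(post)
        if kind == "gap":
            key = tuple(sorted((pre, post)))
            elec[key] = elec.get(key, 0) + count
        else:
            key = (pre, post)
            if key in chem:
                chem[key][0] += count
                if chem[key][1] == UNKNOWN:
                    chem[key][1] = nt
            else:
                chem[key] = [count, nt]
            if nt != UNKNOWN and cell_nt[pre] == UNKNOWN:
                cell_nt[pre] = nt

    cells: dict[str, CellIdentity] = {}
    for name in cell_names:
        if cell_annotations and name in cell_annotations:
            cls, nt = cell_annotations[name]
            nt = _normalise_nt(nt)
        else:
            cls, nt = _infer_class(name), cell_nt[name]
        cells[name] = CellIdentity(name=name, cell_class=cls, neurotransmitter=nt)

    conn = Connectome(
        cells=cells,
        chemical=[
            ChemicalConnection(pre, post, n, nt) for (pre, post), (n, nt) in chem.items()
        ],
        electrical=[ElectricalConnection(a, b, n) for (a, b), n in elec.items()],
        source_tag=dialect,
    )
    conn.validate()
    return conn


def write_connectome_csv(connectome: Connectome, stream: TextIO) -> None:
    """Write a wiring table in the WormWiring dialect (stable row order)."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["Origin", "Target", "Type", "Number of Connections", "Neurotransmitter"])
    for c in sorted(connectome.chemical, key=lambda c: (c.pre, c.post)):
        nt = "" if c.neurotransmitter == UNKNOWN else c.neurotransmitter
        writer.writerow([c.pre, c.post, "Send", c.n_contacts, nt])
    for e in sorted(connectome.electrical, key=lambda e: (e.cell_a, e.cell_b)):
        writer.writerow([e.cell_a, e.cell_b, "GapJunction", e.n_contacts, ""])


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def subset_connectome(c: Connectome, names: Sequence[str]) -> Connectome:
    """Restrict a connectome to the named cells.

    Keeps exactly the named cells and every connection whose two endpoints
    are both in ``names``; unknown names raise :class:`UnknownCellError`
    listing all of them.
    """
    wanted = set(names)
    unknown = sorted(wanted - set(c.cells))
    if unknown:
        raise UnknownCellError(f"unknown cells: {', '.join(unknown)}")
    return Connectome(
        cells={n: c.cells[n] for n in c.cells if n in wanted},
        chemical=[x for x in c.chemical if x.pre in wanted and x.post in wanted],
        electrical=[x for x in c.electrical if x.cell_a in wanted and x.cell_b in wanted],
        source_tag=c.source_tag,
    )


# ---------------------------------------------------------------------------
# Synthetic connectomes
# ---------------------------------------------------------------------------

def _muscle_name(i: int) -> str:
    # Cycle through the four quadrant prefixes; anatomically valid up to 96.
    return f"{MUSCLE_PREFIXES[i % 4]}{i // 4 + 1:02d}"


def generate_synthetic_connectome(
    n_neurons: int,
    n_muscles: int = 0,
    chem_density: float = 0.1,
    gap_density: float = 0.05,
    gaba_fraction: float = 0.3,
    seed: int = 0,
) -> Connectome:
    """Generate a random wiring diagram with the statistical flavour of the
    real *C. elegans* connectome.

    Each ordered neuron->cell pair is chemically connected with probability
    ``chem_density`` and each unordered neuron pair electrically with
    probability ``gap_density``; contact counts follow a geometric
    distribution with minimum 1 (most pairs share few contacts, a few share
    many).  A fraction ``gaba_fraction`` of neurons is GABAergic (hence
    presynaptically inhibitory under the polarity rule); the rest are
    cholinergic.  Muscles are never presynaptic.  Fully reproducible for a
    fixed seed.
    """
    if n_neurons < 1 or n_muscles < 0:
        raise ValueError("need n_neurons >= 1 and n_muscles >= 0")
    for name, p in (("chem_density", chem_density), ("gap_density", gap_density),
                    ("gaba_fraction", gaba_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)

    neuron_names = [f"SYN{i + 1:03d}" for i in range(n_neurons)]
    muscle_names = [_muscle_name(i) for i in range(n_muscles)]
    n_gaba = int(round(gaba_fraction * n_neurons))
    gaba_idx = set(rng.choice(n_neurons, size=n_gaba, replace=False).tolist())
    classes = rng.choice(
        [CellClass.SENSORY, CellClass.INTERNEURON, CellClass.MOTORNEURON],
        size=n_neurons, p=[0.3, 0.3, 0.4],
    )

    cells: dict[str, CellIdentity] = {}
    for i, name in enumerate(neuron_names):
        nt = "GABA" if i in gaba_idx else "Acetylcholine"
        cells[name] = CellIdentity(name=name, cell_class=classes[i], neurotransmitter=nt)
    for name in muscle_names:
        cells[name] = CellIdentity(name=name, cell_class=CellClass.MUSCLE)

    targets = neuron_names + muscle_names
    chemical: list[ChemicalConnection] = []
    for i, pre in enumerate(neuron_names):
        for post in targets:
            if pre == post:
                continue
            if rng.random() < chem_density:
                n = int(rng.geometric(0.35))
                chemical.append(ChemicalConnection(pre, post, n, cells[pre].neurotransmitter))
    electrical: list[ElectricalConnection] = []
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            if rng.random() < gap_density:
                n = int(rng.geometric(0.35))
                electrical.append(ElectricalConnection(neuron_names[i], neuron_names[j], n))

    return Connectome(cells=cells, chemical=chemical, electrical=electrical,
                      source_tag=f"synthetic(seed={seed})")
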