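"""Synapse-count connectome data model, I/O and graph queries.

The central object is :class:`ConnectomeGraph`, a directed graph of neurons
whose edges carry aggregated synapse counts and a sign (+1 excitatory,
-1 inhibitory).  Connectivity percentages throughout this package are
synapse-weighted: a population's input (output) fraction is its share of the
total synapse count onto (out of) the reference population, optionally with
the presynaptic side restricted to a brain region such as the SEZ.

The module also implements the classification of fox downstream ascending
(FDA) neurons: neurons directly postsynaptic to the fox pair that carry an
"ascending" population label, split into FDA-I (direct synapse onto PAM
dopaminergic neurons) and FDA-II (two synapses from PAM, no direct edge).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NEURON_COLUMNS = ["neuron_id", "cell_type", "populations", "side", "region"]
EDGE_COLUMNS = ["pre_id", "post_id", "synapse_count", "sign"]


class ConnectomeError(Exception):
    """Base class for connectome-table problems."""


class ConnectomeFormatError(ConnectomeError):
    """A table is malformed (missing column, bad enum value, bad count)."""


class ConnectomeIntegrityError(ConnectomeError):
    """Tables are individually well-formed but mutually inconsistent."""


class SelectorError(ConnectomeError):
    """A population selector resolved to an empty neuron set."""


class UndefinedFractionError(ConnectomeError):
    """A connectivity fraction has a zero denominator."""


class Side(str, enum.Enum):
    LEFT = "L"
    RIGHT = "R"
    UNKNOWN = "U"


@dataclass(frozen=True)
class NeuronRecord:
    """One neuron: identity, cell type, population labels, laterality, region."""

    neuron_id: str
    cell_type: str
    populations: frozenset = frozenset()
    side: Side = Side.UNKNOWN
    region: str = ""

    def __post_init__(self):
        object.__setattr__(self, "populations", frozenset(self.populations))
        object.__setattr__(self, "side", Side(self.side))


@dataclass(frozen=True)
class EdgeRecord:
    """One aggregated connection pre -> post with a synapse count and sign."""

    pre_id: str
    post_id: str
    synapse_count: int
    sign: int = 1

    def __post_init__(self):
        if self.synapse_count < 1:
            raise ConnectomeFormatError(
                f"synapse_count must be >= 1, got {self.synapse_count} "
                f"for {self.pre_id}->{self.post_id}"
            )
        if self.sign not in (1, -1):
            raise ConnectomeFormatError(
                f"sign must be +1 or -1, got {self.sign} "
                f"for {self.pre_id}->{self.post_id}"
            )


class ConnectomeGraph:
    """Directed graph of neurons with synapse-count-weighted signed edges.

    At most one edge exists per ordered (pre, post) pair; duplicate input
    rows are summed at construction.  Backed by :class:`networkx.DiGraph`.
    """

    def __init__(self, neurons: Iterable[NeuronRecord] = (),
                 edges: Iterable[EdgeRecord] = ()):
        self._g = nx.DiGraph()
        self._neurons: dict[str, NeuronRecord] = {}
        for n in neurons:
            self.add_neuron(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -----------------------------------------------------

    def add_neuron(self, rec: NeuronRecord) -> None:
        if rec.neuron_id in self._neurons:
            raise ConnectomeIntegrityError(f"duplicate neuron id {rec.neuron_id!r}")
        self._neurons[rec.neuron_id] = rec
        self._g.add_node(rec.neuron_id)

    def add_edge(self, rec: EdgeRecord) -> None:
        for endpoint in (rec.pre_id, rec.post_id):
            if endpoint not in self._neurons:
                raise ConnectomeIntegrityError(
                    f"edge {rec.pre_id}->{rec.post_id} references unknown "
                    f"neuron {endpoint!r}"
                )
        if self._g.has_edge(rec.pre_id, rec.post_id):
            data = self._g[rec.pre_id][rec.post_id]
            if data["sign"] != rec.sign:
                raise ConnectomeIntegrityError(
                    f"conflicting signs for duplicate edge "
                    f"{rec.pre_id}->{rec.post_id}"
                )
            data["synapse_count"] += rec.synapse_count
        else:
            self._g.add_edge(rec.pre_id, rec.post_id,
                             synapse_count=rec.synapse_count, sign=rec.sign)

    # -- access -----------------------------------------------------------

    @property
    def neuron_ids(self) -> list:
        return sorted(self._neurons)

    def neuron(self, neuron_id: str) -> NeuronRecord:
        return self._neurons[neuron_id]

    @property
    def n_neurons(self) -> int:
        return len(self._neurons)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[EdgeRecord]:
        for pre, post, data in self._g.edges(data=True):
            yield EdgeRecord(pre, post, data["synapse_count"], data["sign"])

    def in_edges(self, neuron_id: str) -> Iterator[EdgeRecord]:
        for pre, post, data in self._g.in_edges(neuron_id, data=True):
            yield EdgeRecord(pre, post, data["synapse_count"], data["sign"])

    def out_edges(self, neuron_id: str) -> Iterator[EdgeRecord]:
        for pre, post, data in self._g.out_edges(neuron_id, data=True):
            yield EdgeRecord(pre, post, data["synapse_count"], data["sign"])

    def successors(self, neuron_id: str) -> set:
        return set(self._g.successors(neuron_id))

    def predecessors(self, neuron_id: str) -> set:
        return set(self._g.predecessors(neuron_id))

    def has_edge(self, pre_id: str, post_id: str) -> bool:
        return self._g.has_edge(pre_id, post_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectomeGraph):
            return NotImplemented
        return (self._neurons == other._neurons
                and sorted(self.edges(), key=lambda e: (e.pre_id, e.post_id))
                == sorted(other.edges(), key=lambda e: (e.pre_id, e.post_id)))


class SelectorMode(str, enum.Enum):
    BY_CELL_TYPE = "by_cell_type"
    BY_POPULATION_LABEL = "by_population_label"
    BY_ID_LIST = "by_id_list"


@dataclass(frozen=True)
class PopulationSelector:
    """Resolves to a non-empty neuron set by cell type, label, or explicit ids."""

    mode: SelectorMode
    value: object
    side_filter: Side | None = None

    def resolve(self, graph: ConnectomeGraph) -> frozenset:
        mode = SelectorMode(self.mode)
        if mode is SelectorMode.BY_CELL_TYPE:
            hit = {i for i in graph.neuron_ids
                   if graph.neuron(i).cell_type == self.value}
        elif mode is SelectorMode.BY_POPULATION_LABEL:
            hit = {i for i in graph.neuron_ids
                   if self.value in graph.neuron(i).populations}
        else:
            missing = [i for i in self.value if i not in graph._neurons]
            if missing:
                raise SelectorError(f"unknown neuron ids {missing}")
            hit = set(self.value)
        if self.side_filter is not None:
            hit = {i for i in hit if graph.neuron(i).side == Side(self.side_filter)}
        if not hit:
            raise SelectorError(f"selector {self} resolved to an empty set")
        return frozenset(hit)


def by_cell_type(cell_type: str, side: Side | None = None) -> PopulationSelector:
    return PopulationSelector(SelectorMode.BY_CELL_TYPE, cell_type, side)


def by_population(label: str, side: Side | None = None) -> PopulationSelector:
    return PopulationSelector(SelectorMode.BY_POPULATION_LABEL, label, side)


def by_ids(ids: Iterable[str], side: Side | None = None) -> PopulationSelector:
    return PopulationSelector(SelectorMode.BY_ID_LIST, tuple(ids), side)


def _as_set(graph: ConnectomeGraph, sel) -> frozenset:
    if isinstance(sel, PopulationSelector):
        return sel.resolve(graph)
    out = frozenset(sel)
    if not out:
        raise SelectorError("empty neuron set")
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_connectome(neuron_table, edge_table) -> ConnectomeGraph:
    """Read the two-CSV connectome dialect into a :class:`ConnectomeGraph`.

    ``neuron_table`` columns: neuron_id, cell_type, populations (";"-separated),
    side (L/R/U), region.  ``edge_table`` columns: pre_id, post_id,
    synapse_count, and optionally sign (+1/-1, defaulting to +1 with a logged
    warning for rows where it is missing).  Duplicate (pre, post) rows are
    summed into one edge.
    """
    ndf = pd.read_csv(neuron_table, dtype=str, keep_default_na=False)
    for col in NEURON_COLUMNS:
        if col not in ndf.columns:
            raise ConnectomeFormatError(
                f"neuron table is missing required column {col!r}")
    edf = pd.read_csv(edge_table, dtype=str, keep_default_na=False)
    for col in ("pre_id", "post_id", "synapse_count"):
        if col not in edf.columns:
            raise ConnectomeFormatError(
                f"edge table is missing required column {col!r}")

    graph = ConnectomeGraph()
    for row in ndf.itertuples(index=False):
        pops = frozenset(p for p in str(row.populations).split(";") if p)
        try:
            side = Side(row.side)
        except ValueError:
            raise ConnectomeFormatError(
                f"bad side {row.side!r} for neuron {row.neuron_id!r}; "
                f"expected one of L, R, U") from None
        graph.add_neuron(NeuronRecord(row.neuron_id, row.cell_type, pops,
                                      side, row.region))

    have_sign = "sign" in edf.columns
    n_defaulted = 0
    for row in edf.itertuples(index=False):
        try:
            count = int(row.synapse_count)
        except ValueError:
            raise ConnectomeFormatError(
                f"non-integer synapse_count {row.synapse_count!r} for edge "
                f"{row.pre_id}->{row.post_id}") from None
        raw_sign = getattr(row, "sign", "") if have_sign else ""
        if raw_sign in ("", None):
            sign = 1
            n_defaulted += 1
        else:
            try:
                sign = int(raw_sign)
            except ValueError:
                raise ConnectomeFormatError(
                    f"bad sign {raw_sign!r} for edge {row.pre_id}->{row.post_id}"
                ) from None
        graph.add_edge(EdgeRecord(row.pre_id, row.post_id, count, sign))
    if n_defaulted:
        logger.warning("edge table: %d edges without a sign defaulted to "
                       "excitatory (+1)", n_defaulted)
    return graph


def write_tables(graph: ConnectomeGraph, directory) -> tuple[Path, Path]:
    """Write a graph to ``neurons.csv`` and ``edges.csv`` in ``directory``.

    Rows are sorted by id so repeated exports of the same graph are
    byte-identical; composes with :func:`load_connectome` as the identity.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nrows = [
        {
            "neuron_id": n.neuron_id,
            "cell_type": n.cell_type,
            "populations": ";".join(sorted(n.populations)),
            "side": n.side.value,
            "region": n.region,
        }
        for n in (graph.neuron(i) for i in graph.neuron_ids)
    ]
    erows = sorted(
        ({"pre_id": e.pre_id, "post_id": e.post_id,
          "synapse_count": e.synapse_count, "sign": e.sign}
         for e in graph.edges()),
        key=lambda r: (r["pre_id"], r["post_id"]),
    )
    neuron_path = directory / "neurons.csv"
    edge_path = directory / "edges.csv"
    pd.DataFrame(nrows, columns=NEURON_COLUMNS).to_csv(neuron_path, index=False)
    pd.DataFrame(erows, columns=EDGE_COLUMNS).to_csv(edge_path, index=False)
    return neuron_path, edge_path


# ---------------------------------------------------------------------------
# graph queries
# ---------------------------------------------------------------------------

def input_fraction(graph: ConnectomeGraph, target, source,
                   region_filter: str | None = None) -> float:
    """Percentage of synaptic input to ``target`` contributed by ``source``.

    Synapse-count weighted: 100 x (synapses from source neurons onto target
    neurons) / (all synapses onto target neurons).  ``region_filter``
    restricts the presynaptic neurons entering the denominator (and hence the
    numerator) to those whose region field matches, e.g. "SEZ".
    """
    tgt = _as_set(graph, target)
    src = _as_set(graph, source)
    denom = num = 0
    for t in tgt:
        for e in graph.in_edges(t):
            if region_filter is not None and \
                    graph.neuron(e.pre_id).region != region_filter:
                continue
            denom += e.synapse_count
            if e.pre_id in src:
                num += e.synapse_count
    if denom == 0:
        raise UndefinedFractionError(
            f"no synaptic input onto target set (region={region_filter!r})")
    return 100.0 * num / denom


def output_fraction(graph: ConnectomeGraph, source, target,
                    within=None) -> float:
    """Percentage of ``source``'s synaptic output received by ``target``.

    Mirrors :func:`input_fraction` with the outgoing synapse count of
    ``source`` as denominator.  ``within``, if given, restricts the
    denominator to output synapses onto that neuron set (e.g. computing a
    cell type's share of fox output *to FDA neurons* rather than of total
    fox output).
    """
    src = _as_set(graph, source)
    tgt = _as_set(graph, target)
    wit = None if within is None else _as_set(graph, within)
    denom = num = 0
    for s in src:
        for e in graph.out_edges(s):
            if wit is not None and e.post_id not in wit:
                continue
            denom += e.synapse_count
            if e.post_id in tgt:
                num += e.synapse_count
    if denom == 0:
        raise UndefinedFractionError("source set has no synaptic output "
                                     "(after the 'within' restriction)")
    return 100.0 * num / denom


def classify_fda(graph: ConnectomeGraph, fox, pam,
                 ascending_flag: str = "ascending") -> tuple[frozenset, frozenset]:
    """Split fox's direct ascending targets into FDA-I and FDA-II.

    Candidates are neurons directly postsynaptic to the fox set that carry
    the ``ascending_flag`` population label.  FDA-I have a direct edge onto
    the PAM set; FDA-II reach PAM in exactly two hops (any intermediate
    neuron is allowed) without a direct edge.  Candidates with neither a
    direct edge nor a two-hop path are in neither class.
    """
    fox_set = _as_set(graph, fox)
    pam_set = _as_set(graph, pam)
    down = set().union(*(graph.successors(f) for f in fox_set)) - fox_set
    candidates = {n for n in down
                  if ascending_flag in graph.neuron(n).populations}
    fda1, fda2 = set(), set()
    for n in candidates:
        succ = graph.successors(n)
        if succ & pam_set:
            fda1.add(n)
        elif any(graph.successors(m) & pam_set for m in succ):
            fda2.add(n)
    return frozenset(fda1), frozenset(fda2)


def pair_count(graph: ConnectomeGraph, pop) -> int:
    """Number of bilateral cell-type pairs in a neuron set.

    A cell type counts once if the set contains at least one left-side and
    one right-side member with that exact cell_type string; unilateral cell
    types contribute zero.
    """
    ids = _as_set(graph, pop)
    sides_by_type: dict[str, set] = {}
    for i in ids:
        rec = graph.neuron(i)
        sides_by_type.setdefault(rec.cell_type, set()).add(rec.side)
    return sum(1 for sides in sides_by_type.values()
               if Side.LEFT in sides and Side.RIGHT in sides)
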