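"""Molecular graphs, degree-pair edge partitions and compound records.

The hydrogen-suppressed molecular graph of a compound has heavy atoms as
vertices and covalent bonds as edges.  Every degree-based topological index
used downstream depends on the graph only through its *degree-pair edge
partition*: the multiset of unordered endpoint-degree pairs (du, dv) with a
count per pair.  This module provides the graph and partition containers,
derivation of a partition from a graph, validation, and JSON / edge-list IO.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "MolecularGraph",
    "DegreePair",
    "EdgePartition",
    "CompoundRecord",
    "GraphValidationError",
    "CompoundParseError",
    "degrees",
    "edge_partition",
    "validate_partition",
    "load_compounds",
    "save_compounds",
    "read_edgelist",
]


class GraphValidationError(ValueError):
    """A graph or partition violates a structural invariant."""


class CompoundParseError(ValueError):
    """A compound file does not conform to the expected schema."""


@dataclass(frozen=True, order=True)
class DegreePair:
    """Unordered endpoint-degree pair of an edge, stored with du <= dv."""

    du: int
    dv: int

    def __post_init__(self) -> None:
        if self.du < 1 or self.dv < 1:
            raise GraphValidationError(
                f"degrees must be positive, got ({self.du}, {self.dv})"
            )
        if self.du > self.dv:
            lo, hi = self.dv, self.du
            object.__setattr__(self, "du", lo)
            object.__setattr__(self, "dv", hi)

    @classmethod
    def of(cls, a: int, b: int) -> "DegreePair":
        return cls(min(a, b), max(a, b))


class EdgePartition:
    """Multiset of degree pairs with positive counts; sole input of every index.

    Parameters
    ----------
    entries
        Mapping from (du, dv) pairs (any order) or :class:`DegreePair` to a
        positive edge count.  Pairs presented in either order are canonicalised
        and merged.
    """

    def __init__(self, entries: Mapping) -> None:
        tally: Counter[DegreePair] = Counter()
        for key, count in entries.items():
            pair = key if isinstance(key, DegreePair) else DegreePair.of(*key)
            if int(count) != count or count <= 0:
                raise GraphValidationError(
                    f"count for {pair} must be a positive integer, got {count!r}"
                )
            tally[pair] += int(count)
        if not tally:
            raise GraphValidationError("edge partition must contain at least one edge")
        self._entries: dict[DegreePair, int] = dict(sorted(tally.items()))

    @property
    def entries(self) -> dict[DegreePair, int]:
        return dict(self._entries)

    @property
    def m(self) -> int:
        """Total edge count."""
        return sum(self._entries.values())

    def items(self):
        return self._entries.items()

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgePartition) and self._entries == other._entries

    def __repr__(self) -> str:
        inner = ", ".join(f"({p.du},{p.dv}): {c}" for p, c in self._entries.items())
        return f"EdgePartition({{{inner}}})"

    def to_records(self) -> list[dict]:
        return [
            {"du": p.du, "dv": p.dv, "count": c} for p, c in self._entries.items()
        ]


@dataclass
class MolecularGraph:
    """Simple connected undirected graph of heavy atoms.

    Vertices are opaque string labels; an optional ``elements`` mapping carries
    informational element symbols.  Construction validates simplicity (no
    self-loops or duplicate edges), connectivity and the absence of isolated
    vertices.
    """

    edges: list[tuple[str, str]]
    elements: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[frozenset] = set()
        for u, v in self.edges:
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphValidationError(f"duplicate edge {{{u!r}, {v!r}}}")
            seen.add(key)
        g = self.to_networkx()
        if g.number_of_nodes() == 0:
            raise GraphValidationError("graph has no vertices")
        if not nx.is_connected(g):
            raise GraphValidationError("graph is not connected")
        isolated = [v for v, d in g.degree() if d == 0]
        if isolated:
            raise GraphValidationError(f"isolated vertex {isolated[0]!r}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    @property
    def vertex_ids(self) -> list[str]:
        return sorted({v for e in self.edges for v in e})

    @property
    def m(self) -> int:
        return len(self.edges)

    def relabeled(self, mapping: Mapping[str, str]) -> "MolecularGraph":
        """Isomorphic copy under a vertex-label permutation."""
        return MolecularGraph(
            edges=[(mapping[u], mapping[v]) for u, v in self.edges],
            elements={mapping[v]: e for v, e in self.elements.items()},
        )


def degrees(graph: MolecularGraph) -> dict[str, int]:
    """Vertex -> degree map; degrees sum to twice the edge count."""
    return dict(graph.to_networkx().degree())


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Tally the canonical (min(du,dv), max(du,dv)) pair of every edge."""
    deg = degrees(graph)
    tally: Counter[DegreePair] = Counter()
    for u, v in graph.edges:
        tally[DegreePair.of(deg[u], deg[v])] += 1
    return EdgePartition(tally)


def validate_partition(partition: EdgePartition) -> tuple[int, int]:
    """Return (m, Σ count·(du+dv)) after checking partition invariants."""
    m = 0
    degree_sum = 0
    for pair, count in partition.items():
        if count <= 0:
            raise GraphValidationError(f"non-positive count {count} for {pair}")
        if pair.du <= 0 or pair.dv <= 0:
            raise GraphValidationError(f"non-positive degree in {pair}")
        m += count
        degree_sum += count * (pair.du + pair.dv)
    return m, degree_sum


@dataclass
class CompoundRecord:
    """A named compound: edge partition, optional graph, and two properties.

    ``melting_point`` is in degrees Celsius; ``formula_weight`` is the molar
    mass (unitless here).  If a graph is supplied its derived partition must
    equal the stored one.
    """

    name: str
    partition: EdgePartition
    melting_point: float
    formula_weight: float
    graph: MolecularGraph | None = None

    def __post_init__(self) -> None:
        for label, value in (
            ("melting_point", self.melting_point),
            ("formula_weight", self.formula_weight),
        ):
            if not math.isfinite(value):
                raise GraphValidationError(f"{label} of {self.name!r} is not finite")
        if self.graph is not None and edge_partition(self.graph) != self.partition:
            raise GraphValidationError(
                f"graph-derived partition of {self.name!r} does not match the "
                "stored partition"
            )


def _record_to_json(record: CompoundRecord) -> dict:
    obj: dict = {
        "name": record.name,
        "partition": record.partition.to_records(),
        "properties": {
            "melting_point_C": record.melting_point,
            "formula_weight": record.formula_weight,
        },
    }
    if record.graph is not None:
        obj["graph_edges"] = [list(e) for e in record.graph.edges]
    return obj


def _record_from_json(obj: dict, index: int) -> CompoundRecord:
    try:
        name = obj["name"]
        part_rows = obj["partition"]
        props = obj["properties"]
        mp = float(props["melting_point_C"])
        fw = float(props["formula_weight"])
        partition = EdgePartition(
            {(row["du"], row["dv"]): row["count"] for row in part_rows}
        )
    except (KeyError, TypeError) as exc:
        raise CompoundParseError(f"record {index}: malformed compound object ({exc})")
    graph = None
    if "graph_edges" in obj:
        graph = MolecularGraph(edges=[tuple(e) for e in obj["graph_edges"]])
    return CompoundRecord(
        name=name,
        partition=partition,
        melting_point=mp,
        formula_weight=fw,
        graph=graph,
    )


def load_compounds(path: str | Path) -> list[CompoundRecord]:
    """Load compound records from a JSON file (list of compound objects)."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise CompoundParseError("compound file must contain a JSON list")
    if not data:
        raise CompoundParseError("compound file contains no records")
    return [_record_from_json(obj, i) for i, obj in enumerate(data)]


def save_compounds(records: Sequence[CompoundRecord], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_record_to_json(r) for r in records], indent=1) + "\n"
    )


def read_edgelist(path: str | Path) -> MolecularGraph:
    """Read a plain-text edge list: one edge per line, two whitespace-separated
    vertex labels; blank lines and ``#`` comments ignored."""
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CompoundParseError(
                f"line {lineno}: expected two vertex labels, got {line!r}"
            )
        edges.append((parts[0], parts[1]))
    return MolecularGraph(edges=edges)
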