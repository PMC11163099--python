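"""Synthetic molecular-graph-like data with the statistical structure the
QSPR analysis assumes.

Graphs emulate hydrogen-suppressed heavy-atom skeletons: connected, simple,
every degree between 1 and a cap (default 4, the maximum seen in the study
compounds).  The target property of each synthetic compound follows the same
generating model the regression fits,

    P = A + B·TI + ε,   ε ~ Normal(0, σ²),

while the other property is drawn independently of structure so that its
correlations with every index are weak — the regime the study reports for
formula weight.  All randomness flows from a single integer seed; a given
configuration reproduces bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import CompoundRecord, MolecularGraph, edge_partition
from .indices import INDEX_IDS, index_value

__all__ = ["SimConfig", "random_molecular_graph", "synth_compounds"]


@dataclass
class SimConfig:
    """Configuration of a synthetic compound set.

    ``A``/``B``/``sigma`` define the linear generating model of the target
    property on ``index``; ``other_mean``/``other_sd`` the structure-free
    distribution of the second property.
    """

    n_compounds: int = 5
    n_vertices_range: tuple[int, int] = (18, 30)
    max_degree: int = 4
    index: str = "M1"
    property: str = "melting_point"
    A: float = 400.0
    B: float = -1.5
    sigma: float = 5.0
    other_mean: float = 360.0
    other_sd: float = 35.0
    extra_edge_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        if self.n_vertices_range[0] < 2 or self.n_vertices_range[0] > self.n_vertices_range[1]:
            raise ValueError("invalid n_vertices_range")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.index not in INDEX_IDS:
            raise KeyError(f"unknown index {self.index!r}")


def random_molecular_graph(
    n_vertices: int,
    max_degree: int = 4,
    seed: int | np.random.Generator = 0,
    extra_edge_prob: float = 0.15,
) -> MolecularGraph:
    """Connected simple graph with every degree in [1, max_degree].

    Grows a uniform-attachment random spanning tree respecting the degree cap,
    then adds random extra (ring-closing) edges while the cap allows.
    Deterministic for a fixed integer seed.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if max_degree < 2:
        raise ValueError("max_degree must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    labels = [f"v{i}" for i in range(n_vertices)]
    degree = dict.fromkeys(labels, 0)
    edges: list[tuple[str, str]] = []
    present: set[frozenset] = set()

    def add(u: str, v: str) -> None:
        edges.append((u, v))
        present.add(frozenset((u, v)))
        degree[u] += 1
        degree[v] += 1

    # spanning tree: attach each new vertex to a uniformly chosen vertex
    # with spare capacity
    for i in range(1, n_vertices):
        candidates = [v for v in labels[:i] if degree[v] < max_degree]
        if not candidates:
            raise ValueError(
                f"cannot attach vertex {i}: degree cap {max_degree} saturated"
            )
        add(candidates[int(rng.integers(len(candidates)))], labels[i])

    # ring-closing extra edges among residual-capacity vertices
    n_candidates = max(1, int(round(extra_edge_prob * n_vertices)))
    for _ in range(n_candidates):
        spare = [v for v in labels if degree[v] < max_degree]
        if len(spare) < 2:
            break
        i, j = rng.choice(len(spare), size=2, replace=False)
        u, v = spare[int(i)], spare[int(j)]
        if frozenset((u, v)) not in present:
            add(u, v)

    return MolecularGraph(edges=edges)


def synth_compounds(config: SimConfig) -> list[CompoundRecord]:
    """Generate ``config.n_compounds`` records under the linear property model."""
    rng = np.random.default_rng(config.seed)
    records: list[CompoundRecord] = []
    lo, hi = config.n_vertices_range
    for k in range(config.n_compounds):
        n_v = int(rng.integers(lo, hi + 1))
        graph = random_molecular_graph(
            n_v, config.max_degree, rng, config.extra_edge_prob
        )
        partition = edge_partition(graph)
        ti = index_value(partition, config.index)
        target = config.A + config.B * ti + rng.normal(0.0, config.sigma)
        other = rng.normal(config.other_mean, config.other_sd)
        props = {
            config.property: target,
            ("formula_weight" if config.property == "melting_point" else "melting_point"): other,
        }
        records.append(
            CompoundRecord(
                name=f"synthetic-{k + 1}",
                partition=partition,
                melting_point=props["melting_point"],
                formula_weight=props["formula_weight"],
                graph=graph,
            )
        )
    return records
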