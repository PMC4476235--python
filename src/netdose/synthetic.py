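"""Seeded generators for random pathway networks and affinity tables.

The network generator emulates signal-transduction topology: a layered
directed acyclic graph flowing from source nodes through intermediate
layers to a single exit, with optional cross-layer shortcut edges.  An
Erdos-Renyi graph would not do here — network flux is meaningless without
directional flow into an exit node.  All randomness is driven by the seed
in the spec, so generated fixtures are reproducible by contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inhibition import AffinityRecord, AffinityTable
from .network import PathwayNetwork

__all__ = [
    "SyntheticSpec",
    "random_pathway",
    "random_affinities",
    "synthetic_docking_table",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic system."""

    n_nodes: int = 12
    n_edges: int = 18
    n_targets: int = 3
    n_compounds: int = 2
    pki_range: tuple[float, float] = (5.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("need at least n_nodes - 1 edges to reach the exit")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError(
                f"{self.n_edges} edges infeasible for an acyclic {self.n_nodes}-node graph"
            )
        if self.pki_range[0] > self.pki_range[1]:
            raise ValueError("pki_range must be (low, high)")


def random_pathway(spec: SyntheticSpec) -> PathwayNetwork:
    """A random layered DAG with every node on some path to the exit."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    names = [f"N{i:02d}" for i in range(n - 1)] + ["EXIT"]
    # topological order: node i may only feed nodes j > i; EXIT is last
    edges: set[tuple[int, int]] = set()
    # backbone guaranteeing reachability: each node feeds one later node
    for i in range(n - 1):
        j = int(rng.integers(i + 1, n))
        edges.add((i, j))
    # densify with random forward shortcuts
    while len(edges) < spec.n_edges:
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        edges.add((i, j))
    return PathwayNetwork.from_edges(
        sorted((names[i], names[j]) for i, j in edges), exit_node="EXIT"
    )


def random_affinities(net: PathwayNetwork, spec: SyntheticSpec) -> AffinityTable:
    """Random compound->target pKi records over the network's enzymes.

    Targets are drawn from nodes with outgoing edges (a terminal node has
    no edge to penalise); each compound receives 1..n_targets records with
    pKi uniform over ``pki_range``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sources = sorted({e.source for e in net.edges})
    if spec.n_targets > len(sources):
        raise ValueError(
            f"n_targets={spec.n_targets} exceeds the {len(sources)} candidate targets"
        )
    records: list[AffinityRecord] = []
    for c in range(spec.n_compounds):
        k = int(rng.integers(1, spec.n_targets + 1))
        targets = rng.choice(sources, size=k, replace=False)
        for t in targets:
            pki = float(rng.uniform(*spec.pki_range))
            records.append(AffinityRecord(f"C{c:02d}", str(t), pki))
    return AffinityTable(records)


def synthetic_docking_table(
    targets: list[str] | tuple[str, ...],
    n_compounds: int = 5,
    pki_range: tuple[float, float] = (4.0, 5.5),
    seed: int = 0,
) -> AffinityTable:
    """Synthetic stand-in for a docking campaign's affinity table.

    Emulates scoring every compound against every listed target, the way a
    docking run produces one pKi per compound-target pair.  Defaults mimic
    weak-to-moderate natural-product inhibitors: pKi uniform over
    [4, 5.5], i.e. K_I between ~3 and 100 uM.
    """
    rng = np.random.default_rng(seed)
    records = [
        AffinityRecord(f"cmpd{c + 1}", str(t), float(rng.uniform(*pki_range)))
        for c in range(n_compounds)
        for t in targets
    ]
    return AffinityTable(records)
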