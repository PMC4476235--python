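"""Independent brute-force oracles for the shortest-path machinery.

Hand-written Floyd-Warshall and exhaustive simple-path enumeration, kept
deliberately free of networkx so they can cross-check the Dijkstra-based
implementation.
"""

from __future__ import annotations

import math
from itertools import permutations

from netdose import PathwayNetwork


def floyd_warshall(net: PathwayNetwork) -> dict[tuple[str, str], float]:
    """All-pairs shortest paths by plain O(n^3) Floyd-Warshall."""
    nodes = list(net.nodes)
    dist = {(i, j): (0.0 if i == j else math.inf) for i in nodes for j in nodes}
    for e in net.edges:
        dist[(e.source, e.target)] = min(dist[(e.source, e.target)], e.ev)
    for k in nodes:
        for i in nodes:
            dik = dist[(i, k)]
            if math.isinf(dik):
                continue
            for j in nodes:
                alt = dik + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return {(i, j): d for (i, j), d in dist.items() if i != j}


def enumerate_paths(net: PathwayNetwork) -> dict[tuple[str, str], float]:
    """Shortest paths by exhaustive simple-path enumeration (tiny graphs only)."""
    nodes = list(net.nodes)
    weight = {(e.source, e.target): e.ev for e in net.edges}
    best = {(i, j): math.inf for i in nodes for j in nodes if i != j}
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            inner = [n for n in nodes if n not in (i, j)]
            for r in range(len(inner) + 1):
                for mids in permutations(inner, r):
                    path = (i, *mids, j)
                    total = 0.0
                    for u, v in zip(path, path[1:]):
                        w = weight.get((u, v))
                        if w is None:
                            break
                        total += w
                    else:
                        best[(i, j)] = min(best[(i, j)], total)
    return best


def ne_nf_bruteforce(net: PathwayNetwork) -> tuple[float, float]:
    """NE and NF recomputed from the Floyd-Warshall distances."""
    dist = floyd_warshall(net)
    ne = sum(1.0 / d for d in dist.values() if math.isfinite(d))
    nf = sum(
        1.0 / d
        for (i, j), d in dist.items()
        if j == net.exit_node and math.isfinite(d)
    )
    return ne, nf
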