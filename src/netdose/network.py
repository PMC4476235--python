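"""Directed pathway-network data model and file I/O.

A pathway is modelled as a directed graph whose nodes are proteins, small
molecules or abstract processes, with one designated *exit* node (the
biological readout, e.g. PGE2).  Every edge carries a positive *edge value*
(EV) representing the resistance of that signalling step: 1 for an
unperturbed step, growing when the upstream protein is inhibited.

Supported file dialects:

* TSV — header ``source<TAB>target<TAB>ev``; the ``ev`` column is optional
  on read (default 1).
* SIF — ``source<TAB>interaction<TAB>target``; the interaction token is
  ignored on read and written as ``activates``.
* GraphML — node attributes ``kind`` and ``label``, edge attribute ``ev``,
  graph attribute ``exit_node``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

__all__ = [
    "EV_DEFAULT",
    "EV_BOUND",
    "EV_CEIL",
    "NODE_KINDS",
    "PathwayNode",
    "PathwayEdge",
    "PathwayNetwork",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "save_network",
]

#: Edge value of an unperturbed signalling step.
EV_DEFAULT = 1.0
#: Nominal maximal resistance, 1/(1 - 0.995): a fully potent inhibitor is
#: assumed to block 99.5 % of its target's activity.  Used for the
#: all-edges-at-minimum connectivity bounds.
EV_BOUND = 200.0
#: Hard ceiling of the edge-value map 10^(2.303*fa) at fa = 1.  Slightly
#: above EV_BOUND; see docs/methods.md for why both constants exist.
EV_CEIL = 10.0 ** 2.303

NODE_KINDS = ("protein", "small_molecule", "process")

_EV_TOL = 1e-9


class NetworkFormatError(ValueError):
    """A pathway file could not be parsed in the requested dialect."""


class NetworkValidationError(ValueError):
    """A pathway network violates a structural invariant."""


@dataclass(frozen=True)
class PathwayNode:
    """A molecular entity or process in the pathway."""

    id: str
    label: str = ""
    kind: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be non-empty")
        if self.kind not in NODE_KINDS:
            raise NetworkValidationError(
                f"node {self.id!r}: kind {self.kind!r} not in {NODE_KINDS}"
            )
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass
class PathwayEdge:
    """A directed signalling step with resistance ``ev`` (dimensionless)."""

    source: str
    target: str
    ev: float = EV_DEFAULT


@dataclass
class PathwayNetwork:
    """A validated directed pathway network with a designated exit node."""

    nodes: dict[str, PathwayNode]
    edges: list[PathwayEdge]
    exit_node: str

    def __post_init__(self) -> None:
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]] | Iterable[PathwayEdge],
        exit_node: str,
        kinds: Mapping[str, str] | None = None,
        labels: Mapping[str, str] | None = None,
    ) -> "PathwayNetwork":
        """Build a network from (source, target) pairs; all EVs default to 1."""
        kinds = dict(kinds or {})
        labels = dict(labels or {})
        edge_objs: list[PathwayEdge] = []
        node_ids: list[str] = []
        for e in edges:
            if not isinstance(e, PathwayEdge):
                e = PathwayEdge(*e)
            edge_objs.append(e)
            for nid in (e.source, e.target):
                if nid not in node_ids:
                    node_ids.append(nid)
        if exit_node not in node_ids:
            node_ids.append(exit_node)
        nodes = {
            nid: PathwayNode(nid, labels.get(nid, nid), kinds.get(nid, "protein"))
            for nid in node_ids
        }
        return cls(nodes=nodes, edges=edge_objs, exit_node=exit_node)

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        if self.exit_node not in self.nodes:
            raise NetworkValidationError(
                f"exit node {self.exit_node!r} is not in the node set"
            )
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} references undeclared "
                        f"node {endpoint!r}"
                    )
            key = (e.source, e.target)
            if key in seen:
                raise NetworkValidationError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)
            if not (EV_DEFAULT - _EV_TOL <= e.ev <= EV_CEIL + _EV_TOL):
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: ev={e.ev} outside "
                    f"[{EV_DEFAULT}, {EV_CEIL:.3f}]"
                )
        if self.edges and not any(
            nx.has_path(self.to_networkx(), n, self.exit_node)
            for n in self.nodes
            if n != self.exit_node
        ):
            raise NetworkValidationError(
                f"no node can reach the exit node {self.exit_node!r}"
            )

    # -- conversions ----------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Edge-weighted ``networkx`` view (weight attribute ``ev``)."""
        g = nx.DiGraph(exit_node=self.exit_node)
        for n in self.nodes.values():
            g.add_node(n.id, label=n.label, kind=n.kind)
        for e in self.edges:
            g.add_edge(e.source, e.target, ev=e.ev)
        return g

    def copy(self) -> "PathwayNetwork":
        return PathwayNetwork(
            nodes=dict(self.nodes),
            edges=[replace(e) for e in self.edges],
            exit_node=self.exit_node,
        )

    def with_uniform_ev(self, ev: float) -> "PathwayNetwork":
        net = self.copy()
        for e in net.edges:
            e.ev = ev
        return net

    def out_edges(self, node_id: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.source == node_id]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# -- file I/O -----------------------------------------------------------------

Format = Literal["sif", "tsv", "graphml"]


def _detect_format(path: Path) -> Format:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("sif", "tsv", "graphml"):
        return suffix  # type: ignore[return-value]
    raise NetworkFormatError(
        f"cannot infer format from {path.name!r}; pass format= explicitly"
    )


def load_network(
    path: str | Path,
    format: Format | None = None,
    exit_node: str | None = None,
) -> PathwayNetwork:
    """Read a pathway network from ``path``.

    ``exit_node`` must be supplied for SIF/TSV (they carry no graph
    attributes); GraphML files written by :func:`save_network` embed it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "graphml":
        return _load_graphml(path, exit_node)
    if fmt in ("sif", "tsv"):
        if exit_node is None:
            raise NetworkValidationError(f"{fmt} input requires an explicit exit_node")
        return _load_tabular(path, fmt, exit_node)
    raise NetworkFormatError(f"unknown format {fmt!r}")


def _load_tabular(path: Path, fmt: Format, exit_node: str) -> PathwayNetwork:
    edges: list[PathwayEdge] = []
    declared: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "tsv" and lineno == 1 and fields[0] == "source":
                continue  # header
            if fmt == "sif":
                if len(fields) == 1:
                    declared.append(fields[0].strip())
                    continue
                if len(fields) < 3:
                    raise NetworkFormatError(
                        f"{path.name}:{lineno}: SIF line needs "
                        f"source<TAB>interaction<TAB>target"
                    )
                src, tgt, ev = fields[0], fields[2], EV_DEFAULT
            else:
                if len(fields) < 2:
                    raise NetworkFormatError(
                        f"{path.name}:{lineno}: TSV line needs source<TAB>target[<TAB>ev]"
                    )
                src, tgt = fields[0], fields[1]
                try:
                    ev = float(fields[2]) if len(fields) > 2 and fields[2] else EV_DEFAULT
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"{path.name}:{lineno}: bad ev value {fields[2]!r}"
                    ) from exc
            edges.append(PathwayEdge(src.strip(), tgt.strip(), ev))
    net = PathwayNetwork.from_edges(edges, exit_node=exit_node)
    for nid in declared:
        if nid not in net.nodes:
            net.nodes[nid] = PathwayNode(nid)
    return net


def _load_graphml(path: Path, exit_node: str | None) -> PathwayNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat raise various types
        raise NetworkFormatError(f"{path.name}: not parseable as GraphML: {exc}") from exc
    exit_id = exit_node or g.graph.get("exit_node")
    if not exit_id:
        raise NetworkValidationError(
            f"{path.name}: GraphML lacks exit_node attribute and none supplied"
        )
    nodes = {
        str(n): PathwayNode(
            str(n),
            label=str(data.get("label", n)),
            kind=str(data.get("kind", "protein")),
        )
        for n, data in g.nodes(data=True)
    }
    edges = [
        PathwayEdge(str(u), str(v), float(data.get("ev", EV_DEFAULT)))
        for u, v, data in g.edges(data=True)
    ]
    return PathwayNetwork(nodes=nodes, edges=edges, exit_node=str(exit_id))


def save_network(net: PathwayNetwork, path: str | Path, format: Format | None = None) -> None:
    """Write ``net`` so that :func:`load_network` round-trips it exactly."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("source\ttarget\tev\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.ev:g}\n")
        elif fmt == "sif":
            linked = {e.source for e in net.edges} | {e.target for e in net.edges}
            for e in net.edges:
                fh.write(f"{e.source}\tactivates\t{e.target}\n")
            for nid in net.nodes:
                if nid not in linked:
                    fh.write(f"{nid}\n")
        else:
            raise NetworkFormatError(f"unknown format {fmt!r}")
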