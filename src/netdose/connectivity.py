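"""Weighted shortest-path connectivity measures of a pathway network.

Network efficiency (NE) sums the reciprocal weighted shortest-path lengths
over all ordered node pairs; network flux (NF) restricts the sum to paths
ending at the exit node, up-weighting downstream nodes.  Unreachable pairs
contribute 0 (the 1/infinity = 0 convention of the efficiency formalism).

Inhibition readouts are expressed as percent decreases between the
unperturbed network (all EV = 1, the maximum) and the fully blocked one
(all EV = 200, the minimum):

    NEd = (NE_max - NE) / (NE_max - NE_min) * 100 %
    NFd = (NF_max - NF) / (NF_max - NF_min) * 100 %
    NEF = sqrt(NEd * NFd)

NEF, the geometric mean, is the model's preferred predictor of percent
inhibition.  Because the edge-value map can slightly exceed 200 (up to
10^2.303 ~ 200.9 at full inhibition), NEd/NFd are clamped to [0, 100]
after the formulas above; the clamp is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .network import EV_BOUND, EV_DEFAULT, PathwayNetwork

__all__ = [
    "ConnectivityResult",
    "NetworkBounds",
    "shortest_path_lengths",
    "network_efficiency",
    "network_flux",
    "network_bounds",
    "connectivity_result",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityResult:
    """NE/NF and the derived percent-inhibition readouts for one scenario."""

    ne: float
    nf: float
    ned: float
    nfd: float
    nef: float

    def measure(self, name: str) -> float:
        """Look up a readout by name ('nef', 'ned' or 'nfd')."""
        if name not in ("ne", "nf", "ned", "nfd", "nef"):
            raise ValueError(f"unknown connectivity measure {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class NetworkBounds:
    """NE/NF extremes with every edge at EV=1 (max) and EV=200 (min)."""

    ne_max: float
    ne_min: float
    nf_max: float
    nf_min: float


def shortest_path_lengths(net: PathwayNetwork) -> dict[tuple[str, str], float]:
    """All-pairs directed shortest-path lengths under the ev weights.

    Returns ``{(i, j): d_ij}`` for i != j, with ``math.inf`` for
    unreachable pairs.  Edge values are non-negative, so Dijkstra applies.
    """
    for e in net.edges:
        if e.ev < 0:
            raise ValueError(f"negative edge value on {e.source}->{e.target}")
    g = net.to_networkx()
    dist = {
        (src, dst): d
        for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="ev")
        for dst, d in lengths.items()
        if src != dst
    }
    for i in net.nodes:
        for j in net.nodes:
            if i != j and (i, j) not in dist:
                dist[(i, j)] = math.inf
    return dist


def network_efficiency(net: PathwayNetwork) -> float:
    """NE: sum of 1/d_ij over ordered pairs i != j (1/inf := 0)."""
    return sum(
        1.0 / d for d in shortest_path_lengths(net).values() if math.isfinite(d)
    )


def network_flux(net: PathwayNetwork) -> float:
    """NF: sum of 1/d(i, exit) over i != exit (1/inf := 0)."""
    dist = shortest_path_lengths(net)
    return sum(
        1.0 / d
        for (i, j), d in dist.items()
        if j == net.exit_node and math.isfinite(d)
    )


def network_bounds(net: PathwayNetwork) -> NetworkBounds:
    """NE/NF at all-EV=1 (maximum connectivity) and all-EV=200 (minimum)."""
    hi = net.with_uniform_ev(EV_DEFAULT)
    lo = net.with_uniform_ev(EV_BOUND)
    return NetworkBounds(
        ne_max=network_efficiency(hi),
        ne_min=network_efficiency(lo),
        nf_max=network_flux(hi),
        nf_min=network_flux(lo),
    )


def _percent_decrease(value: float, vmax: float, vmin: float, name: str) -> float:
    pct = (vmax - value) / (vmax - vmin) * 100.0
    if pct < 0.0 or pct > 100.0:
        logger.debug("%s = %.4f%% clamped into [0, 100]", name, pct)
    return min(100.0, max(0.0, pct))


def connectivity_result(
    net: PathwayNetwork, bounds: NetworkBounds | None = None
) -> ConnectivityResult:
    """NE, NF and the percent readouts NEd/NFd/NEF for one network state."""
    if bounds is None:
        bounds = network_bounds(net)
    if not (bounds.ne_max > bounds.ne_min and bounds.nf_max > bounds.nf_min):
        raise ValueError(
            "degenerate connectivity bounds: the network is insensitive to "
            "uniform edge perturbation (ne_max == ne_min or nf_max == nf_min)"
        )
    dist = shortest_path_lengths(net)
    finite = [(pair, d) for pair, d in dist.items() if math.isfinite(d)]
    ne = sum(1.0 / d for _, d in finite)
    nf = sum(1.0 / d for (i, j), d in finite if j == net.exit_node)
    ned = _percent_decrease(ne, bounds.ne_max, bounds.ne_min, "NEd")
    nfd = _percent_decrease(nf, bounds.nf_max, bounds.nf_min, "NFd")
    return ConnectivityResult(ne=ne, nf=nf, ned=ned, nfd=nfd, nef=math.sqrt(ned * nfd))
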