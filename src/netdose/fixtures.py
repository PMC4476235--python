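"""Packaged reference data: the LPS-induced PGE2 production network.

The pathway describes how bacterial lipopolysaccharide (LPS) drives
prostaglandin E2 (PGE2) synthesis in macrophages.  LPS binds CD14, the
complex presents the stimulus to Toll-like receptor 4 (TLR4), and the
signal splits into the MyD88-dependent branch (IRAK4/IRAK1 -> TRAF6) and
the TRIF-dependent branch (TRAF6:RIP1, TRAF3).  Both converge on the TAK1
kinase hub, which fans out to the IKK/NF-kB axis and the three MAP-kinase
cascades (MKK3/6 -> p38, MKK4/7 -> JNK, MEK1/2 -> ERK).  The transcription
factors NF-kB, AP-1, CREB (via the p38/ERK-activated kinase MSK1) and
IRF-5 induce COX-2; COX-2 converts arachidonic acid to PGH2, and
prostaglandin E synthase (PGES) yields PGE2, the network's exit node.

Node ids are normalised ASCII tokens (``NFKB`` for NF-kappaB, ``COX2`` for
COX-2, ...); the display name is kept in the node label.  The transcription
has 30 nodes and 38 directed edges, and contains the 14 proteins used as
docking targets in the source study.
"""

from __future__ import annotations

import pandas as pd

from .network import PathwayNetwork

__all__ = [
    "lps_pge2_fixture",
    "DOCKING_TARGETS",
    "ec50_table",
    "LPS_PGE2_EDGES",
]

#: The 14 pathway proteins used as molecular-docking targets
#: (normalised node id -> display name).
DOCKING_TARGETS: dict[str, str] = {
    "TLR4": "TLR4",
    "PGES": "PGES",
    "TAK1": "TAK1",
    "AP1": "AP-1",
    "NFKB": "NF-κB",
    "ERK": "ERK",
    "COX2": "COX-2",
    "JNK": "JNK",
    "MKK4_7": "MKK4/7",
    "MKK3_6": "MKK3/6",
    "P38": "p38",
    "MEK1_2": "MEK1/2",
    "TRAF6_RIP1": "TRAF6:RIP1",
    "TRAF6": "TRAF6",
}

#: Directed edges of the LPS -> PGE2 pathway (source upstream, target
#: downstream along signal flow).
LPS_PGE2_EDGES: tuple[tuple[str, str], ...] = (
    ("LPS", "LPS_CD14"),
    ("CD14", "LPS_CD14"),
    ("LPS_CD14", "TLR4"),
    ("TLR4", "MYD88"),
    ("TLR4", "TRIF"),
    ("MYD88", "IRAK4"),
    ("IRAK4", "IRAK1"),
    ("IRAK1", "TRAF6"),
    ("TRIF", "TRAF6_RIP1"),
    ("TRIF", "TRAF3"),
    ("TRAF6_RIP1", "TAK1"),
    ("TRAF6", "TAK1"),
    ("TRAF3", "IRF5"),
    ("TAK1", "IKK"),
    ("TAK1", "MKK3_6"),
    ("TAK1", "MKK4_7"),
    ("TAK1", "MEK1_2"),
    ("IKK", "NFKB"),
    ("MKK3_6", "P38"),
    ("MKK4_7", "JNK"),
    ("MEK1_2", "ERK"),
    ("P38", "AP1"),
    ("JNK", "AP1"),
    ("ERK", "AP1"),
    ("P38", "MSK1"),
    ("ERK", "MSK1"),
    ("ERK", "PLA2"),
    ("MSK1", "CREB"),
    ("NFKB", "COX2"),
    ("AP1", "COX2"),
    ("CREB", "COX2"),
    ("IRF5", "COX2"),
    ("NFKB", "PGES"),
    ("PLA2", "AA"),
    ("AA", "PGH2"),
    ("COX2", "PGH2"),
    ("PGH2", "PGE2"),
    ("PGES", "PGE2"),
)

_NODE_KINDS = {
    "LPS": "small_molecule",
    "AA": "small_molecule",
    "PGH2": "small_molecule",
    "PGE2": "small_molecule",
    "LPS_CD14": "process",
}

_NODE_LABELS = {
    "LPS_CD14": "LPS:CD14",
    "MYD88": "MyD88",
    "IRF5": "IRF-5",
    "P38": "p38",
    "AA": "arachidonic acid",
    **DOCKING_TARGETS,
}


def lps_pge2_fixture() -> PathwayNetwork:
    """The packaged LPS -> PGE2 pathway network (30 nodes, 38 edges).

    LPS is a pure source (no incoming edge) and PGE2 is the exit node.
    All edge values are initialised to 1.
    """
    return PathwayNetwork.from_edges(
        LPS_PGE2_EDGES,
        exit_node="PGE2",
        kinds=_NODE_KINDS,
        labels=_NODE_LABELS,
    )


def ec50_table() -> pd.DataFrame:
    """Reference dose-response fit parameters for the five test compounds.

    Columns: Hill-fit top/bottom asymptotes (%), predicted EC50 (uM), slope
    parameter, fit R2, and the experimentally measured EC50e (uM).
    """
    rows = [
        ("Caffeic acid", 99.49, 0.28, 30.20, 0.98, 0.99994, 17.35),
        ("Coumarin", 99.99, 0.85, 52.95, 1.12, 0.99996, 49.14),
        ("Isochlorogenic acid B", 111.20, -3.63, 116.16, 0.56, 0.9998, 96.82),
        ("Protocatechuic acid", 101.18, -1.46, 42.82, 0.77, 0.99995, 46.34),
        ("Scopoletin", 100.72, 0.60, 45.48, 1.01, 0.99994, 38.46),
    ]
    return pd.DataFrame(
        rows,
        columns=["compound", "e_max", "e_min", "ec50_uM", "n", "r2", "ec50e_uM"],
    )
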