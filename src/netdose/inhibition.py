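"""Non-competitive inhibition model: doses + binding constants -> edge values.

For a non-competitive inhibitor the residual enzyme activity is
``1 / (1 + [I]/K_I)``, so the *fraction of affection* is

    fa = 1 - 1 / (1 + [I]/K_I)

and, for n mutually exclusive inhibitors of the same target,

    fa = 1 - 1 / (1 + sum_i [I_i]/K_i).

An inhibited target raises the resistance of every signalling edge leaving
it:

    EV = 10^(2.303 * fa)

so EV runs from 1 (fa = 0) to 10^2.303 ~ 200.9 (fa = 1).

Units: binding affinities are supplied as pKi = -log10(K_I in mol/L), so
K_I in uM is ``10**(6 - pKi)``; all concentrations are uM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .network import PathwayNetwork, NetworkValidationError

__all__ = [
    "AffinityRecord",
    "AffinityTable",
    "Dose",
    "DoseScenario",
    "fraction_affected",
    "fraction_affected_multi",
    "edge_value",
    "apply_scenario",
]

logger = logging.getLogger(__name__)

_EV_EXPONENT = 2.303


def pki_to_ki_um(pki: float) -> float:
    """Convert pKi (K_I in mol/L) to K_I in uM."""
    return 10.0 ** (6.0 - pki)


@dataclass(frozen=True)
class AffinityRecord:
    """A predicted compound-target binding affinity."""

    compound_id: str
    target_node: str
    pki: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pki):
            raise ValueError(
                f"{self.compound_id}->{self.target_node}: pKi must be finite"
            )

    @property
    def ki_um(self) -> float:
        return pki_to_ki_um(self.pki)


@dataclass
class AffinityTable:
    """Compound -> target binding-affinity records (one per pair)."""

    records: list[AffinityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.compound_id, r.target_node)
            if key in seen:
                raise ValueError(f"duplicate affinity record for {key}")
            seen.add(key)

    def for_compound(self, compound_id: str) -> list[AffinityRecord]:
        return [r for r in self.records if r.compound_id == compound_id]

    def compounds(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.compound_id not in out:
                out.append(r.compound_id)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AffinityTable":
        required = {"compound_id", "target_node", "pki"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"affinity table missing columns: {sorted(missing)}")
        return cls(
            [
                AffinityRecord(str(r.compound_id), str(r.target_node), float(r.pki))
                for r in df.itertuples(index=False)
            ]
        )

    @classmethod
    def read(cls, path: str | Path) -> "AffinityTable":
        """Read a CSV/TSV with header ``compound_id, target_node, pki``."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.compound_id, r.target_node, r.pki) for r in self.records],
            columns=["compound_id", "target_node", "pki"],
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class Dose:
    """One compound at one concentration (uM)."""

    compound_id: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.compound_id}: concentration must be >= 0")


@dataclass
class DoseScenario:
    """A set of simultaneous doses, at most one per compound."""

    doses: list[Dose] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.compound_id for d in self.doses]
        if len(ids) != len(set(ids)):
            raise ValueError("at most one dose per compound in a scenario")

    @classmethod
    def single(cls, compound_id: str, concentration: float) -> "DoseScenario":
        return cls([Dose(compound_id, concentration)])


def fraction_affected(conc: float, ki: float) -> float:
    """Fraction of target activity lost to one non-competitive inhibitor."""
    if ki <= 0:
        raise ValueError(f"ki must be > 0, got {ki}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return 1.0 - 1.0 / (1.0 + conc / ki)


def fraction_affected_multi(pairs: Sequence[tuple[float, float]]) -> float:
    """Joint fraction affected for mutually exclusive inhibitors.

    ``pairs`` is a sequence of (concentration, ki) in uM; the dose ratios
    add, so the result depends only on ``sum(conc/ki)``.
    """
    total = 0.0
    for conc, ki in pairs:
        if ki <= 0:
            raise ValueError(f"ki must be > 0, got {ki}")
        if conc < 0:
            raise ValueError(f"concentration must be >= 0, got {conc}")
        total += conc / ki
    return 1.0 - 1.0 / (1.0 + total)


def edge_value(fa: float) -> float:
    """Edge resistance 10^(2.303*fa) for a target inhibited by fraction fa."""
    if not 0.0 <= fa <= 1.0:
        raise ValueError(f"fraction affected must be in [0, 1], got {fa}")
    return 10.0 ** (_EV_EXPONENT * fa)


def target_fractions(
    net: PathwayNetwork, aff: AffinityTable, scenario: DoseScenario
) -> dict[str, float]:
    """Fraction affected per target node under ``scenario``.

    Each dosed compound contributes ``conc/ki`` at every target it has an
    affinity record for (polypharmacology: one compound may hit several
    targets, each with its own K_I).
    """
    for r in aff.records:
        if r.target_node not in net.nodes:
            raise NetworkValidationError(
                f"affinity target {r.target_node!r} is not a network node"
            )
    known = {r.compound_id for r in aff.records}
    contributions: dict[str, list[tuple[float, float]]] = {}
    for dose in scenario.doses:
        if dose.compound_id not in known:
            logger.warning(
                "dose for %r has no affinity record; it contributes nothing",
                dose.compound_id,
            )
            continue
        for r in aff.for_compound(dose.compound_id):
            contributions.setdefault(r.target_node, []).append(
                (dose.concentration, r.ki_um)
            )
    return {
        node: fraction_affected_multi(pairs) for node, pairs in contributions.items()
    }


def apply_scenario(
    net: PathwayNetwork, aff: AffinityTable, scenario: DoseScenario
) -> PathwayNetwork:
    """Return a copy of ``net`` with edge values set by the dosing scenario.

    Every edge leaving an inhibited target gets ``ev = 10^(2.303*fa)`` for
    that target's joint fraction affected; all other edges keep ev = 1.
    Topology is never altered.
    """
    fractions = target_fractions(net, aff, scenario)
    out = net.with_uniform_ev(1.0)
    for e in out.edges:
        fa = fractions.get(e.source)
        if fa is not None:
            e.ev = edge_value(fa)
    return out
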