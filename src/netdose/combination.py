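"""Two-drug combination analysis: surfaces, isoboles and the combination index.

The model evaluates a pair of inhibitors dosed together by applying both to
the pathway network (shared targets combine their dose ratios, exclusive
targets are penalised independently) and reading out NEF.  Synergy is
quantified by Chou's combination index at the jointly attained effect x:

    CI = D_a / (D_x)_a + D_b / (D_x)_b

where (D_x) is the dose at which each drug *alone* produces effect x,
obtained by inverting the model's own monotone single-drug curve.
CI < 1 marks synergism, CI = 1 Loewe-additive behaviour, CI > 1
antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dose_response import ScenarioEvaluator
from .inhibition import AffinityTable, Dose, DoseScenario
from .network import PathwayNetwork

__all__ = [
    "DoseResponseSurface",
    "IsobolePoint",
    "OptimalCombination",
    "AttainabilityError",
    "surface",
    "single_dose_for_effect",
    "combination_index",
    "isobologram",
    "optimal_combination",
]

_DOSE_RTOL = 1e-6
_EFFECT_ATOL = 0.1  # percentage points
# CI variation below this is dose-inversion noise, not a synergy signal
_FLAT_CI_SPAN = 1e-5


class AttainabilityError(ValueError):
    """A requested effect level exceeds a drug's saturating response."""


@dataclass
class DoseResponseSurface:
    """Percent inhibition over a 2-D dose grid, indexed [a, b]."""

    compound_a: str
    compound_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.grid_a = np.asarray(self.grid_a, dtype=float)
        self.grid_b = np.asarray(self.grid_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.grid_a.size, self.grid_b.size):
            raise ValueError("response matrix shape must be (len(grid_a), len(grid_b))")

    def write(self, path: str | Path) -> None:
        """Dense TSV matrix with grid_b as columns and grid_a as the index."""
        df = pd.DataFrame(
            self.response,
            index=pd.Index(self.grid_a, name=f"{self.compound_a}_uM"),
            columns=[f"{c:g}" for c in self.grid_b],
        )
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class IsobolePoint:
    """A dose pair on one iso-effect contour, with its combination index."""

    dose_a: float
    dose_b: float
    effect_level: float
    ci: float


@dataclass(frozen=True)
class OptimalCombination:
    """Minimum-CI point on an isobole and the ratio diagnostics around it."""

    point: IsobolePoint
    dose_ratio: float  # dose_a / dose_b at the optimum (inf on the a-axis)
    ec50_ratio: float  # single-drug equi-effective dose ratio a/b
    flat_landscape: bool  # True when CI is constant along the isobole


def _default_log_grid(upper: float, n: int = 25) -> np.ndarray:
    """0 prepended to a log-spaced grid reaching ``upper``."""
    return np.concatenate([[0.0], np.geomspace(upper / 10 ** 3, upper, n - 1)])


def _evaluator(net: PathwayNetwork, aff: AffinityTable, evaluator: ScenarioEvaluator | None) -> ScenarioEvaluator:
    return evaluator if evaluator is not None else ScenarioEvaluator(net, aff)


def _pair_effect(
    ev: ScenarioEvaluator, compound_a: str, compound_b: str, da: float, db: float, measure: str
) -> float:
    doses = [Dose(compound_a, da)]
    if compound_b != compound_a:
        doses.append(Dose(compound_b, db))
    elif db:
        raise ValueError("self-pairing requires distinct pseudo-compound ids")
    return ev.effect(DoseScenario(doses), measure)


def surface(
    net: PathwayNetwork,
    aff: AffinityTable,
    compound_a: str,
    compound_b: str,
    grid_a: Sequence[float] | None = None,
    grid_b: Sequence[float] | None = None,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> DoseResponseSurface:
    """Dose-response surface of a compound pair.

    Default grids are 25-point log grids (0 prepended) reaching four times
    the compound's half-plateau dose; rows/columns at zero dose reproduce
    the single-drug curves exactly.
    """
    ev = _evaluator(net, aff, evaluator)
    if grid_a is None:
        grid_a = _default_log_grid(4.0 * single_dose_for_effect(
            net, aff, compound_a, ev.plateau(compound_a, measure) / 2, measure, ev))
    if grid_b is None:
        grid_b = _default_log_grid(4.0 * single_dose_for_effect(
            net, aff, compound_b, ev.plateau(compound_b, measure) / 2, measure, ev))
    grid_a = np.asarray(list(grid_a), dtype=float)
    grid_b = np.asarray(list(grid_b), dtype=float)
    response = np.empty((grid_a.size, grid_b.size))
    for i, da in enumerate(grid_a):
        for j, db in enumerate(grid_b):
            response[i, j] = _pair_effect(ev, compound_a, compound_b, da, db, measure)
    return DoseResponseSurface(compound_a, compound_b, grid_a, grid_b, response)


def single_dose_for_effect(
    net: PathwayNetwork,
    aff: AffinityTable,
    compound_id: str,
    effect: float,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> float:
    """Invert the monotone single-drug curve: dose producing ``effect`` %.

    Bisection to relative dose tolerance 1e-6.  Raises
    :class:`AttainabilityError` when the effect exceeds the compound's
    saturating response.
    """
    if not 0.0 < effect < 100.0:
        raise AttainabilityError(f"effect must be in (0, 100), got {effect}")
    ev = _evaluator(net, aff, evaluator)
    plateau = ev.plateau(compound_id, measure)
    if effect >= plateau:
        raise AttainabilityError(
            f"effect {effect:.3g}% exceeds the saturating response "
            f"{plateau:.3g}% of {compound_id!r}"
        )
    hi = 1.0
    while ev.single_effect(compound_id, hi, measure) < effect:
        hi *= 10.0
    lo = 0.0
    # bisection on a monotone curve; terminate on relative dose width
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if ev.single_effect(compound_id, mid, measure) < effect:
            lo = mid
        else:
            hi = mid
        if hi - lo <= _DOSE_RTOL * hi:
            break
    return (lo + hi) / 2.0


def combination_index(
    net: PathwayNetwork,
    aff: AffinityTable,
    dose_a: Dose,
    dose_b: Dose,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> float:
    """Chou combination index of a two-drug dose pair.

    The joint effect x is computed from the combined scenario; each
    denominator (D_x) is the dose at which that drug alone reaches x.
    A zero dose drops its term, and with a single non-zero dose the index
    is identically 1 (the definition degenerates to D/(D_x) with D = D_x).
    """
    ev = _evaluator(net, aff, evaluator)
    active = [d for d in (dose_a, dose_b) if d.concentration > 0]
    if not active:
        raise ValueError("combination index of an empty scenario is undefined")
    if len(active) == 1:
        return 1.0
    x = _pair_effect(
        ev, dose_a.compound_id, dose_b.compound_id,
        dose_a.concentration, dose_b.concentration, measure,
    )
    if not 0.0 < x < 100.0:
        raise AttainabilityError(
            f"combined effect {x:.3g}% is outside (0, 100); CI undefined"
        )
    ci = 0.0
    for d in active:
        dx = single_dose_for_effect(net, aff, d.compound_id, x, measure, ev)
        ci += d.concentration / dx
    return ci


def isobologram(
    net: PathwayNetwork,
    aff: AffinityTable,
    compound_a: str,
    compound_b: str,
    effect: float,
    n_points: int = 11,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> list[IsobolePoint]:
    """Dose pairs producing one fixed effect level, each with its CI.

    dose_a is swept linearly over [0, (D_x)_a]; dose_b is solved per point
    by bisection so that the combined response matches ``effect`` within
    0.1 percentage points.
    """
    ev = _evaluator(net, aff, evaluator)
    dxa = single_dose_for_effect(net, aff, compound_a, effect, measure, ev)
    dxb = single_dose_for_effect(net, aff, compound_b, effect, measure, ev)
    points: list[IsobolePoint] = []
    for da in np.linspace(0.0, dxa, n_points):
        db = _solve_partner_dose(ev, compound_a, compound_b, da, effect, dxb, measure)
        ci = da / dxa + db / dxb
        points.append(IsobolePoint(dose_a=float(da), dose_b=float(db), effect_level=effect, ci=float(ci)))
    return points


def _solve_partner_dose(
    ev: ScenarioEvaluator,
    compound_a: str,
    compound_b: str,
    da: float,
    effect: float,
    dxb: float,
    measure: str,
) -> float:
    """Bisection for the b-dose completing (da, ?) to the target effect."""
    if _pair_effect(ev, compound_a, compound_b, da, 0.0, measure) >= effect - 1e-12:
        return 0.0
    lo, hi = 0.0, dxb
    # da >= 0 can only help, so the single-drug dose dxb brackets the root
    for _ in range(200):
        mid = (lo + hi) / 2.0
        x = _pair_effect(ev, compound_a, compound_b, da, mid, measure)
        if x < effect:
            lo = mid
        else:
            hi = mid
        if hi - lo <= _DOSE_RTOL * max(hi, 1e-30) and abs(x - effect) <= _EFFECT_ATOL:
            break
    return (lo + hi) / 2.0


def optimal_combination(
    net: PathwayNetwork,
    aff: AffinityTable,
    compound_a: str,
    compound_b: str,
    effect: float,
    n_scan: int = 33,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> OptimalCombination:
    """Minimum-CI dose pair on the isobole at ``effect`` %.

    A linear scan over the sweep parameter t = dose_a/(D_x)_a is refined
    by bounded golden-section search; the reported ratio diagnostics
    compare the optimal dose ratio with the single-drug equi-effective
    (EC50-like) ratio.
    """
    ev = _evaluator(net, aff, evaluator)
    dxa = single_dose_for_effect(net, aff, compound_a, effect, measure, ev)
    dxb = single_dose_for_effect(net, aff, compound_b, effect, measure, ev)

    def point_at(t: float) -> IsobolePoint:
        da = t * dxa
        db = _solve_partner_dose(ev, compound_a, compound_b, da, effect, dxb, measure)
        return IsobolePoint(float(da), float(db), effect, float(da / dxa + db / dxb))

    ts = np.linspace(0.0, 1.0, n_scan)
    scan = [point_at(t) for t in ts]
    cis = np.array([p.ci for p in scan])
    flat = cis.max() - cis.min() < _FLAT_CI_SPAN
    best_idx = int(np.argmin(cis))
    best = scan[best_idx]
    if not flat and 0 < best_idx < n_scan - 1:
        res = minimize_scalar(
            lambda t: point_at(float(t)).ci,
            bounds=(ts[best_idx - 1], ts[best_idx + 1]),
            method="bounded",
            options={"xatol": 1e-4},
        )
        candidate = point_at(float(res.x))
        if candidate.ci < best.ci:
            best = candidate
    dose_ratio = best.dose_a / best.dose_b if best.dose_b > 0 else math.inf
    return OptimalCombination(
        point=best, dose_ratio=dose_ratio, ec50_ratio=dxa / dxb, flat_landscape=flat
    )


def isobole_frame(points: Sequence[IsobolePoint]) -> pd.DataFrame:
    """Tabulate isobole points as ``dose_a  dose_b  effect  CI``."""
    return pd.DataFrame(
        [(p.dose_a, p.dose_b, p.effect_level, p.ci) for p in points],
        columns=["dose_a", "dose_b", "effect", "CI"],
    )
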