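"""Predicted dose-response curves and Hill-type curve fitting.

A single-compound dose grid is turned into a curve by applying each dose
to the pathway network and reading out a connectivity measure (NEF by
default) as percent inhibition.  Curves are summarised by the four-
parameter logistic

    y = E_max - (E_max - E_min) / (1 + ([I]/EC50)^n)

with top/bottom asymptotes E_max/E_min (percent), half-maximal
concentration EC50 (uM) and slope parameter n (Hill coefficient).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .connectivity import ConnectivityResult, NetworkBounds, connectivity_result, network_bounds
from .inhibition import AffinityTable, Dose, DoseScenario, apply_scenario
from .network import PathwayNetwork

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "Ec50Correlation",
    "FitError",
    "ScenarioEvaluator",
    "predict_curve",
    "default_concentration_grid",
    "hill_eval",
    "fit_hill",
    "ec50_correlation",
]

logger = logging.getLogger(__name__)

CURVE_SOURCES = ("predicted_nef", "predicted_ned", "predicted_nfd", "experimental")


class FitError(RuntimeError):
    """Nonlinear curve fitting failed; the message carries diagnostics."""


@dataclass
class DoseResponseCurve:
    """Percent inhibition at each concentration of one compound."""

    compound_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    source: str = "predicted_nef"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if self.concentrations.size and (
            np.any(self.concentrations < 0)
            or np.any(np.diff(self.concentrations) <= 0)
        ):
            raise ValueError("concentrations must be non-negative and strictly ascending")
        if self.source not in CURVE_SOURCES:
            raise ValueError(f"source {self.source!r} not in {CURVE_SOURCES}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"concentration_uM": self.concentrations, "response_pct": self.responses}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, compound_id: str = "", source: str = "experimental") -> "DoseResponseCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(
            compound_id=compound_id or Path(path).stem,
            concentrations=df["concentration_uM"].to_numpy(),
            responses=df["response_pct"].to_numpy(),
            source=source,
        )


@dataclass(frozen=True)
class HillFit:
    """Fitted four-parameter logistic and its goodness of fit."""

    e_max: float
    e_min: float
    ec50: float
    n: float
    r2: float

    def __post_init__(self) -> None:
        if self.e_max <= self.e_min:
            raise ValueError("e_max must exceed e_min")
        if self.ec50 <= 0 or self.n <= 0:
            raise ValueError("ec50 and n must be positive")


class ScenarioEvaluator:
    """Applies dosing scenarios to one network/affinity pair.

    Caches the connectivity bounds (a property of the topology alone) so
    repeated evaluations along a dose grid or surface cost one weighted
    all-pairs shortest-path computation each.
    """

    def __init__(self, net: PathwayNetwork, aff: AffinityTable):
        self.net = net
        self.aff = aff
        self.bounds: NetworkBounds = network_bounds(net)

    def result(self, scenario: DoseScenario) -> ConnectivityResult:
        perturbed = apply_scenario(self.net, self.aff, scenario)
        return connectivity_result(perturbed, self.bounds)

    def effect(self, scenario: DoseScenario, measure: str = "nef") -> float:
        return self.result(scenario).measure(measure)

    def single_effect(self, compound_id: str, conc: float, measure: str = "nef") -> float:
        return self.effect(DoseScenario.single(compound_id, conc), measure)

    def plateau(self, compound_id: str, measure: str = "nef", conc: float = 1e9) -> float:
        """Saturating-dose effect of one compound (its maximal response)."""
        return self.single_effect(compound_id, conc, measure)


def _check_compound(aff: AffinityTable, net: PathwayNetwork, compound_id: str) -> None:
    records = [r for r in aff.for_compound(compound_id) if r.target_node in net.nodes]
    if not records:
        raise ValueError(
            f"compound {compound_id!r} has no affinity record targeting the network"
        )


def default_concentration_grid(
    evaluator: ScenarioEvaluator,
    compound_id: str,
    measure: str = "nef",
    n_points: int = 12,
    span: float = 100.0,
) -> np.ndarray:
    """Log-spaced grid centred on the compound's half-plateau concentration.

    The centre is found by bisection for the dose producing half the
    saturating response; the grid spans ``centre/span`` to ``centre*span``.
    """
    plateau = evaluator.plateau(compound_id, measure)
    if plateau <= 0:
        raise ValueError(f"compound {compound_id!r} has no effect on the network")
    half = plateau / 2.0
    lo, hi = 0.0, 1.0
    while evaluator.single_effect(compound_id, hi, measure) < half:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - guarded by plateau check
            raise ValueError("could not bracket the half-plateau dose")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if evaluator.single_effect(compound_id, mid, measure) < half:
            lo = mid
        else:
            hi = mid
    centre = (lo + hi) / 2.0
    return np.geomspace(centre / span, centre * span, n_points)


def predict_curve(
    net: PathwayNetwork,
    aff: AffinityTable,
    compound_id: str,
    concentrations: Sequence[float] | None = None,
    measure: str = "nef",
    evaluator: ScenarioEvaluator | None = None,
) -> DoseResponseCurve:
    """Model-predicted dose-response curve of one compound.

    Each concentration is applied as a single-compound scenario and the
    chosen connectivity readout (nef/ned/nfd) recorded as percent
    inhibition; responses are non-decreasing in dose.
    """
    _check_compound(aff, net, compound_id)
    ev = evaluator if evaluator is not None else ScenarioEvaluator(net, aff)
    if concentrations is None:
        grid = default_concentration_grid(ev, compound_id, measure)
    else:
        grid = np.asarray(list(concentrations), dtype=float)
        if grid.size == 0:
            raise ValueError("empty concentration grid")
    responses = [ev.single_effect(compound_id, c, measure) for c in grid]
    return DoseResponseCurve(
        compound_id=compound_id,
        concentrations=grid,
        responses=np.array(responses),
        source=f"predicted_{measure}",
    )


def hill_eval(conc: float | np.ndarray, fit: HillFit) -> float | np.ndarray:
    """Evaluate the four-parameter logistic at ``conc`` (uM)."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / fit.ec50) ** fit.n, 0.0)
    y = fit.e_max - (fit.e_max - fit.e_min) / (1.0 + ratio)
    return float(y) if y.ndim == 0 else y


def _hill(conc, e_max, e_min, ec50, n):
    ratio = np.where(conc > 0, (conc / ec50) ** n, 0.0)
    return e_max - (e_max - e_min) / (1.0 + ratio)


def fit_hill(
    curve: DoseResponseCurve,
    e_max_bounds: tuple[float, float] | None = None,
    e_min_bounds: tuple[float, float] = (-20.0, 20.0),
) -> HillFit:
    """Nonlinear least-squares fit of the four-parameter logistic.

    Default asymptote bounds assume percent-inhibition data plateauing
    near 100 % (E_max in [80, 120], E_min in [-20, 20]); when the observed
    plateau is below 80 % the E_max band is widened around it, since a
    compound touching few network targets saturates well short of full
    inhibition.
    """
    x = curve.concentrations
    y = curve.responses
    if x.size < 5:
        raise FitError("need at least 5 points to fit a 4-parameter curve")
    y_span = float(y.max() - y.min())
    if y_span < 1e-6:
        raise FitError("degenerate flat curve: responses do not vary with dose")
    if e_max_bounds is None:
        if y.max() >= 80.0:
            e_max_bounds = (80.0, 120.0)
        else:
            e_max_bounds = (0.75 * y.max(), 1.5 * y.max())
            logger.debug(
                "plateau %.1f%% below 80%%: widening E_max bounds to %s",
                y.max(), e_max_bounds,
            )
    half = (y.max() + y.min()) / 2.0
    ec50_guess = float(x[np.argmin(np.abs(y - half))])
    if ec50_guess <= 0:
        ec50_guess = float(x[x > 0].min()) if np.any(x > 0) else 1.0
    p0 = [
        np.clip(y.max(), *e_max_bounds),
        np.clip(y.min(), *e_min_bounds),
        ec50_guess,
        1.0,
    ]
    bounds = (
        [e_max_bounds[0], e_min_bounds[0], 1e-12, 0.05],
        [e_max_bounds[1], e_min_bounds[1], 1e12, 20.0],
    )
    try:
        popt, _ = curve_fit(
            _hill, x, y, p0=p0, bounds=bounds,
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    residuals = y - _hill(x, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return HillFit(e_max=popt[0], e_min=popt[1], ec50=popt[2], n=popt[3], r2=r2)


@dataclass(frozen=True)
class Ec50Correlation:
    """Agreement between predicted and experimental EC50s.

    ``r2`` is the ordinary coefficient of determination of the ordinary
    least-squares line of experimental on predicted values; ``r2_adjusted``
    corrects it for the small sample and is the headline value.
    """

    r2: float
    r2_adjusted: float
    slope: float
    intercept: float
    n: int


def ec50_correlation(
    predicted: Sequence[float], experimental: Sequence[float]
) -> Ec50Correlation:
    """Regress experimental EC50s on predicted ones (uM scales)."""
    pred = np.asarray(list(predicted), dtype=float)
    expt = np.asarray(list(experimental), dtype=float)
    if pred.shape != expt.shape:
        raise ValueError("predicted and experimental lists must have equal length")
    n = pred.size
    if n < 3:
        raise ValueError(f"need at least 3 EC50 pairs, got {n}")
    slope, intercept = np.polyfit(pred, expt, 1)
    residuals = expt - (intercept + slope * pred)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((expt - expt.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return Ec50Correlation(
        r2=r2, r2_adjusted=r2_adj, slope=float(slope), intercept=float(intercept), n=n
    )


def fit_report(fits: dict[str, HillFit]) -> pd.DataFrame:
    """Tabulate per-compound Hill fits (one row per compound)."""
    return pd.DataFrame(
        [
            (cid, f.e_max, f.e_min, f.ec50, f.n, f.r2)
            for cid, f in fits.items()
        ],
        columns=["compound", "E_max", "E_min", "EC50", "n", "R2"],
    )
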