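"""Two-drug surfaces, isoboles, combination index and Loewe consistency."""

from __future__ import annotations

import math

import numpy as np
import pytest

from netdose import (
    AffinityRecord,
    AffinityTable,
    AttainabilityError,
    Dose,
    PathwayNetwork,
    ScenarioEvaluator,
    combination_index,
    isobologram,
    optimal_combination,
    predict_curve,
    single_dose_for_effect,
    surface,
)

# Toy system: two parallel branches S->A->M and S->B->M converging on the
# exit.  Compound x hits {S, A, M}, compound y hits {S, B, M} (shared S and
# M, exclusive middle nodes), all with Ki = 10 uM; both single-drug
# responses saturate above 92 % NEF.
TOY_EDGES = [("S", "A"), ("S", "B"), ("A", "M"), ("B", "M"), ("M", "EXIT")]


@pytest.fixture(scope="module")
def toy_net() -> PathwayNetwork:
    return PathwayNetwork.from_edges(TOY_EDGES, exit_node="EXIT")


@pytest.fixture(scope="module")
def toy_aff() -> AffinityTable:
    return AffinityTable(
        [AffinityRecord("x", t, 5.0) for t in ("S", "A", "M")]
        + [AffinityRecord("y", t, 5.0) for t in ("S", "B", "M")]
    )


@pytest.fixture(scope="module")
def toy_eval(toy_net, toy_aff) -> ScenarioEvaluator:
    return ScenarioEvaluator(toy_net, toy_aff)


@pytest.fixture(scope="module")
def sham_aff() -> AffinityTable:
    """One physical compound entered under two pseudo-identities."""
    return AffinityTable(
        [AffinityRecord(cid, t, 5.0) for cid in ("d1", "d2") for t in ("S", "A", "M")]
    )


class TestSurface:
    def test_marginals_match_single_drug_curves(self, toy_net, toy_aff, toy_eval):
        grid = np.array([0.0, 1.0, 5.0, 20.0])
        surf = surface(toy_net, toy_aff, "x", "y", grid, grid, evaluator=toy_eval)
        curve_x = predict_curve(toy_net, toy_aff, "x", grid[1:], evaluator=toy_eval)
        np.testing.assert_allclose(surf.response[1:, 0], curve_x.responses, rtol=1e-12)
        curve_y = predict_curve(toy_net, toy_aff, "y", grid[1:], evaluator=toy_eval)
        np.testing.assert_allclose(surf.response[0, 1:], curve_y.responses, rtol=1e-12)
        assert surf.response[0, 0] == 0.0

    def test_monotone_along_both_axes(self, toy_net, toy_aff, toy_eval):
        grid = np.array([0.0, 0.5, 2.0, 8.0, 32.0])
        surf = surface(toy_net, toy_aff, "x", "y", grid, grid, evaluator=toy_eval)
        assert np.all(np.diff(surf.response, axis=0) >= -1e-9)
        assert np.all(np.diff(surf.response, axis=1) >= -1e-9)

    def test_sham_diagonal_equals_summed_single_dose(self, toy_net, sham_aff):
        ev = ScenarioEvaluator(toy_net, sham_aff)
        grid = np.array([0.0, 2.0, 6.0])
        surf = surface(toy_net, sham_aff, "d1", "d2", grid, grid, evaluator=ev)
        for i, da in enumerate(grid):
            for j, db in enumerate(grid):
                expected = ev.single_effect("d1", da + db)
                assert surf.response[i, j] == pytest.approx(expected, rel=1e-12)

    def test_surface_write(self, tmp_path, toy_net, toy_aff, toy_eval):
        grid = np.array([0.0, 1.0])
        surf = surface(toy_net, toy_aff, "x", "y", grid, grid, evaluator=toy_eval)
        out = tmp_path / "surface.tsv"
        surf.write(out)
        assert out.read_text().startswith("x_uM")


class TestSingleDoseForEffect:
    def test_inverse_identity(self, toy_net, toy_aff, toy_eval):
        for probe in (0.7, 3.0, 11.0):
            effect = toy_eval.single_effect("x", probe)
            dose = single_dose_for_effect(
                toy_net, toy_aff, "x", effect, evaluator=toy_eval
            )
            assert dose == pytest.approx(probe, rel=1e-4)

    def test_small_effects_need_small_doses(self, toy_net, toy_aff, toy_eval):
        dose = single_dose_for_effect(toy_net, toy_aff, "x", 0.01, evaluator=toy_eval)
        assert dose < 1e-3

    def test_unattainable_effect_raises(self, toy_net, toy_aff, toy_eval):
        with pytest.raises(AttainabilityError, match="saturating"):
            single_dose_for_effect(toy_net, toy_aff, "x", 99.0, evaluator=toy_eval)
        with pytest.raises(AttainabilityError):
            single_dose_for_effect(toy_net, toy_aff, "x", 0.0, evaluator=toy_eval)

    def test_matches_bruteforce_grid_scan(self, toy_net, toy_aff, toy_eval):
        dose = single_dose_for_effect(toy_net, toy_aff, "x", 50.0, evaluator=toy_eval)
        grid = np.geomspace(1e-3, 1e3, 10_000)
        effects = [toy_eval.single_effect("x", c) for c in grid]
        best = grid[int(np.argmin(np.abs(np.array(effects) - 50.0)))]
        assert dose == pytest.approx(best, rel=2e-3)


class TestCombinationIndex:
    def test_single_nonzero_dose_is_exactly_one(self, toy_net, toy_aff, toy_eval):
        ci = combination_index(
            toy_net, toy_aff, Dose("x", 4.0), Dose("y", 0.0), evaluator=toy_eval
        )
        assert ci == 1.0

    @pytest.mark.parametrize("split", [0.1, 0.5, 0.9])
    def test_sham_combination_is_loewe_additive(self, toy_net, sham_aff, split):
        ev = ScenarioEvaluator(toy_net, sham_aff)
        total = 4.0
        ci = combination_index(
            toy_net,
            sham_aff,
            Dose("d1", split * total),
            Dose("d2", (1 - split) * total),
            evaluator=ev,
        )
        assert ci == pytest.approx(1.0, abs=1e-6)

    def test_empty_scenario_rejected(self, toy_net, toy_aff, toy_eval):
        with pytest.raises(ValueError, match="empty"):
            combination_index(
                toy_net, toy_aff, Dose("x", 0.0), Dose("y", 0.0), evaluator=toy_eval
            )

    def test_cross_checked_by_bruteforce_isobole_scan(self, toy_net, toy_aff, toy_eval):
        da, db = 1.5, 2.5
        ci = combination_index(
            toy_net, toy_aff, Dose("x", da), Dose("y", db), evaluator=toy_eval
        )
        # oracle: dense-grid inversion of each single-drug curve at the
        # jointly attained effect
        from netdose.inhibition import DoseScenario

        x = toy_eval.effect(DoseScenario([Dose("x", da), Dose("y", db)]))
        grid = np.geomspace(1e-4, 1e4, 20_000)
        inv = {}
        for cid in ("x", "y"):
            effects = np.array([toy_eval.single_effect(cid, c) for c in grid])
            inv[cid] = float(np.interp(x, effects, grid))
        expected = da / inv["x"] + db / inv["y"]
        assert ci == pytest.approx(expected, rel=1e-3)

    def test_scale_invariance(self, toy_net, toy_aff):
        """Rescaling all doses and binding constants by one factor leaves
        the combination index unchanged."""
        scale = 10.0
        scaled_aff = AffinityTable(
            [
                AffinityRecord(r.compound_id, r.target_node, r.pki - math.log10(scale))
                for r in toy_aff.records
            ]
        )
        ci = combination_index(toy_net, toy_aff, Dose("x", 1.5), Dose("y", 2.5))
        ci_scaled = combination_index(
            toy_net, scaled_aff, Dose("x", 1.5 * scale), Dose("y", 2.5 * scale)
        )
        assert ci_scaled == pytest.approx(ci, rel=1e-6)


class TestIsobologram:
    def test_endpoints_are_single_drug_doses(self, toy_net, toy_aff, toy_eval):
        points = isobologram(
            toy_net, toy_aff, "x", "y", 50.0, n_points=5, evaluator=toy_eval
        )
        dxa = single_dose_for_effect(toy_net, toy_aff, "x", 50.0, evaluator=toy_eval)
        dxb = single_dose_for_effect(toy_net, toy_aff, "y", 50.0, evaluator=toy_eval)
        assert points[0].dose_a == 0.0
        assert points[0].dose_b == pytest.approx(dxb, rel=1e-4)
        assert points[-1].dose_a == pytest.approx(dxa, rel=1e-4)
        assert points[-1].dose_b == pytest.approx(0.0, abs=1e-6 * dxb)

    def test_every_point_reproduces_the_effect(self, toy_net, toy_aff, toy_eval):
        from netdose.inhibition import DoseScenario

        for p in isobologram(
            toy_net, toy_aff, "x", "y", 60.0, n_points=7, evaluator=toy_eval
        ):
            x = toy_eval.effect(DoseScenario([Dose("x", p.dose_a), Dose("y", p.dose_b)]))
            assert x == pytest.approx(60.0, abs=0.1)

    def test_sham_isobole_is_linear(self, toy_net, sham_aff):
        """For a self-combination the kinetics are strictly dose-additive,
        so the iso-effect contour is the straight line d1 + d2 = const."""
        ev = ScenarioEvaluator(toy_net, sham_aff)
        points = isobologram(
            toy_net, sham_aff, "d1", "d2", 50.0, n_points=7, evaluator=ev
        )
        totals = [p.dose_a + p.dose_b for p in points]
        assert max(totals) == pytest.approx(min(totals), rel=1e-4)


class TestOptimalCombination:
    def test_sham_landscape_is_flat(self, toy_net, sham_aff):
        ev = ScenarioEvaluator(toy_net, sham_aff)
        opt = optimal_combination(toy_net, sham_aff, "d1", "d2", 50.0, evaluator=ev)
        assert opt.flat_landscape
        assert opt.point.ci == pytest.approx(1.0, abs=1e-6)

    def test_optimum_not_worse_than_endpoints(self, toy_net, toy_aff, toy_eval):
        opt = optimal_combination(toy_net, toy_aff, "x", "y", 50.0, evaluator=toy_eval)
        assert opt.point.ci <= 1.0 + 1e-9

    def test_matches_exhaustive_scan(self, toy_net, toy_aff, toy_eval):
        opt = optimal_combination(
            toy_net, toy_aff, "x", "y", 50.0, n_scan=17, evaluator=toy_eval
        )
        fine = isobologram(
            toy_net, toy_aff, "x", "y", 50.0, n_points=201, evaluator=toy_eval
        )
        best = min(p.ci for p in fine)
        assert opt.point.ci <= best + 1e-4

    def test_reports_ratio_diagnostics(self, toy_net, toy_aff, toy_eval):
        opt = optimal_combination(toy_net, toy_aff, "x", "y", 50.0, evaluator=toy_eval)
        dxa = single_dose_for_effect(toy_net, toy_aff, "x", 50.0, evaluator=toy_eval)
        dxb = single_dose_for_effect(toy_net, toy_aff, "y", 50.0, evaluator=toy_eval)
        assert opt.ec50_ratio == pytest.approx(dxa / dxb, rel=1e-6)
        if opt.point.dose_b > 0:
            assert opt.dose_ratio == pytest.approx(
                opt.point.dose_a / opt.point.dose_b, rel=1e-9
            )
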