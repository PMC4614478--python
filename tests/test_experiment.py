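"""Sweep harness, regression and design comparison."""

import numpy as np
import pandas as pd
import pytest

from numentry import (
    EXACT_MISMATCH,
    OUT_BY_FACTOR,
    OVERDOSE_ONLY,
    ErrorModel,
    ExperimentConfig,
    FixedTargets,
    RiskPoint,
    TargetNumber,
    compare_designs,
    estimate_risk,
    fit_all,
    fit_line,
    points_frame,
    sweep,
)


def tiny_config(**kw):
    base = dict(
        designs=("A", "C"),
        v_grid=(0.2, 0.5, 0.9),
        trials_per_point=300,
        operator=ErrorModel(per_class_error_prob=0.01),
        seed=5,
    )
    base.update(kw)
    return ExperimentConfig(**base)


class TestEstimateRisk:
    def test_correct_design_has_zero_risk_for_careful_operator(self):
        cfg = tiny_config(v_grid=(0.5,), trials_per_point=2000)
        pt = estimate_risk("C", 0.0, cfg)
        assert pt.risk == 0.0 and pt.risk_ratio is None

    def test_single_trial_risk_is_the_harm_indicator(self):
        cfg = tiny_config(trials_per_point=1)
        pt = estimate_risk("C", 1.0, cfg)
        assert pt.risk in (0.0, 1.0) and pt.trials == 1

    def test_binomial_standard_error(self):
        cfg = tiny_config(v_grid=(1.0,), trials_per_point=500)
        pt = estimate_risk("A", 1.0, cfg)
        assert pt.se == pytest.approx(
            np.sqrt(pt.risk * (1 - pt.risk) / pt.trials)
        )
        assert pt.risk_ratio == pytest.approx(pt.risk)


class TestHarmMetrics:
    t = TargetNumber.from_string("10")

    def test_exact(self):
        m = EXACT_MISMATCH
        assert m.harm("10", self.t) == 0
        assert m.harm("10.", self.t) == 0  # equal value, different string
        assert m.harm("11", self.t) == 1
        assert m.harm("1..0", self.t) == 1
        assert m.harm(None, self.t) == 1

    def test_out_by_factor(self):
        m = OUT_BY_FACTOR(5)
        assert m.harm("11", self.t) == 0  # wrong but within factor 5
        assert m.harm("50", self.t) == 1
        assert m.harm("2", self.t) == 1
        assert m.harm("0", self.t) == 1  # one side zero

    def test_overdose_only(self):
        m = OVERDOSE_ONLY
        assert m.harm("11", self.t) == 1
        assert m.harm("9", self.t) == 0
        assert m.harm("1..0", self.t) == 0  # unreadable, not an overdose

    def test_metric_changes_measured_risk(self):
        cfg = tiny_config(designs=("C",), v_grid=(1.0,), trials_per_point=3000)
        exact = estimate_risk("C", 1.0, cfg).risk
        lax = estimate_risk(
            "C", 1.0, tiny_config(designs=("C",), v_grid=(1.0,),
                                  trials_per_point=3000,
                                  harm_metric=OUT_BY_FACTOR(5))
        ).risk
        assert lax < exact


class TestSweep:
    def test_shape_one_row_per_cell(self):
        table = sweep(tiny_config())
        assert len(table) == 2 * 3
        assert set(table["design"]) == {"A", "C"}

    def test_bit_reproducible(self):
        a = sweep(tiny_config())
        b = sweep(tiny_config())
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_cells_independent_of_grid_composition(self):
        # the same (design, v, trials) cell gives the same estimate no
        # matter which other cells are swept alongside it
        full = sweep(tiny_config())
        part = sweep(tiny_config(designs=("C",), v_grid=(0.5,)))
        got = full[(full["design"] == "C") & (full["v"] == 0.5)]["risk"].iloc[0]
        assert got == part["risk"].iloc[0]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tiny_config(v_grid=(0.5, 0.2))
        with pytest.raises(ValueError):
            tiny_config(v_grid=(0.2, 1.5))
        with pytest.raises(ValueError):
            tiny_config(trials_per_point=0)
        with pytest.raises(ValueError):
            tiny_config(designs=("A", "Z"))


def synthetic_points(design, slope, intercept, vs, trials=10_000, se=0.0):
    return [
        RiskPoint(design, v, trials, intercept + slope * v, se,
                  (intercept + slope * v) / v if v > 0 else None)
        for v in vs
    ]


class TestFitLine:
    vs = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))

    def test_exact_line_recovered(self):
        fit = fit_line(synthetic_points("X", 0.02, 0.0, self.vs))
        assert fit.slope == pytest.approx(0.02)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_risk_r_squared_zero_by_convention(self):
        fit = fit_line(synthetic_points("X", 0.0, 0.3, self.vs))
        assert (fit.slope, fit.r_squared) == (0.0, 0.0)
        assert fit.intercept == pytest.approx(0.3)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_line(synthetic_points("X", 0.1, 0.0, (0.2, 0.4)))

    def test_weighted_variant_agrees_on_exact_data(self):
        pts = synthetic_points("X", 0.05, 0.01, self.vs, se=1e-3)
        unweighted = fit_line(pts)
        weighted = fit_line(pts, weighted=True)
        assert weighted.slope == pytest.approx(unweighted.slope)
        assert weighted.intercept == pytest.approx(unweighted.intercept)

    def test_mixed_designs_rejected(self):
        pts = synthetic_points("X", 0.1, 0, self.vs) + synthetic_points(
            "Y", 0.1, 0, self.vs
        )
        with pytest.raises(ValueError):
            fit_line(pts)


class TestCompareDesigns:
    vs = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))

    def test_identical_designs_no_dominance_no_crossing(self):
        pts = synthetic_points("X", 0.02, 0.0, self.vs, se=1e-3)
        pts += synthetic_points("Y", 0.02, 0.0, self.vs, se=1e-3)
        report = compare_designs(points_frame(pts))
        assert not report.dominance.loc["X", "Y"]
        assert not report.dominance.loc["Y", "X"]
        assert report.crossings == []

    def test_clear_separation_is_dominance(self):
        pts = synthetic_points("S", 0.01, 0.0, self.vs, se=1e-4)
        pts += synthetic_points("R", 0.05, 0.01, self.vs, se=1e-4)
        report = compare_designs(points_frame(pts))
        assert report.dominance.loc["S", "R"]
        assert not report.dominance.loc["R", "S"]
        assert report.ranking == ["S", "R"]

    def test_resolvable_crossing_is_reported(self):
        pts = synthetic_points("X", 0.10, 0.00, self.vs, se=1e-4)
        pts += synthetic_points("Y", 0.01, 0.04, self.vs, se=1e-4)
        report = compare_designs(points_frame(pts))
        assert len(report.crossings) == 1
        a, b, vstar = report.crossings[0]
        assert {a, b} == {"X", "Y"}
        assert vstar == pytest.approx(0.04 / 0.09)

    def test_mismatched_grids_rejected(self):
        pts = synthetic_points("X", 0.1, 0.0, self.vs)
        pts += synthetic_points("Y", 0.1, 0.0, (0.2, 0.5, 0.8))
        with pytest.raises(ValueError):
            compare_designs(points_frame(pts))

    def test_report_renders(self):
        pts = synthetic_points("X", 0.02, 0.0, self.vs, se=1e-3)
        pts += synthetic_points("Y", 0.05, 0.0, self.vs, se=1e-3)
        text = compare_designs(points_frame(pts)).to_text()
        assert "ranking" in text and "X" in text


def test_fit_all_covers_every_design():
    table = sweep(tiny_config(trials_per_point=500))
    fits = fit_all(table)
    assert set(fits["design"]) == {"A", "C"}
    assert ((fits["r_squared"] >= 0) & (fits["r_squared"] <= 1)).all()


def test_fixed_targets_drive_the_sweep():
    cfg = tiny_config(
        designs=("C",), v_grid=(1.0,), trials_per_point=200,
        targets=FixedTargets.of("7"),
        operator=ErrorModel(per_class_error_prob=0.0),
    )
    assert estimate_risk("C", 1.0, cfg).risk == 0.0
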