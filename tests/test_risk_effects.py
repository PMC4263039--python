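"""Risk reductions, demographic weighting and cost consequences."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capicea.risk_effects import (
    OUTCOMES,
    SEXES,
    RiskEngineInput,
    RiskError,
    RiskProfile,
    absolute_risk_reduction,
    cost_consequence,
    reduction_grid,
    risk_source,
    weight_profile,
)

# Published risk grid: (outcome, sex) -> (intervention, comparator, printed ARR,
# printed cost consequence per 1% ARR).
PUBLISHED = {
    ("CHD", "male"): (9.92, 13.05, 3.13, 320.97),
    ("CHD", "female"): (5.36, 7.11, 1.76, 571.70),
    ("fatal_CHD", "male"): (6.06, 8.74, 2.68, 374.01),
    ("fatal_CHD", "female"): (3.28, 4.78, 1.50, 667.19),
    ("stroke", "male"): (6.40, 7.12, 0.72, 1397.88),
    ("stroke", "female"): (4.54, 5.05, 0.51, 1960.31),
    ("fatal_stroke", "male"): (0.83, 1.13, 0.30, 3345.60),
    ("fatal_stroke", "female"): (0.62, 0.82, 0.20, 5018.40),
}


class TestWeightProfile:
    def test_equal_weights_average(self):
        mean, _ = weight_profile([(6.06, 0, 0.5), (3.28, 0, 0.5)])
        assert mean == pytest.approx(4.67)

    def test_single_subgroup_identity(self):
        assert weight_profile([(8.74, 0.96, 1.0)]) == pytest.approx((8.74, 0.96))

    def test_weights_normalised(self):
        a = weight_profile([(6.0, 1.0, 2.0), (3.0, 0.5, 2.0)])
        b = weight_profile([(6.0, 1.0, 0.5), (3.0, 0.5, 0.5)])
        assert a == pytest.approx(b)

    def test_se_pooling_rule(self):
        # sqrt(0.5*1^2 + 0.5*0.5^2) with normalised weights
        _, se = weight_profile([(6.0, 1.0, 1.0), (3.0, 0.5, 1.0)])
        assert se == pytest.approx(math.sqrt(0.5 * 1 + 0.5 * 0.25))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(RiskError, match="zero"):
            weight_profile([(6.0, 0, 0.0), (3.0, 0, 0.0)])

    def test_empty_rejected(self):
        with pytest.raises(RiskError, match="at least one"):
            weight_profile([])


class TestAbsoluteRiskReduction:
    @pytest.mark.parametrize("outcome,sex", list(PUBLISHED))
    def test_fixture_arr_matches_rounded_means(self, risk_grid, outcome, sex):
        """ARR from the packaged grid equals the difference of its means.

        The printed CHD/female cell (1.76) disagrees with its own rounded
        means by 0.01; from the packaged (rounded) means the difference is
        exactly 1.75, so that cell alone is checked at 0.015.
        """
        rr = absolute_risk_reduction(
            risk_grid[("comparator", outcome, sex)], risk_grid[("intervention", outcome, sex)]
        )
        printed = PUBLISHED[(outcome, sex)][2]
        tol = 0.015 if (outcome, sex) == ("CHD", "female") else 1e-9
        assert rr.arr == pytest.approx(printed, abs=max(tol, 1e-9))

    def test_arr_and_rr_m_consistent(self, risk_grid):
        for (outcome, sex), rr in reduction_grid(risk_grid).items():
            comp = risk_grid[("comparator", outcome, sex)]
            assert rr.arr == pytest.approx(comp.mean_risk * (1 - rr.rr_m))

    def test_rr_m_scale_invariant(self):
        # expressing risks as percent or proportion leaves the ratio unchanged
        pct = absolute_risk_reduction(
            RiskProfile("comparator", "fatal_CHD", "male", 8.74),
            RiskProfile("intervention", "fatal_CHD", "male", 6.06),
        )
        prop = absolute_risk_reduction(
            RiskProfile("comparator", "fatal_CHD", "male", 0.0874),
            RiskProfile("intervention", "fatal_CHD", "male", 0.0606),
        )
        assert pct.rr_m == pytest.approx(prop.rr_m)

    def test_equal_profiles_give_null_effect(self):
        p = RiskProfile("comparator", "stroke", "male", 5.0)
        q = RiskProfile("intervention", "stroke", "male", 5.0)
        rr = absolute_risk_reduction(p, q)
        assert rr.arr == 0 and rr.rr_m == 1

    def test_zero_comparator_risk_rejected(self):
        with pytest.raises(RiskError, match="zero"):
            absolute_risk_reduction(
                RiskProfile("comparator", "stroke", "male", 0.0),
                RiskProfile("intervention", "stroke", "male", 0.0),
            )

    def test_mismatched_cells_rejected(self):
        with pytest.raises(RiskError, match="mismatched"):
            absolute_risk_reduction(
                RiskProfile("comparator", "stroke", "male", 5.0),
                RiskProfile("intervention", "stroke", "female", 4.0),
            )

    def test_swapped_arms_rejected(self):
        with pytest.raises(RiskError, match="order"):
            absolute_risk_reduction(
                RiskProfile("intervention", "stroke", "male", 5.0),
                RiskProfile("comparator", "stroke", "male", 4.0),
            )


class TestCostConsequence:
    @pytest.mark.parametrize("outcome,sex", list(PUBLISHED))
    def test_published_cost_consequences_within_1pct(
        self, cost_comparison, risk_grid, outcome, sex
    ):
        """Published values used unrounded ARRs; 1% relative tolerance."""
        rr = reduction_grid(risk_grid)[(outcome, sex)]
        cc = cost_consequence(cost_comparison, rr)
        assert cc.cost_per_pct_arr == pytest.approx(PUBLISHED[(outcome, sex)][3], rel=0.01)

    def test_unit_arr_returns_cost_difference(self, cost_comparison):
        from capicea.risk_effects import RiskReduction

        cc = cost_consequence(cost_comparison, RiskReduction("stroke", "male", 1.0, 0.9))
        assert cc.cost_per_pct_arr == pytest.approx(1003.68)

    def test_non_reducing_outcome_rejected(self, cost_comparison):
        from capicea.risk_effects import RiskReduction

        with pytest.raises(RiskError, match="not risk-reducing"):
            cost_consequence(cost_comparison, RiskReduction("stroke", "male", 0.0, 1.0))

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, cost_comparison, k_cost, arr):
        """Doubling the cost difference doubles the consequence; doubling ARR halves it."""
        from capicea.risk_effects import RiskReduction

        base = cost_consequence(cost_comparison, RiskReduction("stroke", "male", arr, 0.9))
        half = cost_consequence(
            cost_comparison, RiskReduction("stroke", "male", 2 * arr, 0.9)
        )
        assert half.cost_per_pct_arr == pytest.approx(base.cost_per_pct_arr / 2)


class TestRiskSource:
    def test_fixture_engine_covers_full_grid(self, risk_grid):
        assert len(risk_grid) == 16
        for key, (i_mean, c_mean, _, _) in PUBLISHED.items():
            outcome, sex = key
            assert risk_grid[("intervention", outcome, sex)].mean_risk == i_mean
            assert risk_grid[("comparator", outcome, sex)].mean_risk == c_mean

    def test_constant_engine_gives_null_reductions(self):
        def engine():
            return [
                RiskProfile(a, o, s, 5.0)
                for a in ("intervention", "comparator")
                for o in OUTCOMES
                for s in SEXES
            ]

        grid = risk_source(engine)
        assert all(rr.arr == 0 for rr in reduction_grid(grid).values())

    def test_incomplete_grid_rejected(self):
        def engine():
            return [
                RiskProfile(a, o, s, 5.0)
                for a in ("intervention", "comparator")
                for o in OUTCOMES
                for s in SEXES
                if not (o == "fatal_stroke" and s == "female")
            ]

        with pytest.raises(RiskError, match="incomplete"):
            risk_source(engine)

    def test_duplicate_cell_rejected(self):
        def engine():
            return [RiskProfile("comparator", "stroke", "male", 5.0)] * 2

        with pytest.raises(RiskError, match="duplicate"):
            risk_source(engine)


def test_risk_profile_validation():
    with pytest.raises(RiskError):
        RiskProfile("comparator", "stroke", "male", 101.0)
    with pytest.raises(RiskError):
        RiskProfile("comparator", "stroke", "male", 5.0, se=-1)
    with pytest.raises(RiskError):
        RiskProfile("comparator", "angina", "male", 5.0)


def test_engine_input_physiologic_ranges():
    ok = dict(
        mean_age=55,
        ethnicity="black_african",
        smoking_status="non_smoker",
        diabetes_duration=8,
        hba1c=8.8,
        sbp=140,
        total_cholesterol=5.2,
        hdl=1.1,
    )
    RiskEngineInput(**ok)
    with pytest.raises(RiskError, match="hba1c"):
        RiskEngineInput(**{**ok, "hba1c": 72})  # mmol/mol given where % expected
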