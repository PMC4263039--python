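"""Abridged life-table construction, cause decomposition and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capicea.lifetable import (
    AgeBand,
    HazardRatioSet,
    LifeTableError,
    MortalitySchedule,
    apply_intervention,
    band_to_q,
    build_life_table,
    decompose_mortality,
    default_bands,
    diabetic_cvd_mortality,
    life_years_gained,
)
from capicea.synthetic import single_year_person_years

BANDS = default_bands()


def schedule(m_total, m_ihd=None, m_stroke=None, sex="male"):
    m_total = np.asarray(m_total, float)
    if m_ihd is None:
        m_ihd = 0.1 * m_total
    if m_stroke is None:
        m_stroke = 0.1 * m_total
    return MortalitySchedule(sex, BANDS, m_total, np.asarray(m_ihd), np.asarray(m_stroke))


RATES = np.array([0.002, 0.004, 0.008, 0.016, 0.032, 0.1])


class TestDecomposition:
    def test_arithmetic(self):
        s = schedule([0.010] * 6, [0.001] * 6, [0.001] * 6)
        d = decompose_mortality(s)
        assert d.m_cvd == pytest.approx([0.002] * 6)
        assert d.m_other == pytest.approx([0.008] * 6)

    def test_no_cvd_means_other_equals_total(self):
        s = schedule(RATES, np.zeros(6), np.zeros(6))
        d = decompose_mortality(s)
        assert d.m_other == pytest.approx(RATES)

    def test_causes_exceeding_total_rejected(self):
        with pytest.raises(LifeTableError):
            schedule([0.010] * 6, [0.006] * 6, [0.006] * 6)

    def test_conservation_roundtrip(self):
        s = schedule(RATES)
        d = decompose_mortality(s)
        np.testing.assert_allclose(d.m_total, s.m_total, rtol=0, atol=1e-18)


class TestDiabeticCvdMortality:
    def test_cause_specific_multiplication(self):
        s = schedule([0.010] * 6, [0.002] * 6, [0.001] * 6)
        hr = HazardRatioSet(2.03, 2.54, 2.00, 2.04)
        d = diabetic_cvd_mortality(decompose_mortality(s), hr)
        assert d.m_ihd == pytest.approx([0.00406] * 6)
        assert d.m_stroke == pytest.approx([0.002] * 6)
        assert d.m_other == pytest.approx([0.007] * 6)

    def test_unit_hazard_ratios_are_identity(self):
        d = decompose_mortality(schedule(RATES))
        out = diabetic_cvd_mortality(d, HazardRatioSet(1, 1, 1, 1))
        np.testing.assert_allclose(out.m_total, d.m_total)

    def test_female_ratios_selected_by_sex(self):
        s = schedule([0.010] * 6, [0.002] * 6, [0.001] * 6, sex="female")
        d = diabetic_cvd_mortality(decompose_mortality(s), HazardRatioSet(2.03, 2.54, 2.00, 2.04))
        assert d.m_ihd == pytest.approx([0.002 * 2.54] * 6)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(LifeTableError):
            HazardRatioSet(0.0, 2.54, 2.00, 2.04)


class TestApplyIntervention:
    def test_pooled_scaling(self):
        d = decompose_mortality(schedule([0.010] * 6, [0.002] * 6, [0.002] * 6))
        out = apply_intervention(d, 0.69)
        assert out.m_cvd == pytest.approx([0.004 * 0.69] * 6)
        assert out.m_other == pytest.approx(d.m_other)

    def test_recomposition_total(self):
        # m_other 0.008 + 0.5 * m_cvd 0.004 recomposes to 0.010
        d = decompose_mortality(schedule([0.012] * 6, [0.002] * 6, [0.002] * 6))
        out = apply_intervention(d, 0.5)
        assert out.m_total == pytest.approx([0.010] * 6)

    def test_unit_ratio_is_identity(self):
        d = decompose_mortality(schedule(RATES))
        np.testing.assert_allclose(apply_intervention(d, 1.0).m_total, d.m_total)

    def test_cause_specific_ratios(self):
        d = decompose_mortality(schedule([0.010] * 6, [0.002] * 6, [0.001] * 6))
        out = apply_intervention(d, 0.5, 0.8)
        assert out.m_ihd == pytest.approx([0.001] * 6)
        assert out.m_stroke == pytest.approx([0.0008] * 6)

    def test_nonpositive_ratio_rejected(self):
        d = decompose_mortality(schedule(RATES))
        with pytest.raises(LifeTableError):
            apply_intervention(d, 0.0)


class TestBuildLifeTable:
    def test_band_death_probability_closed_form(self):
        # q = n*M / (1 + n*(1-a)*M) with a=0.5: 0.1/1.05
        assert band_to_q(0.01, 10) == pytest.approx(0.1 / 1.05)

    @pytest.mark.parametrize("m", [0.005, 0.01, 0.02, 0.05])
    def test_constant_hazard_matches_exponential_life_expectancy(self, m):
        """With a flat hazard M the analytic life expectancy is 1/M."""
        lt = build_life_table(np.full(6, m), radix=1.0)
        assert lt.e_x[0] == pytest.approx(1.0 / m, rel=0.03)

    def test_two_band_toy_against_single_year_oracle(self):
        bands = (AgeBand(25, 10), AgeBand(35, None))
        lt = build_life_table([0.02, 0.1], radix=1000.0, bands=bands)

        def rate(x):
            return 0.02 if x < 35 else 0.1

        oracle = 1000.0 * single_year_person_years(rate, start_age=25, max_age=120)
        assert lt.T_x[0] == pytest.approx(oracle, rel=0.02)

    def test_survivors_non_increasing_and_T_decreasing(self):
        lt = build_life_table(RATES, radix=1000.0)
        assert np.all(np.diff(lt.l_x) <= 0)
        assert np.all(np.diff(lt.T_x) < 0)

    def test_e_is_T_over_l(self):
        lt = build_life_table(RATES, radix=1000.0)
        np.testing.assert_allclose(lt.e_x, lt.T_x / lt.l_x)

    def test_radix_invariance(self):
        a = build_life_table(RATES, radix=1.0)
        b = build_life_table(RATES, radix=37654.0)
        np.testing.assert_allclose(a.e_x, b.e_x)
        np.testing.assert_allclose(b.T_x, 37654.0 * a.T_x)

    @given(st.integers(0, 5), st.floats(0.3, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_lowering_mortality_never_lowers_survival(self, band, factor):
        lowered = RATES.copy()
        lowered[band] *= factor
        base = build_life_table(RATES, radix=1.0)
        better = build_life_table(lowered, radix=1.0)
        assert np.all(better.e_x >= base.e_x - 1e-12)
        assert np.all(better.T_x >= base.T_x - 1e-12)

    def test_zero_open_band_rate_rejected(self):
        bad = RATES.copy()
        bad[-1] = 0.0
        with pytest.raises(LifeTableError, match="open-band"):
            build_life_table(bad, radix=1.0)

    def test_band_layout_validation(self):
        with pytest.raises(LifeTableError, match="contiguous"):
            build_life_table([0.01, 0.1], 1.0, bands=(AgeBand(25, 10), AgeBand(40, None)))
        with pytest.raises(LifeTableError, match="open"):
            build_life_table([0.01, 0.02], 1.0, bands=(AgeBand(25, 10), AgeBand(35, 10)))


class TestLifeYearsGained:
    def test_published_cohort_difference(self, published_lifetable):
        """Male cohort gain from the printed cumulative person-year columns."""
        row = published_lifetable.query("sex == 'male' and band_start == 25").iloc[0]
        assert row.T_intervention - row.T_comparator == 26484

    def test_identical_tables_give_zero(self):
        lt = build_life_table(RATES, radix=1.0)
        lyg, de = life_years_gained(lt, lt)
        assert lyg == 0 and np.all(de == 0)

    def test_lower_mortality_gains_years(self):
        base = build_life_table(RATES, radix=1.0)
        lowered = RATES.copy()
        lowered[2] *= 0.5
        better = build_life_table(lowered, radix=1.0)
        lyg, de = life_years_gained(better, base)
        assert lyg > 0
        assert np.all(de >= -1e-12)  # unaffected bands may carry fp noise

    def test_mismatched_bands_rejected(self):
        a = build_life_table(RATES, radix=1.0)
        b = build_life_table(
            [0.01, 0.1], radix=1.0, bands=(AgeBand(25, 10), AgeBand(35, None))
        )
        with pytest.raises(LifeTableError, match="band"):
            life_years_gained(a, b)

    def test_mismatched_radix_rejected(self):
        a = build_life_table(RATES, radix=1.0)
        b = build_life_table(RATES, radix=2.0)
        with pytest.raises(LifeTableError, match="radi"):
            life_years_gained(a, b)


class TestPublishedTableConsistency:
    def test_e25_is_T25_over_l25_on_printed_male_row(self, published_lifetable):
        row = published_lifetable.query("sex == 'male' and band_start == 25").iloc[0]
        assert round(row.T_comparator / row.l_comparator, 1) == 40.2
        assert round(row.T_intervention / row.l_intervention, 1) == 41.0

    def test_e_equals_T_over_l_within_rounding_everywhere(self, published_lifetable):
        for _, row in published_lifetable.iterrows():
            for arm in ("comparator", "intervention"):
                ratio = row[f"T_{arm}"] / row[f"l_{arm}"]
                assert ratio == pytest.approx(row[f"e_{arm}"], abs=0.06)
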