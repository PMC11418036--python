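"""Q-value engine: polynomials, plateaus, interpolation, rescaling, units."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrbench import (
    Concentration,
    UMOL_PER_MGDL,
    q_fixed,
    q_interpolated,
    q_lookup,
    q_poly_europe,
    rescale_creatinine,
)
from egfrbench.qvalues import QMode, QSpec, Sex, load_q_registry


class TestEuropePolynomial:
    @pytest.mark.parametrize("sex,plateau", [("F", 0.70), ("M", 0.90)])
    def test_levels_off_at_adult_plateau(self, sex, plateau):
        assert abs(q_poly_europe(25, sex).to_mg_dl() - plateau) <= 0.02

    def test_male_value_at_25_matches_hand_evaluation(self):
        # independent inline evaluation of the printed polynomial
        ln_q = 3.200 + 0.259 * 25 - 0.543 * math.log(25) - 0.00763 * 25**2 + 0.0000790 * 25**3
        assert q_poly_europe(25, "M").to_umol_l() == pytest.approx(math.exp(ln_q), rel=1e-12)
        assert round(q_poly_europe(25, "M").to_umol_l(), 2) == 80.86

    def test_natural_log_not_base10(self):
        # with log10 the male curve would sit near 2.5 mg/dL at 25, far off
        # the printed plateau; the implementation must stay below 1 mg/dL
        ln_q10 = 3.200 + 0.259 * 25 - 0.543 * math.log10(25) - 0.00763 * 25**2 + 0.0000790 * 25**3
        assert math.exp(ln_q10) / UMOL_PER_MGDL > 2.0
        assert q_poly_europe(25, "M").to_mg_dl() < 1.0

    @pytest.mark.parametrize("age", [1.9, 25.1, -3.0])
    def test_age_domain_is_enforced(self, age):
        with pytest.raises(ValueError, match=r"\[2, 25\]"):
            q_poly_europe(age, "F")

    def test_positive_and_sex_ordered_on_grid(self):
        ages = np.linspace(2, 25, 120)
        for age in ages:
            assert q_poly_europe(age, "M").value > 0
            assert q_poly_europe(age, "F").value > 0
        for age in np.linspace(12, 25, 60):
            assert q_poly_europe(age, "M").value >= q_poly_europe(age, "F").value


class TestFixedQ:
    @pytest.mark.parametrize(
        "population,sex,expected",
        [("us", "M", 0.97), ("us", "F", 0.73), ("europe", "F", 0.70), ("europe", "M", 0.90)],
    )
    def test_adult_plateaus(self, population, sex, expected):
        spec = load_q_registry()[population]
        assert q_fixed(sex, spec).to_mg_dl() == pytest.approx(expected)

    def test_female_below_male_for_all_builtin_specs(self):
        for spec in load_q_registry().values():
            assert spec.adult_plateau_by_sex[Sex.FEMALE] < spec.adult_plateau_by_sex[Sex.MALE]


class TestInterpolatedQ:
    @pytest.mark.parametrize("sex,plateau", [("M", 0.97), ("F", 0.73)])
    def test_meets_adult_plateau_exactly_at_25(self, us_spec, sex, plateau):
        assert q_interpolated(25, sex, us_spec).to_mg_dl() == pytest.approx(plateau, rel=1e-12)

    @pytest.mark.parametrize("sex", ["M", "F"])
    def test_equals_reference_curve_at_and_below_12(self, us_spec, sex):
        for age in (5.0, 12.0):
            assert q_interpolated(age, sex, us_spec).to_umol_l() == pytest.approx(
                q_poly_europe(age, sex).to_umol_l(), rel=1e-12
            )

    def test_midpoint_factor_is_linear_in_age(self, us_spec):
        # at 18.5 y the multiplication factor is halfway between 1 and the ratio
        ref = q_poly_europe(18.5, "M").to_umol_l()
        ref25 = q_poly_europe(25, "M").to_umol_l()
        expected = ref * (1 + 0.5 * (0.97 * UMOL_PER_MGDL / ref25 - 1))
        assert q_interpolated(18.5, "M", us_spec).to_umol_l() == pytest.approx(expected, rel=1e-12)

    def test_missing_reference_is_a_configuration_error(self, europe_spec):
        with pytest.raises(ValueError, match="reference"):
            q_interpolated(18, "M", europe_spec)


class TestLookupDispatch:
    def test_adult_age_returns_plateau(self, europe_spec):
        assert q_lookup(40, "M", europe_spec).to_mg_dl() == pytest.approx(0.9)

    def test_infancy_is_rejected(self, europe_spec):
        with pytest.raises(ValueError, match="minimum"):
            q_lookup(1.5, "F", europe_spec)

    def test_fixed_mode_uses_plateau_below_25(self, europe_spec):
        assert q_lookup(20, "F", europe_spec, QMode.FIXED).to_mg_dl() == pytest.approx(0.7)

    def test_us_curve_continuous_at_25(self, us_spec):
        for eps in (1e-3, 1e-6):
            below = q_lookup(25 - eps, "F", us_spec).to_mg_dl()
            above = q_lookup(25 + eps, "F", us_spec).to_mg_dl()
            assert abs(below - above) < 10 * eps + 1e-9

    def test_europe_continuous_at_25_within_rounding(self, europe_spec):
        gap = abs(q_lookup(25, "M", europe_spec).to_mg_dl() - q_lookup(25.0001, "M", europe_spec).to_mg_dl())
        assert gap <= 0.02

    def test_curve_positive_up_to_old_age(self, us_spec, europe_spec):
        for spec in (us_spec, europe_spec):
            for age in np.linspace(2, 100, 99):
                assert q_lookup(age, "M", spec).to_umol_l() > 0

    def test_value_at_20_between_q12_and_q25(self, europe_spec):
        q12 = q_lookup(12, "M", europe_spec).to_umol_l()
        q25 = q_lookup(25, "M", europe_spec).to_umol_l()
        q20 = q_lookup(20, "M", europe_spec).to_umol_l()
        assert min(q12, q25) < q20 < max(q12, q25)


class TestRescaling:
    @pytest.mark.parametrize(
        "scr,q,expected",
        [
            (Concentration.mg_dl(0.90), Concentration.mg_dl(0.90), 1.0),
            (Concentration.umol_l(79.56), Concentration.mg_dl(0.90), 1.0),
            (Concentration.mg_dl(1.35), Concentration.mg_dl(0.90), 1.5),
        ],
    )
    def test_units_reconciled_before_division(self, scr, q, expected):
        assert rescale_creatinine(scr, q) == pytest.approx(expected, rel=1e-12)

    def test_bare_numbers_are_refused(self):
        with pytest.raises(TypeError):
            rescale_creatinine(1.0, Concentration.mg_dl(0.9))

    @given(st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_unit_roundtrip_stable(self, mg_dl):
        c = Concentration.mg_dl(mg_dl)
        back = Concentration.umol_l(c.to_umol_l()).to_mg_dl()
        assert back == pytest.approx(mg_dl, rel=1e-9)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            Concentration.umol_l(0.0)


class TestSpecValidation:
    def test_spec_without_curve_or_reference_rejected(self):
        with pytest.raises(ValueError):
            QSpec("broken", None, {Sex.FEMALE: 0.7, Sex.MALE: 0.9}, None)

    def test_female_plateau_must_be_below_male(self):
        with pytest.raises(ValueError):
            QSpec("inverted", None, {Sex.FEMALE: 1.0, Sex.MALE: 0.9},
                  load_q_registry()["europe"])
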