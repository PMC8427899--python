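"""Fuel-property correlations: closed-form oracles, linearity, monotonicity,
normalization-mode semantics and standards compliance."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import mycofuel.fuel as fuel
from mycofuel.datasets import sww_day6_profile
from mycofuel.fame import FAME_REGISTRY, FameError, build_profile
from mycofuel.fuel import (
    cetane_number,
    check_compliance,
    cloud_point,
    cold_filter_plugging_point,
    compute_report,
    degree_of_unsaturation,
    density,
    higher_heating_value,
    iodine_value,
    kinematic_viscosity,
    load_standard_limits,
    long_chain_saturated_factor,
    oxidative_stability,
    pour_point,
    saponification_value,
)


def _pure(code):
    return build_profile([(code, 100.0)])


def _kv_term(mw, d):
    return math.exp(-12.503 + 2.496 * math.log(mw) - 0.178 * d)


class TestSingleSpeciesClosedForms:
    """A 100 % pure profile must equal the per-ester closed form."""

    @pytest.mark.parametrize("code", ["C16:0", "C18:0", "C18:1", "C18:3"])
    def test_kinematic_viscosity(self, code):
        fa = FAME_REGISTRY[code]
        assert kinematic_viscosity(_pure(code)) == pytest.approx(
            _kv_term(fa.mw_fame, fa.double_bonds), rel=1e-12
        )

    def test_kv_oleate_value(self):
        assert kinematic_viscosity(_pure("C18:1")) == pytest.approx(
            4.60, abs=0.01
        )

    def test_density_oleate(self):
        assert density(_pure("C18:1")) == pytest.approx(0.8746, abs=1e-4)

    def test_hhv_stearate_and_linolenate(self):
        assert higher_heating_value(_pure("C18:0")) == pytest.approx(
            40.18, abs=0.01
        )
        assert higher_heating_value(_pure("C18:3")) == pytest.approx(
            39.43, abs=0.01
        )

    def test_sv_stearate_and_palmitate(self):
        assert saponification_value(_pure("C18:0")) == pytest.approx(
            187.60, abs=0.01
        )
        assert saponification_value(_pure("C16:0")) == pytest.approx(
            207.06, abs=0.01
        )

    def test_iv_oleate(self):
        assert iodine_value(_pure("C18:1")) == pytest.approx(85.67, abs=0.01)

    def test_iv_saturated_is_zero(self):
        p = build_profile([("C16:0", 40), ("C18:0", 50), ("C20:0", 10)])
        assert iodine_value(p) == 0.0


class TestMixing:
    def test_kv_log_linear_mixing(self):
        """Equal halves mix to the geometric mean of the pure values."""
        half = build_profile([("C18:0", 50), ("C18:1", 50)])
        pure0 = kinematic_viscosity(_pure("C18:0"))
        pure1 = kinematic_viscosity(_pure("C18:1"))
        assert kinematic_viscosity(half) == pytest.approx(
            math.sqrt(pure0 * pure1), rel=1e-12
        )

    @given(scale=st.floats(0.1, 1.0))
    def test_linear_properties_scale_with_total(self, scale):
        """rho, HHV, SV, IV, LCSF are linear in the weight-percents."""
        base = [("C18:0", 40.0), ("C18:1", 30.0), ("C18:2", 20.0)]
        p1 = build_profile(base)
        p2 = build_profile([(c, w * scale) for c, w in base])
        for f in (density, higher_heating_value, saponification_value,
                  iodine_value, long_chain_saturated_factor):
            assert f(p2) == pytest.approx(scale * f(p1), rel=1e-9)

    @given(scale=st.floats(0.1, 1.0))
    def test_renormalized_mode_scale_invariant(self, scale):
        base = [("C18:0", 40.0), ("C18:1", 30.0), ("C18:2", 20.0)]
        p1 = build_profile(base, mode="renormalized")
        p2 = build_profile(
            [(c, w * scale) for c, w in base], mode="renormalized"
        )
        for f in (kinematic_viscosity, density, saponification_value,
                  iodine_value, long_chain_saturated_factor):
            assert f(p2) == pytest.approx(f(p1), rel=1e-9)

    def test_sww_day6_iv(self):
        assert iodine_value(sww_day6_profile()) == pytest.approx(
            34.49, abs=0.01
        )


class TestScalarCorrelations:
    @pytest.mark.parametrize(
        "sv,iv,expected",
        [(142.10, 27.85, 78.44), (127.25, 30.52, 82.32), (5458.0, 0.0, 47.3)],
    )
    def test_cetane_number(self, sv, iv, expected):
        assert cetane_number(sv, iv) == pytest.approx(expected, abs=0.005)

    def test_cetane_requires_positive_sv(self):
        with pytest.raises(FameError):
            cetane_number(0.0, 10.0)

    @pytest.mark.parametrize(
        "mufa,pufa,expected",
        [(16.23, 4.82, 25.87), (9.62, 10.87, 31.36), (0, 0, 0)],
    )
    def test_degree_of_unsaturation(self, mufa, pufa, expected):
        assert degree_of_unsaturation(mufa, pufa) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "c2,c3,expected",
        [(0, 0, 45.52), (19.12, 9.09, 3.83), (12.81, 0, 7.66)],
    )
    def test_oxidative_stability(self, c2, c3, expected):
        assert oxidative_stability(c2, c3) == pytest.approx(expected, abs=0.005)

    def test_lcsf_cases(self):
        assert long_chain_saturated_factor(
            build_profile([("C18:1", 50)])
        ) == 0.0
        assert long_chain_saturated_factor(
            sww_day6_profile()
        ) == pytest.approx(32.50, abs=0.005)
        assert long_chain_saturated_factor(
            build_profile([("C22:0", 10)])
        ) == pytest.approx(15.0)

    def test_cold_flow_linear_forms(self):
        assert cold_filter_plugging_point(0) == pytest.approx(-16.477)
        assert cold_filter_plugging_point(32.50) == pytest.approx(
            85.63, abs=0.005
        )
        assert cold_filter_plugging_point(5.246) == pytest.approx(0.0, abs=0.01)
        assert cloud_point(0) == pytest.approx(-4.992)
        assert pour_point(0) == pytest.approx(-12.24)
        assert cloud_point(2.65) == pytest.approx(-3.60, abs=0.005)
        assert pour_point(2.65) == pytest.approx(-10.73, abs=0.005)
        assert cloud_point(0.95) == pytest.approx(-4.49, abs=0.005)
        assert pour_point(0.95) == pytest.approx(-11.70, abs=0.005)


class TestMonotonicity:
    @given(
        sv=st.floats(100, 250),
        iv1=st.floats(0, 100),
        delta=st.floats(0.1, 50),
    )
    def test_cn_decreases_in_iv(self, sv, iv1, delta):
        assert cetane_number(sv, iv1 + delta) < cetane_number(sv, iv1)

    @given(total=st.floats(0, 60), delta=st.floats(0.1, 30))
    def test_os_decreases_in_pufa(self, total, delta):
        assert oxidative_stability(total + delta, 0) < oxidative_stability(
            total, 0
        )

    @given(x=st.floats(0, 60), delta=st.floats(0.1, 30))
    def test_cold_flow_increase_in_saturates(self, x, delta):
        assert cold_filter_plugging_point(x + delta) > (
            cold_filter_plugging_point(x)
        )
        assert cloud_point(x + delta) > cloud_point(x)
        assert pour_point(x + delta) > pour_point(x)


class TestReport:
    def test_pure_stearate_chain(self):
        rep = compute_report(_pure("C18:0"))
        assert rep.sv == pytest.approx(187.60, abs=0.01)
        assert rep.iv == 0.0
        assert rep.cn == pytest.approx(75.39, abs=0.01)

    def test_sww_day6_chain(self):
        rep = compute_report(sww_day6_profile())
        assert rep.iv == pytest.approx(34.49, abs=0.01)
        assert rep.lcsf == pytest.approx(32.50, abs=0.01)
        assert rep.du == pytest.approx(40.05, abs=0.01)
        assert rep.kv > 0 and rep.density > 0 and rep.os > 0
        assert rep.flags == {}

    def test_du_identity_against_aggregates(self):
        p = sww_day6_profile()
        rep = compute_report(p)
        assert rep.du == pytest.approx(p.mufa + 2 * p.pufa, abs=1e-12)

    def test_empty_profile_is_structured_error(self):
        with pytest.raises(FameError, match="no FAME entries"):
            build_profile([])

    def test_partial_total_scales_density(self):
        """An open mass balance scales density proportionally in
        as-reported mode (the convention partial GC reports use)."""
        p = sww_day6_profile()  # total 92.98 %
        full = sww_day6_profile(mode="renormalized")
        assert density(p) == pytest.approx(
            density(full) * p.total_percent / 100.0, rel=1e-9
        )


@pytest.fixture(scope="module")
def limits():
    return load_standard_limits()


class TestCompliance:

    def test_cn_pass_against_indian_standard(self, limits):
        rep = compute_report(sww_day6_profile())
        df = check_compliance(rep, limits["IS 15607"])
        row = df.set_index("property").loc["cn"]
        assert row["verdict"] == "pass"
        assert row["minimum"] == 51.0

    def test_low_density_fails(self, limits):
        rep = compute_report(sww_day6_profile())
        assert rep.density < 0.86
        df = check_compliance(rep, limits["EN 14214"])
        assert df.set_index("property").loc["density", "verdict"] == "fail"

    def test_hhv_not_specified_anywhere(self, limits):
        rep = compute_report(sww_day6_profile())
        for sid in ("ASTM D6751", "EN 14214", "IS 15607"):
            df = check_compliance(rep, limits[sid])
            assert (
                df.set_index("property").loc["hhv", "verdict"]
                == "not_specified"
            )

    def test_sv_unregulated(self, limits):
        rep = compute_report(sww_day6_profile())
        for sid in limits:
            df = check_compliance(rep, limits[sid])
            assert (
                df.set_index("property").loc["sv", "verdict"]
                == "not_specified"
            )

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError, match="min .* max"):
            fuel.StandardLimits("X", {"cn": {"min": 60, "max": 50}})
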