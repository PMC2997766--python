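"""Right-heart formulas: Bernoulli pressures, RAP lookup, PVR, conversions."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemostress import (
    bernoulli_gradient,
    convert_resistance,
    mean_pa_pressure,
    pa_diastolic_pressure,
    pa_pulse_pressure,
    pulmonary_vascular_capacitance,
    pvr_doppler,
    pvr_invasive,
    right_atrial_pressure,
    rv_systolic_pressure,
)

velocity = st.floats(min_value=0.0, max_value=8.0, allow_nan=False)
rap_values = st.floats(min_value=0.0, max_value=25.0, allow_nan=False)


class TestRightAtrialPressure:
    @pytest.mark.parametrize(
        "diameter, collapse, rap, low, high",
        [
            (1.8, 0.60, 3, 0, 5),  # small, collapsing: normal RA pressure
            (2.5, 0.30, 15, 10, 20),  # dilated, non-collapsing: high
            (2.5, 0.60, 8, 5, 10),  # indeterminate pattern: intermediate
            (1.8, 0.30, 8, 5, 10),  # the other indeterminate pattern
            (2.1, 0.50, 3, 0, 5),  # both boundaries: small+collapsing branch
        ],
    )
    def test_lookup(self, diameter, collapse, rap, low, high):
        est = right_atrial_pressure(diameter, collapse)
        assert est.rap == rap
        assert (est.low, est.high) == (low, high)

    @given(
        diameter=st.floats(min_value=0.5, max_value=4.0, allow_nan=False),
        collapse=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_lookup_total(self, diameter, collapse):
        """Every (diameter, collapse) pair maps to exactly one of {3, 8, 15}."""
        assert right_atrial_pressure(diameter, collapse).rap in {3.0, 8.0, 15.0}


class TestBernoulliPressures:
    @pytest.mark.parametrize("v, expected", [(0, 0), (1, 4), (2.8, 31.36)])
    def test_gradient(self, v, expected):
        assert bernoulli_gradient(v) == pytest.approx(expected)

    @given(v1=velocity, v2=velocity)
    def test_gradient_monotone_in_velocity(self, v1, v2):
        if v1 < v2:
            assert bernoulli_gradient(v1) < bernoulli_gradient(v2) or v1 == v2

    @pytest.mark.parametrize(
        "trv, rap, expected", [(0, 3, 3), (3.0, 3, 39), (2.5, 8, 33)]
    )
    def test_rvsp(self, trv, rap, expected):
        assert rv_systolic_pressure(trv, rap) == pytest.approx(expected)

    @pytest.mark.parametrize("v, rap, expected", [(0, 8, 8), (1.0, 3, 7), (1.5, 8, 17)])
    def test_padp(self, v, rap, expected):
        assert pa_diastolic_pressure(v, rap) == pytest.approx(expected)

    def test_mpap_standard_and_doppler(self):
        std, dop = mean_pa_pressure(spap=25, padp=10)
        assert std == pytest.approx(15.0)
        assert dop is None
        std, dop = mean_pa_pressure(spap=20, padp=20)
        assert std == pytest.approx(20.0)  # degenerate equality
        std, dop = mean_pa_pressure(pr_peak_velocity=1.8, rap=3)
        assert std is None
        assert dop == pytest.approx(15.96)

    def test_mpap_doppler_without_rap_term(self):
        _, dop = mean_pa_pressure(pr_peak_velocity=1.8, rap=3, add_rap=False)
        assert dop == pytest.approx(12.96)

    def test_mpap_rejects_inverted_pressures(self):
        with pytest.raises(ValueError):
            mean_pa_pressure(spap=10, padp=25)

    @pytest.mark.parametrize("trv, predv, expected", [(2.0, 2.0, 0.0), (3.0, 1.0, 32.0)])
    def test_papp(self, trv, predv, expected):
        assert pa_pulse_pressure(trv, predv) == pytest.approx(expected)

    def test_papp_rejects_inconsistent_jets(self):
        with pytest.raises(ValueError, match="inconsistent"):
            pa_pulse_pressure(1.0, 2.0)

    @given(trv=velocity, predv=velocity, rap=rap_values)
    def test_papp_equals_spap_minus_padp(self, trv, predv, rap):
        """The RAP terms cancel: PAPP == SPAP − PADP for any common RAP."""
        if predv > trv:
            return
        papp = pa_pulse_pressure(trv, predv)
        diff = rv_systolic_pressure(trv, rap) - pa_diastolic_pressure(predv, rap)
        assert papp == pytest.approx(diff, rel=1e-12, abs=1e-9)


class TestVascularResistance:
    @pytest.mark.parametrize(
        "mpap, pcwp, co, expected", [(18, 18, 5, 0), (15, 5, 5.0, 160), (40, 12, 4.0, 560)]
    )
    def test_pvr_invasive(self, mpap, pcwp, co, expected):
        assert pvr_invasive(mpap, pcwp, co) == pytest.approx(expected)

    def test_pvr_invasive_rejects_wedge_above_mpap(self):
        with pytest.raises(ValueError):
            pvr_invasive(10, 12, 5)

    @pytest.mark.parametrize(
        "trv, tvi, wood, reliable, severity",
        [
            (2.0, 20, 1.0, True, "normal"),
            (3.0, 10, 3.0, True, "intermediate"),  # at the significant-PH threshold
            (3.5, 10, 3.5, True, "significant_ph"),
            (4.5, 5, 9.0, False, "significant_ph"),
        ],
    )
    def test_pvr_doppler(self, trv, tvi, wood, reliable, severity):
        est = pvr_doppler(trv, tvi)
        assert est.wood == pytest.approx(wood)
        assert est.reliable is reliable
        assert est.severity == severity

    @pytest.mark.parametrize("sv, papp, expected", [(32, 32, 1.0), (70, 20, 3.5), (45, 30, 1.5)])
    def test_pvc(self, sv, papp, expected):
        assert pulmonary_vascular_capacitance(sv, papp) == pytest.approx(expected)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value, src, dst, expected",
        [
            (3, "wood", "dyn", 240),
            (1.5, "wood", "dyn", 120),
            (80, "dyn", "wood", 1.0),
            (100, "dyn", "wood", 1.25),
            (3, "wood", "mpa", 24),
            (900, "dyn", "mpa", 90),  # dyn->MPa is a factor of 10 via Wood
            (100, "dyn", "mpa", 10),
            (10, "mpa", "dyn", 100),
            (7, "wood", "wood", 7),
        ],
    )
    def test_printed_conversions(self, value, src, dst, expected):
        assert convert_resistance(value, src, dst) == pytest.approx(expected)
        assert float(convert_resistance(value, src, dst)) == expected  # exact here

    @given(
        value=st.fractions(min_value=0, max_value=10**6, max_denominator=10**6),
        path=st.permutations(["wood", "dyn", "mpa"]),
    )
    def test_round_trip_exact_for_rationals(self, value, path):
        """Factors are exact integer ratios, so rational round trips are identities."""
        x = value
        for src, dst in zip(path, path[1:] + [path[0]]):
            x = convert_resistance(x, src, dst)
        assert x == value

    @given(value=st.floats(min_value=1e-3, max_value=1e6, allow_nan=False))
    def test_round_trip_floats_within_rounding(self, value):
        back = convert_resistance(convert_resistance(value, "wood", "dyn"), "dyn", "wood")
        assert back == pytest.approx(value, rel=1e-15)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unknown resistance unit"):
            convert_resistance(1.0, "wood", "psi")
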