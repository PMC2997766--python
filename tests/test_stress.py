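"""Cross-stage operations: cycle length, panels, FFR, deltas, consistency."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemostress import (
    EngineConfig,
    compare_stages,
    cycle_length,
    derive_panel,
    exercise_spap_flag,
    force_frequency,
    mpap_consistency,
    percent_change,
    sv_decomposition,
)
from hemostress.stress_analysis import PANEL_PARAMETERS

# printed cycle-duration table entries that 60000/HR reproduces exactly
CYCLE_TABLE = {
    50: 1200, 60: 1000, 70: 857, 80: 750, 100: 600, 110: 545, 120: 500,
    140: 429, 150: 400, 160: 375, 170: 353, 180: 333,
}


class TestCycleLength:
    @pytest.mark.parametrize("hr, expected", sorted(CYCLE_TABLE.items()))
    def test_printed_table(self, hr, expected):
        assert cycle_length(hr) == expected

    def test_half_away_from_zero_rounding(self):
        # printed table has 666 at 90 and 463 at 130; the formula rounds
        # 666.67 -> 667 and 461.54 -> 462 (table entries treated as typos)
        assert cycle_length(90) == 667
        assert cycle_length(130) == 462

    def test_figure_value_75bpm(self):
        assert cycle_length(75) == 800

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cycle_length(0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "rest, peak, expected", [(7.0, 7.0, 0.0), (50, 100, 100.0), (80, 60, -25.0)]
    )
    def test_values(self, rest, peak, expected):
        assert percent_change(rest, peak) == pytest.approx(expected)

    def test_zero_rest_not_computable(self):
        assert percent_change(0.0, 10.0) is None


class TestForceFrequency:
    @pytest.mark.parametrize(
        "series, shape, chr_",
        [
            ([(60, 5), (100, 7), (140, 9)], "up_sloping", 140),
            ([(60, 5), (100, 7), (140, 5)], "flat_or_negative", 100),
            ([(60, 5), (100, 9), (140, 7)], "biphasic", 100),
            ([(60, 5), (140, 4)], "flat_or_negative", 60),
            ([(60, 5), (140, 6)], "up_sloping", 140),
            # peak equals an intermediate (not strictly above all): biphasic
            ([(60, 5), (100, 7), (140, 7)], "biphasic", 100),
            # ties in the maximum take the earliest stage
            ([(60, 7), (100, 7), (140, 5)], "flat_or_negative", 60),
        ],
    )
    def test_three_way_rule(self, series, shape, chr_):
        result = force_frequency(series)
        assert result.shape == shape
        assert result.critical_heart_rate == chr_

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            force_frequency([(60, 5)])

    @given(
        values=st.lists(st.floats(min_value=0.1, max_value=50, allow_nan=False), min_size=2, max_size=6),
        scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_invariant_to_uniform_scaling(self, values, scale):
        series = [(60 + 20 * i, v) for i, v in enumerate(values)]
        scaled = [(hr, v * scale) for hr, v in series]
        a, b = force_frequency(series), force_frequency(scaled)
        assert a.shape == b.shape
        assert a.critical_heart_rate == b.critical_heart_rate


class TestSVDecomposition:
    @pytest.mark.parametrize(
        "rest, peak, expected",
        [
            ((120, 50), (130, 40), (50.0, 50.0)),
            ((120, 50), (120, 30), (0.0, 100.0)),
            ((120, 50), (135, 45), (75.0, 25.0)),
        ],
    )
    def test_worked_values(self, rest, peak, expected):
        assert sv_decomposition(rest, peak) == pytest.approx(expected)

    def test_zero_delta_not_computable(self):
        assert sv_decomposition((120, 50), (130, 60)) is None

    @given(
        edv_r=st.floats(min_value=60, max_value=250, allow_nan=False),
        esv_r=st.floats(min_value=10, max_value=59, allow_nan=False),
        edv_p=st.floats(min_value=60, max_value=250, allow_nan=False),
        esv_p=st.floats(min_value=10, max_value=59, allow_nan=False),
    )
    def test_contributions_sum_to_100(self, edv_r, esv_r, edv_p, esv_p):
        out = sv_decomposition((edv_r, esv_r), (edv_p, esv_p))
        if out is not None:
            assert out[0] + out[1] == pytest.approx(100.0, rel=1e-9, abs=1e-9)


class TestExerciseSPAP:
    @pytest.mark.parametrize(
        "spap, athlete, expected",
        [
            (40, False, "normal"),
            (50, False, "abnormal"),
            (55, True, "may_be_physiologic"),
            (40, True, "normal"),
            (65, True, "abnormal"),
        ],
    )
    def test_flag(self, spap, athlete, expected):
        assert exercise_spap_flag(spap, athlete) == expected


class TestMPAPConsistency:
    @pytest.mark.parametrize(
        "std, dop, consistent, diff",
        [(15, 15, True, 0.0), (15, 22, False, 7.0), (20, 17, True, 3.0)],
    )
    def test_default_tolerance(self, std, dop, consistent, diff):
        note = mpap_consistency(std, dop)
        assert note.consistent is consistent
        assert note.difference == pytest.approx(diff)


class TestDerivePanel:
    def test_full_record_populates_every_parameter(self, full_stage, subject):
        panel = derive_panel(full_stage, subject)
        assert set(panel.values) >= set(PANEL_PARAMETERS)
        assert panel.not_computable == {}

    def test_totality_with_and_without_inputs(self, subject, full_stage):
        stripped = dataclasses.replace(full_stage, tr_velocity=None)
        panel = derive_panel(stripped, subject)
        for name in PANEL_PARAMETERS:
            assert (name in panel.values) != (name in panel.not_computable)

    def test_missing_tr_velocity_disables_dependents(self, subject, full_stage):
        stripped = dataclasses.replace(full_stage, tr_velocity=None)
        panel = derive_panel(stripped, subject)
        for name in ("spap", "papp", "pvr_wood", "tr_gradient"):
            assert name in panel.not_computable
            assert "tr_velocity" in panel.not_computable[name]
        assert "pvc" in panel.not_computable  # transitively, via PAPP
        assert "padp" in panel.values  # PR-based values unaffected

    def test_missing_ivc_disables_rap_dependents(self, subject, full_stage):
        stripped = dataclasses.replace(full_stage, ivc_diameter=None, ivc_collapse=None)
        panel = derive_panel(stripped, subject)
        for name in ("rap", "spap", "padp", "mpap_standard", "mpap_doppler"):
            assert name in panel.not_computable
        assert "papp" in panel.values  # RAP cancels out of the pulse pressure

    def test_normal_fixture_rest_svr_in_normal_band(self):
        from hemostress import make_fixture

        case = make_fixture("normal", 1)
        panel = derive_panel(case.rest, case.subject)
        # recompute by hand from the stage's raw measurements
        sv = case.rest.edv - case.rest.esv
        co = case.rest.heart_rate * sv / 1000.0
        map_ = (case.rest.sbp - case.rest.dbp) / 3.0 + case.rest.dbp
        assert panel.values["svr"] == pytest.approx(80 * (map_ - 5) / co, rel=1e-9)
        assert 900 <= panel.values["svr"] <= 1300
        assert "svr" not in panel.flags

    def test_ees_pressure_convention_switch(self, subject, full_stage):
        default = derive_panel(full_stage, subject)
        raw_sbp = derive_panel(full_stage, subject, EngineConfig(ees_pressure="sbp"))
        assert raw_sbp.values["ees_index"] == pytest.approx(
            default.values["ees_index"] / 0.9, rel=1e-12
        )


class TestCompareStages:
    def test_pct_change_zero_for_equal_values(self, minimal_case):
        comparison = compare_stages(minimal_case)
        assert comparison.pct_changes["bsa"] == 0.0  # BSA is a rest-only quantity

    def test_deltas_match_panels(self, minimal_case):
        comparison = compare_stages(minimal_case)
        for name, delta in comparison.deltas.items():
            assert delta == pytest.approx(
                comparison.peak.values[name] - comparison.rest.values[name]
            )

    def test_ffr_uses_raw_systolic_pressure(self, minimal_case):
        comparison = compare_stages(minimal_case)
        assert comparison.ffr is not None
        (hr0, v0), (hr1, v1) = comparison.ffr.sp_esvi_by_stage
        bsa = comparison.rest.values["bsa"]
        assert v0 == pytest.approx(120 / (50 / bsa))
        assert v1 == pytest.approx(170 / (35 / bsa))
        assert comparison.ffr.shape == "up_sloping"

    def test_sv_decomposition_present(self, minimal_case):
        edv_c, esv_c = compare_stages(minimal_case).sv_decomposition
        assert edv_c + esv_c == pytest.approx(100.0)
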