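"""Scenario pipeline: joints, cell phases, experimental/fitted phases, prediction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavedecision import (
    BinaryScenario,
    ConfigurationError,
    InvalidInputError,
    MissingObservationError,
    PhaseFitRule,
    analyze,
    cell_joints,
    experimental_phase,
    fitted_phase,
    known_condition_phases,
    min_conditional_rule,
    predict_unknown,
    preset_rule,
)
from wavedecision.fixtures import fixture_scenarios, load_fixture
from wavedecision.scenario import read_scenarios, scenarios_to_frame, write_scenarios


def wide_face_scenario(p_unknown=0.39):
    """First categorization study, wide faces: the published worked example."""
    return BinaryScenario(
        study_id="CD1-W",
        paradigm="categorization_wide",
        p_cond_pos=0.84,
        p_ref_given_pos=1 - 0.35,  # reference decision = withdraw
        p_ref_given_neg=1 - 0.52,
        p_focal_unknown=p_unknown,
        focal_decision="alternative",
    )


def gambling_scenario():
    """First two-stage gambling experiment."""
    return BinaryScenario(
        study_id="G1",
        paradigm="gambling",
        p_cond_pos=0.5,
        p_ref_given_pos=0.69,
        p_ref_given_neg=0.57,
        p_focal_unknown=0.38,
        focal_decision="reference",
    )


class TestCellJoints:
    def test_wide_face_joints(self):
        joints = cell_joints(wide_face_scenario())
        assert joints.joint("alternative", "positive") == pytest.approx(0.84 * 0.35)
        assert joints.decision_marginals["alternative"] == pytest.approx(0.3772)
        assert joints.decision_marginals["reference"] == pytest.approx(0.6228)

    def test_gambling_joints(self):
        joints = cell_joints(gambling_scenario())
        assert joints.joint("reference", "positive") == pytest.approx(0.345)
        assert joints.joint("reference", "negative") == pytest.approx(0.285)

    def test_joints_sum_to_one(self):
        joints = cell_joints(wide_face_scenario())
        assert sum(joints.joints.values()) == pytest.approx(1.0, abs=1e-12)

    def test_certain_condition_zeroes_negative_joints(self):
        s = BinaryScenario("x", "custom", 1.0, 0.4, 0.7)
        joints = cell_joints(s)
        assert joints.joint("reference", "negative") == 0.0
        assert joints.joint("alternative", "negative") == 0.0


class TestKnownConditionPhases:
    def test_gambling_cell_phases(self):
        table = known_condition_phases(gambling_scenario())
        assert round(table.theta(1), 2) == 134.37
        assert round(table.theta(2), 2) == 146.22
        assert round(table.theta(3), 2) == 138.83
        assert round(table.theta(4), 2) == 139.59
        assert not table.any_clamped

    def test_wide_face_cell_phases_with_clamp(self):
        table = known_condition_phases(wide_face_scenario())
        assert round(table.theta(1), 2) == 129.33
        assert table.theta(3) == 180.0
        assert table.phase(3).clamped
        assert not table.phase(1).clamped

    def test_symmetric_scenario_pairs_cells(self):
        s = BinaryScenario("sym", "custom", 0.5, 0.61, 0.61)
        table = known_condition_phases(s)
        assert table.theta(1) == table.theta(3)
        assert table.theta(2) == table.theta(4)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_swapping_conditionals_swaps_cells_at_equal_marginals(self, a, b):
        s = BinaryScenario("s", "custom", 0.5, a, b)
        t = BinaryScenario("t", "custom", 0.5, b, a)
        ts, tt = known_condition_phases(s), known_condition_phases(t)
        assert ts.theta(1) == pytest.approx(tt.theta(3), abs=1e-12)
        assert ts.theta(2) == pytest.approx(tt.theta(4), abs=1e-12)


class TestExperimentalPhase:
    def test_gambling_phase(self):
        assert round(experimental_phase(gambling_scenario()).theta_deg, 2) == 113.49

    def test_wide_face_phase(self):
        assert round(experimental_phase(wide_face_scenario()).theta_deg, 2) == 87.65

    def test_classical_observation_gives_ninety(self):
        s = wide_face_scenario(p_unknown=0.3772)  # exactly the focal marginal
        assert experimental_phase(s).theta_deg == pytest.approx(90.0, abs=1e-10)

    def test_missing_observation_raises(self):
        with pytest.raises(MissingObservationError):
            experimental_phase(wide_face_scenario(p_unknown=None))


class TestFittedPhase:
    def test_wide_rule(self):
        table = known_condition_phases(wide_face_scenario())
        theta = fitted_phase(table, preset_rule("categorization_wide"))
        assert round(theta, 2) == 85.58

    def test_gambling_rule(self):
        table = known_condition_phases(gambling_scenario())
        theta = fitted_phase(table, preset_rule("gambling"))
        assert round(theta, 2) == 106.89

    def test_clamped_cell_maps_to_ninety(self):
        # a cooperation cell clamped at 180 halves to exactly 90
        s = BinaryScenario("PD3", "prisoners_dilemma", 0.5, 0.90, 0.87, 0.87)
        table = known_condition_phases(s)
        assert table.phase(2).clamped and table.theta(2) == 180.0
        assert fitted_phase(table, preset_rule("prisoners_dilemma")) == 90.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            preset_rule("custom")

    def test_malformed_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            PhaseFitRule("sum_complement", (1,))
        with pytest.raises(ConfigurationError):
            PhaseFitRule("half_complement", (5,))

    def test_min_conditional_alternative_differs_from_fixed_cell(self):
        # when cooperation under known-cooperation is rarest, the searching
        # rule picks cell 4 while the preset stays on cell 2
        s = BinaryScenario("PD6", "prisoners_dilemma", 0.5, 0.77, 0.83, 0.80)
        rule = min_conditional_rule(s)
        assert rule.cells == (4,)
        table = known_condition_phases(s)
        assert fitted_phase(table, rule) != pytest.approx(
            fitted_phase(table, preset_rule("prisoners_dilemma"))
        )


class TestPredictUnknown:
    def test_gambling_prediction(self):
        s = gambling_scenario()
        theta = fitted_phase(known_condition_phases(s), preset_rule("gambling"))
        assert round(predict_unknown(s, theta).value, 2) == 0.45

    def test_wide_face_prediction(self):
        s = wide_face_scenario()
        theta = fitted_phase(known_condition_phases(s), preset_rule("categorization_wide"))
        assert round(predict_unknown(s, theta).value, 2) == 0.40

    def test_ninety_degrees_is_focal_marginal(self):
        s = wide_face_scenario()
        assert predict_unknown(s, 90.0).value == pytest.approx(0.3772)


class TestAnalyze:
    def test_first_dilemma_experiment(self):
        # fraction-reconstructed inputs reproduce the published fit
        s = fixture_scenarios(load_fixture("prisoners_dilemma"), input_set="fractions")[0]
        r = analyze(s)
        assert round(r.theta_fit_deg, 2) == 105.30
        assert r.residual_deg == pytest.approx(-7.07, abs=0.02)
        assert round(r.p_fit.value, 2) == 0.52

    def test_matching_prediction_and_observation(self):
        s = BinaryScenario("G9", "gambling", 0.5, 0.30, 0.24, 0.17)
        r = analyze(s)
        assert round(r.p_fit.value, 2) == 0.17 == s.p_focal_unknown

    def test_prediction_only_mode(self):
        r = analyze(wide_face_scenario(p_unknown=None))
        assert r.theta_expt is None
        assert r.residual_deg is None
        assert round(r.theta_fit_deg, 2) == 85.58
        assert round(r.p_fit.value, 2) == 0.40

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(5.0, 175.0))
    def test_self_consistency_of_prediction(self, theta):
        s = gambling_scenario()
        p = predict_unknown(s, theta)
        if 0.0 <= p.value <= 1.0:
            recovered = experimental_phase(
                BinaryScenario("rt", "gambling", 0.5, 0.69, 0.57, p.value)
            )
            assert recovered.theta_deg == pytest.approx(theta, abs=1e-9)


class TestScenarioValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(InvalidInputError):
            BinaryScenario("bad", "gambling", 0.5, 1.2, 0.5)

    def test_unknown_paradigm(self):
        with pytest.raises(ConfigurationError):
            BinaryScenario("bad", "not-a-paradigm", 0.5, 0.5, 0.5)

    def test_bad_focal_decision(self):
        with pytest.raises(InvalidInputError):
            BinaryScenario("bad", "gambling", 0.5, 0.5, 0.5, focal_decision="other")


class TestScenarioIO:
    def test_round_trip(self, tmp_path, gambling_scenarios):
        path = tmp_path / "scenarios.csv"
        write_scenarios(gambling_scenarios, path)
        back = read_scenarios(path)
        assert [s.study_id for s in back] == [s.study_id for s in gambling_scenarios]
        for a, b in zip(back, gambling_scenarios):
            assert a.p_ref_given_pos == b.p_ref_given_pos
            assert a.p_focal_unknown == b.p_focal_unknown

    def test_missing_unknown_column_is_optional(self, tmp_path, gambling_scenarios):
        df = scenarios_to_frame(gambling_scenarios).drop(columns=["p_focal_unknown"])
        path = tmp_path / "no_unknown.csv"
        df.to_csv(path, index=False)
        back = read_scenarios(path)
        assert all(s.p_focal_unknown is None for s in back)

    def test_malformed_probability_names_the_row(self, tmp_path, gambling_scenarios):
        df = scenarios_to_frame(gambling_scenarios)
        df.loc[3, "p_ref_given_pos"] = 1.2
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(InvalidInputError, match="row 3"):
            read_scenarios(path)
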