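"""Core interference math: superposition, combination, phase inversion."""

import cmath
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavedecision import (
    DegenerateInputError,
    InvalidInputError,
    WaveComponent,
    invert_phase,
    resultant_intensity,
    two_wave_probability,
)


def phasor_intensity(components):
    """Independent oracle: squared modulus of the complex phasor sum."""
    return abs(sum(cmath.rect(math.sqrt(i), math.radians(t)) for i, t in components)) ** 2


class TestResultantIntensity:
    @pytest.mark.parametrize(
        "components, expected",
        [
            # fully constructive: (sqrt(.5) + sqrt(.5))^2
            ([(0.5, 0.0), (0.5, 0.0)], 2.0),
            # fully destructive, equal amplitudes
            ([(0.3, 0.0), (0.3, 180.0)], 0.0),
            # three-wave case frozen from the phasor oracle
            ([(0.25, 10.0), (0.16, 70.0), (0.09, 200.0)], 0.2502886477715681),
            ([(0.7, 123.4)], 0.7),
        ],
    )
    def test_known_values(self, components, expected):
        assert resultant_intensity(components) == pytest.approx(expected, abs=1e-12)
        # the frozen three-wave value really is the oracle's output
        assert phasor_intensity(components) == pytest.approx(expected, abs=1e-12)

    def test_accepts_wave_components(self):
        comps = [WaveComponent(0.25, 10.0), WaveComponent(0.16, 70.0)]
        assert resultant_intensity(comps) == pytest.approx(phasor_intensity([(0.25, 10), (0.16, 70)]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            resultant_intensity([(-0.1, 0.0), (0.5, 10.0)])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            resultant_intensity([])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 10.0, allow_nan=False),
                st.floats(0.0, 360.0, exclude_max=True),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_phasor_oracle(self, components):
        expected = phasor_intensity(components)
        assert resultant_intensity(components) == pytest.approx(
            expected, rel=1e-10, abs=1e-10
        )


class TestTwoWaveProbability:
    def test_published_gambling_prediction(self):
        # joints 0.5*0.69 and 0.5*0.57 at the fitted phase of that experiment
        got = two_wave_probability(0.345, 0.285, 106.89)
        assert got.value == pytest.approx(0.4478, abs=5e-4)
        assert round(got.value, 2) == 0.45
        assert not got.out_of_range

    @pytest.mark.parametrize("p1,p2", [(0.3, 0.4), (0.05, 0.9), (0.5, 0.5)])
    def test_ninety_degrees_recovers_total_probability(self, p1, p2):
        assert two_wave_probability(p1, p2, 90.0).value == pytest.approx(p1 + p2, abs=1e-15)

    def test_absent_wave(self):
        assert two_wave_probability(0.0, 0.37, 123.0).value == pytest.approx(0.37)

    def test_out_of_range_flagged_not_truncated(self):
        got = two_wave_probability(0.8, 0.8, 0.0)  # = 3.2
        assert got.value == pytest.approx(3.2)
        assert got.out_of_range
        assert float(got) == got.value

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidInputError):
            two_wave_probability(-0.1, 0.5, 10.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(0.01, 1.0),
        st.floats(0.01, 1.0),
        st.floats(0.0, 360.0),
    )
    def test_symmetry_and_bounds(self, p1, p2, theta):
        v = two_wave_probability(p1, p2, theta).value
        assert v == pytest.approx(two_wave_probability(p1, p2, 360.0 - theta).value, abs=1e-12)
        assert v == pytest.approx(two_wave_probability(p2, p1, theta).value, abs=1e-12)
        lo = (math.sqrt(p1) - math.sqrt(p2)) ** 2
        hi = (math.sqrt(p1) + math.sqrt(p2)) ** 2
        assert lo - 1e-12 <= v <= hi + 1e-12

    def test_bounds_attained_at_extreme_phases(self):
        p1, p2 = 0.3, 0.6
        assert two_wave_probability(p1, p2, 0.0).value == pytest.approx(
            (math.sqrt(p1) + math.sqrt(p2)) ** 2
        )
        assert two_wave_probability(p1, p2, 180.0).value == pytest.approx(
            (math.sqrt(p1) - math.sqrt(p2)) ** 2
        )


class TestInvertPhase:
    def test_published_cell_phase(self):
        # joint(attack, good) = 0.84*0.35 against p(attack) and p(good)
        got = invert_phase(0.294, 0.3772, 0.84)
        assert round(got.theta_deg, 2) == 145.09
        assert not got.clamped

    def test_clamped_cell(self):
        # joint(withdraw, bad) = 0.16*0.48 against p(withdraw), p(bad)
        got = invert_phase(0.0768, 0.6228, 0.16)
        assert got.raw_cosine == pytest.approx(-1.118, abs=5e-4)
        assert got.clamped
        assert got.theta_deg == 180.0

    def test_zero_interference_gives_ninety(self):
        p1, p2 = 0.22, 0.41
        got = invert_phase(p1 + p2, p1, p2)
        assert got.theta_deg == pytest.approx(90.0, abs=1e-12)
        assert not got.clamped

    @pytest.mark.parametrize("p1,p2", [(0.0, 0.5), (0.5, 0.0)])
    def test_vanishing_component_degenerate(self, p1, p2):
        with pytest.raises(DegenerateInputError):
            invert_phase(0.3, p1, p2)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.floats(0.01, 1.0),
        st.floats(0.01, 1.0),
        st.floats(0.1, 179.9),
    )
    def test_round_trips_two_wave_probability(self, p1, p2, theta):
        combined = two_wave_probability(p1, p2, theta).value
        got = invert_phase(combined, p1, p2)
        assert not got.clamped
        assert got.theta_deg == pytest.approx(theta, abs=1e-9)

    @pytest.mark.parametrize("theta", [0.0, 180.0])
    def test_round_trip_at_phase_extremes(self, theta):
        # arccos amplifies round-off where its derivative diverges, so the
        # endpoints get a looser band than the interior identity
        got = invert_phase(two_wave_probability(0.3, 0.6, theta).value, 0.3, 0.6)
        assert got.theta_deg == pytest.approx(theta, abs=1e-5)
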