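"""Unit and property tests for the waterlogging stress functions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barleywl.stress import (
    StressParams,
    fraction_roots_waterlogged,
    oxdef_photo_factor,
    oxdef_pheno_factor,
    stage_modifier_pheno,
    three_stage_response,
)


class TestOxdefPhoto:
    @pytest.mark.parametrize(
        "rtfr, expected",
        [(0.0, 1.0), (0.5, 1.0), (0.79, 1.0), (0.8, 1.0), (0.9, 0.5), (1.0, 0.0)],
    )
    def test_piecewise_values(self, rtfr, expected):
        assert oxdef_photo_factor(rtfr) == pytest.approx(expected)

    @pytest.mark.parametrize("rtfr", [-0.1, 1.1])
    def test_domain(self, rtfr):
        with pytest.raises(ValueError):
            oxdef_photo_factor(rtfr)


class TestOxdefPheno:
    @pytest.mark.parametrize(
        "rtfr, expected",
        [(0.0, 1.0), (0.7, 1.0), (0.8, 1.0), (0.9, 0.9), (1.0, 0.8)],
    )
    def test_piecewise_values(self, rtfr, expected):
        assert oxdef_pheno_factor(rtfr) == pytest.approx(expected)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(max_examples=200, derandomize=True)
def test_stress_indices_monotone_and_bounded(a, b):
    """Both indices are non-increasing in rtfr, bounded, and unity below 0.8."""
    lo, hi = min(a, b), max(a, b)
    for f, floor in ((oxdef_photo_factor, 0.0), (oxdef_pheno_factor, 0.8)):
        assert f(lo) >= f(hi)
        assert floor <= f(hi) <= 1.0
        if hi < 0.8:
            assert f(hi) == 1.0


@given(st.floats(0.0, 1.0))
@settings(max_examples=100, derandomize=True)
def test_stress_indices_continuous_at_threshold(x):
    """No jump at the 0.8 threshold: values near it stay near 1."""
    eps = 1e-9
    assert oxdef_photo_factor(0.8 + eps) == pytest.approx(1.0, abs=1e-6)
    assert oxdef_pheno_factor(0.8 + eps) == pytest.approx(1.0, abs=1e-6)
    del x


class TestStageModifier:
    @pytest.mark.parametrize(
        "stage, expected",
        [
            (1.0, 0.65),
            (4.0, 0.65),
            (4.75, 0.80),
            (5.5, 0.95),
            (6.0, 1.0),
            (8.0, 1.25),
            (10.0, 1.5),
            (11.0, 1.5),
        ],
    )
    def test_anchor_and_interpolated_values(self, stage, expected):
        assert stage_modifier_pheno(stage) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            stage_modifier_pheno(0.5)
        with pytest.raises(ValueError):
            stage_modifier_pheno(11.5)

    @given(st.floats(1.0, 11.0), st.floats(1.0, 11.0))
    @settings(max_examples=100, derandomize=True)
    def test_non_decreasing_in_stage(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert stage_modifier_pheno(lo) <= stage_modifier_pheno(hi) + 1e-12


class TestThreeStageResponse:
    def test_lag_stage_unaffected(self):
        for floor in (0.0, 0.5, 1.0):
            assert three_stage_response(0.0, 0.0, 3, 10, floor) == 1.0
            assert three_stage_response(3.0, 0.0, 3, 10, floor) == 1.0

    def test_full_stress_stage(self):
        assert three_stage_response(5.0, 0.0, 3, 10, 0.6) == 0.0
        assert three_stage_response(13.0, 0.25, 3, 10, 0.6) == 0.25

    def test_adapted_stage_floor(self):
        assert three_stage_response(14.0, 0.0, 3, 10, 0.6) == 0.6
        assert three_stage_response(30.0, 0.0, 3, 10, 1.0) == 1.0  # tolerant
        # raw stress milder than the floor passes through unchanged
        assert three_stage_response(30.0, 0.9, 3, 10, 0.6) == 0.9

    @given(
        st.floats(0, 60),
        st.floats(0, 1),
        st.floats(0, 1).flatmap(lambda a: st.tuples(st.just(a), st.floats(a, 1))),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_floor(self, age, raw, floors):
        lo, hi = floors
        assert three_stage_response(age, raw, 3, 10, lo) <= three_stage_response(
            age, raw, 3, 10, hi
        )


class TestFractionRootsWaterlogged:
    thick = np.array([150.0, 150.0, 200.0, 300.0])

    def test_no_saturation(self):
        assert fraction_roots_waterlogged(600, [False] * 4, self.thick) == 0.0

    def test_full_saturation(self):
        assert fraction_roots_waterlogged(600, [True] * 4, self.thick) == 1.0

    def test_partial_layer_proration(self):
        # roots 600 mm deep; bottom 300 mm of the root zone saturated:
        # layer 3 (300-500) and the rooted half of layer 4 (500-600)
        flags = [False, False, True, True]
        assert fraction_roots_waterlogged(600, flags, self.thick) == pytest.approx(0.5)

    def test_pre_emergence(self):
        assert fraction_roots_waterlogged(0, [True] * 4, self.thick) == 0.0

    def test_roots_within_first_layer(self):
        assert fraction_roots_waterlogged(50, [True, False, False, False], self.thick) == 1.0
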