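"""Unit and property tests for the desirability mapping functions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from desirank import (
    CategoricalSpec,
    InvalidSpecError,
    MonotoneSpec,
    PlateauSpec,
    SigmoidSpec,
    UnknownCategoryError,
    d_cat,
    d_central,
    d_ends,
    d_high,
    d_low,
    d_sigmoid,
    desirability,
    quantile_cuts,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@st.composite
def monotone_specs(draw, direction="high"):
    c1 = draw(st.floats(-100, 100))
    c2 = draw(st.floats(c1 + 1e-6, c1 + 200))
    dmin = draw(st.floats(0, 1))
    dmax = draw(st.floats(dmin, 1))
    scale = draw(st.floats(0.1, 5))
    return MonotoneSpec(c1, c2, dmin, dmax, scale, direction)


@st.composite
def plateau_specs(draw, direction="central"):
    cuts = sorted(draw(st.lists(st.floats(-100, 100), min_size=4, max_size=4)))
    dmin = draw(st.floats(0, 1))
    dmax = draw(st.floats(dmin, 1))
    scale = draw(st.floats(0.1, 5))
    return PlateauSpec(*cuts, dmin, dmax, scale, direction)


class TestMonotone:
    @pytest.mark.parametrize(
        "x, spec, expected",
        [
            # boundary plateaus
            (0.0, MonotoneSpec(0, 2), 0.0),
            (2.0, MonotoneSpec(0, 2), 1.0),
            (-5.0, MonotoneSpec(0, 2, des_min=0.2), 0.2),
            # linear midpoint and curvature
            (1.0, MonotoneSpec(0, 2), 0.5),
            (0.5, MonotoneSpec(0, 2, scale=2), 0.0625),
        ],
    )
    def test_d_high_values(self, x, spec, expected):
        assert d_high(x, spec) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, expected",
        [
            # maximum desirability below the lower cut, filtered out above
            # the upper cut, linear midpoint in between
            (0.00005, 1.0),
            (0.2, 0.0),
            ((0.0001 + 0.1) / 2, 0.5),
        ],
    )
    def test_d_low_p_value_criterion(self, p, expected):
        spec = MonotoneSpec(0.0001, 0.1, direction="low")
        assert d_low(p, spec) == pytest.approx(expected)

    @given(x=finite, spec=monotone_specs())
    def test_bounds(self, x, spec):
        d = d_high(x, spec)
        assert spec.des_min <= d <= spec.des_max <= 1.0

    @given(x1=finite, x2=finite, spec=monotone_specs())
    def test_monotonicity(self, x1, x2, spec):
        lo, hi = sorted([x1, x2])
        assert d_high(lo, spec) <= d_high(hi, spec) + 1e-12
        low_spec = MonotoneSpec(spec.cut1, spec.cut2, spec.des_min,
                                spec.des_max, spec.scale, "low")
        assert d_low(lo, low_spec) >= d_low(hi, low_spec) - 1e-12

    @given(x=finite, spec=monotone_specs())
    def test_mirror_identity(self, x, spec):
        """d_low(x; c1, c2) == d_high(-x; -c2, -c1) for scale 1."""
        low = MonotoneSpec(spec.cut1, spec.cut2, spec.des_min, spec.des_max,
                           1.0, "low")
        high = MonotoneSpec(-spec.cut2, -spec.cut1, spec.des_min,
                            spec.des_max, 1.0, "high")
        assert d_low(x, low) == pytest.approx(d_high(-x, high), abs=1e-9)

    def test_degenerate_cut_is_right_closed_step(self):
        """Coincident cuts give a step: x >= cut takes the large-x side, so
        a 'p < 0.05' threshold excludes p == 0.05 exactly."""
        step_high = MonotoneSpec(1.0, 1.0)
        assert d_high(0.999, step_high) == 0.0
        assert d_high(1.0, step_high) == 1.0
        step_low = MonotoneSpec(0.05, 0.05, direction="low")
        assert d_low(0.049, step_low) == 1.0
        assert d_low(0.05, step_low) == 0.0

    def test_missing_and_infinite_inputs(self):
        spec = MonotoneSpec(0, 2, des_min=0.1)
        assert math.isnan(d_high(float("nan"), spec))
        assert d_high(float("inf"), spec) == 1.0
        assert d_high(float("-inf"), spec) == 0.1
        out = d_high(np.array([np.nan, 1.0, np.inf]), spec)
        assert math.isnan(out[0]) and out[1] == pytest.approx(0.55)
        assert out[2] == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cut1=2, cut2=1),
            dict(cut1=math.nan, cut2=1),
            dict(cut1=0, cut2=1, scale=0),
            dict(cut1=0, cut2=1, des_min=0.9, des_max=0.1),
            dict(cut1=0, cut2=1, des_min=-0.1),
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(InvalidSpecError):
            MonotoneSpec(**kwargs)


class TestPlateau:
    spec = PlateauSpec(-2, -1, 1, 2)

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 1.0), (-2.0, 0.0), (2.0, 0.0), (-1.5, 0.5), (1.5, 0.5), (9, 0.0)],
    )
    def test_central_values(self, x, expected):
        assert d_central(x, self.spec) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (-3.0, 1.0), (3.0, 1.0), (1.5, 0.5), (-1.5, 0.5)],
    )
    def test_ends_values(self, x, expected):
        ends = PlateauSpec(-2, -1, 1, 2, direction="ends")
        assert d_ends(x, ends) == pytest.approx(expected)

    @given(x=finite, spec=plateau_specs())
    def test_bounds_and_reflection(self, x, spec):
        c = d_central(x, spec)
        assert spec.des_min <= c <= spec.des_max
        if spec.des_min == 0.0 and spec.des_max == 1.0 and spec.scale == 1.0:
            ends = PlateauSpec(spec.cut1, spec.cut2, spec.cut3, spec.cut4,
                               direction="ends")
            assert d_ends(x, ends) == pytest.approx(1.0 - c, abs=1e-9)

    @given(x1=finite, x2=finite, spec=plateau_specs())
    def test_central_unimodal(self, x1, x2, spec):
        """Non-decreasing left of the plateau, non-increasing right of it."""
        lo, hi = sorted([x1, x2])
        mid = (spec.cut2 + spec.cut3) / 2
        if hi <= mid:
            assert d_central(lo, spec) <= d_central(hi, spec) + 1e-12
        if lo >= mid:
            assert d_central(lo, spec) >= d_central(hi, spec) - 1e-12

    def test_unordered_cuts_rejected(self):
        with pytest.raises(InvalidSpecError):
            PlateauSpec(0, 2, 1, 3)


class TestCategorical:
    spec = CategoricalSpec({"yes": 1.0, "no": 0.2})

    def test_annotation_mapping(self):
        assert d_cat("yes", self.spec) == 1.0
        assert d_cat("no", self.spec) == 0.2

    def test_default_passthrough_and_error(self):
        with_default = CategoricalSpec({"yes": 1.0}, default=0.5)
        assert d_cat("unknown", with_default) == 0.5
        with pytest.raises(UnknownCategoryError):
            d_cat("unknown", self.spec)

    def test_missing_label_is_missing(self):
        assert math.isnan(d_cat(float("nan"), self.spec))
        assert math.isnan(d_cat(None, self.spec))

    def test_string_keys_match_numeric_labels(self):
        spec = CategoricalSpec({"1": 1.0, "0": 0.2})
        assert d_cat(1, spec) == 1.0
        assert d_cat(0, spec) == 0.2

    def test_out_of_range_mapping_rejected(self):
        with pytest.raises(InvalidSpecError):
            CategoricalSpec({"yes": 1.5})


class TestSigmoid:
    def test_midpoint_and_asymptotes(self):
        spec = SigmoidSpec(midpoint=3.0, steepness=2.0, des_min=0.2, des_max=0.8)
        assert d_sigmoid(3.0, spec) == pytest.approx(0.5)
        assert d_sigmoid(1e6, spec) == pytest.approx(0.8)
        assert d_sigmoid(-1e6, spec) == pytest.approx(0.2)
        down = SigmoidSpec(midpoint=0.0, steepness=-1.0)
        assert d_sigmoid(1e6, down) == pytest.approx(0.0)

    @given(x=finite,
           mid=st.floats(-50, 50),
           steep=st.floats(0.01, 10),
           dmin=st.floats(0, 0.5), dmax=st.floats(0.5, 1))
    def test_bounds(self, x, mid, steep, dmin, dmax):
        spec = SigmoidSpec(mid, steep, dmin, dmax)
        assert dmin <= d_sigmoid(x, spec) <= dmax

    def test_zero_steepness_rejected(self):
        with pytest.raises(InvalidSpecError):
            SigmoidSpec(0.0, 0.0)


def test_dispatcher_routes_by_spec_type():
    assert desirability(1.0, MonotoneSpec(0, 2)) == 0.5
    assert desirability(0.0, PlateauSpec(-2, -1, 1, 2)) == 1.0
    assert desirability("yes", CategoricalSpec({"yes": 1.0})) == 1.0
    assert desirability(0.0, SigmoidSpec(0.0, 1.0)) == 0.5
    with pytest.raises(TypeError):
        desirability(1.0, object())


def test_quantile_cuts_top_fraction():
    """'The top 10% gets maximum desirability' converts to the 90th
    percentile as the upper cut."""
    values = np.arange(101.0)
    (cut,) = quantile_cuts(values, 0.9)
    assert cut == pytest.approx(90.0)
    assert quantile_cuts([1.0, np.nan, 3.0], [0.0, 1.0]) == [1.0, 3.0]
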