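"""Tests for the weighted-geometric-mean aggregation and data fusion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from desirank import (
    ConfigError,
    Experiment,
    ExperimentManifest,
    InvalidWeightsError,
    combine_hierarchical,
    effective_weights,
    overall_desirability,
)


def fsum_geometric_mean(d, w):
    """Independent extended-precision oracle: exp(sum w ln d / sum w) with
    compensated summation, scalar Python arithmetic only."""
    pairs = [(di, wi) for di, wi in zip(d, w) if wi > 0 and not math.isnan(di)]
    if not pairs:
        return math.nan
    if any(di == 0.0 for di, _ in pairs):
        return 0.0
    num = math.fsum(wi * math.log(di) for di, wi in pairs)
    den = math.fsum(wi for _, wi in pairs)
    return math.exp(num / den)


class TestOverallDesirability:
    @pytest.mark.parametrize(
        "d, w, expected",
        [
            ([1, 1, 1], [1, 1, 1], 1.0),
            ([0.25, 1.0], [1, 1], 0.5),
            # one unacceptable criterion forces the overall to zero
            ([0.0, 0.9, 1.0], [1, 1, 1], 0.0),
        ],
    )
    def test_examples(self, d, w, expected):
        assert overall_desirability(d, w) == pytest.approx(expected)

    def test_weight_ratio_equivalence(self):
        """Only relative weight ratios matter: 20/10, 2/1, 1/0.5 agree."""
        d = [0.4, 0.8]
        results = {
            overall_desirability(d, w)
            for w in ([20, 10], [2, 1], [1, 0.5])
        }
        assert max(results) - min(results) < 1e-14

    def test_oracle_equivalence_bulk(self):
        rng = np.random.default_rng(42)
        n = 10_000
        d = rng.uniform(1e-6, 1.0, (n, 5))
        w = rng.uniform(0.1, 3.0, 5)
        got = overall_desirability(d, w)
        want = np.array([fsum_geometric_mean(row, w) for row in d])
        assert np.max(np.abs(got - want) / want) < 1e-12

    @given(
        d=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        w_raw=st.lists(st.floats(0.01, 10), min_size=1, max_size=8),
    )
    def test_matches_oracle_and_mean_bounds(self, d, w_raw):
        n = min(len(d), len(w_raw))
        d, w = d[:n], np.array(w_raw[:n])
        D = overall_desirability(d, w)
        want = fsum_geometric_mean(d, w)
        assert D == pytest.approx(want, rel=1e-12, abs=1e-12)
        # geometric mean bounds: min d <= D <= max d <= 1, and AM-GM
        assert min(d) - 1e-12 <= D <= max(d) + 1e-12
        arithmetic = float(np.dot(w, d) / w.sum())
        assert D <= arithmetic + 1e-12

    @given(
        d=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
        c=st.floats(0.001, 1000),
    )
    def test_weight_scale_invariance(self, d, c):
        w = np.ones(len(d))
        assert overall_desirability(d, w) == pytest.approx(
            overall_desirability(d, c * w), rel=1e-12
        )

    @given(d=st.lists(st.floats(0.01, 1), min_size=2, max_size=6), seed=st.integers(0, 100))
    def test_permutation_invariance(self, d, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 2.0, len(d))
        perm = rng.permutation(len(d))
        assert overall_desirability(d, w) == pytest.approx(
            overall_desirability(np.array(d)[perm], w[perm]), rel=1e-12
        )

    def test_missing_criteria_renormalise(self):
        """A missing criterion drops out; the rest keep their ratios."""
        full = overall_desirability([0.5, 0.8], [1.0, 2.0])
        with_missing = overall_desirability([0.5, 0.8, np.nan], [1.0, 2.0, 5.0])
        assert with_missing == pytest.approx(full, rel=1e-14)
        assert math.isnan(overall_desirability([np.nan, np.nan], [1, 1]))

    def test_zero_weight_is_an_off_switch(self):
        """Even d=0 cannot zero the overall when its weight is 0."""
        assert overall_desirability([0.0, 0.5], [0.0, 1.0]) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "w", [[-1, 1], [0, 0], [np.nan, 1], [np.inf, 1]]
    )
    def test_invalid_weights(self, w):
        with pytest.raises(InvalidWeightsError):
            overall_desirability([0.5, 0.5], w)

    def test_out_of_range_desirability_rejected(self):
        with pytest.raises(ValueError):
            overall_desirability([1.5, 0.5], [1, 1])


class TestEffectiveWeights:
    @pytest.mark.parametrize(
        "w, mask, expected",
        [
            ([1, 1, 2], None, [0.25, 0.25, 0.5]),
            ([1, 1, 2], [False, False, True], [0.5, 0.5, 0.0]),
            ([3], None, [1.0]),
        ],
    )
    def test_examples(self, w, mask, expected):
        np.testing.assert_allclose(effective_weights(w, mask), expected)

    def test_all_observed_zero(self):
        with pytest.raises(InvalidWeightsError):
            effective_weights([1.0, 0.0], [True, False])

    @given(
        w=st.lists(st.floats(0.1, 5), min_size=2, max_size=6),
        drop=st.integers(0, 5),
    )
    def test_ratios_preserved(self, w, drop):
        drop = drop % len(w)
        mask = np.zeros(len(w), dtype=bool)
        mask[drop] = True
        eff = effective_weights(w, mask)
        assert eff.sum() == pytest.approx(1.0)
        survivors = [i for i in range(len(w)) if i != drop]
        for i in survivors:
            for j in survivors:
                assert eff[i] * w[j] == pytest.approx(eff[j] * w[i], rel=1e-9)


class TestHierarchicalFusion:
    def test_single_experiment_is_identity(self):
        d = pd.Series({"a": 0.9, "b": 0.4})
        fused = combine_hierarchical(
            ExperimentManifest([Experiment("only", d, 3.0)])
        )
        assert fused.loc["a", "overall_D"] == pytest.approx(0.9)
        assert (fused["evidence_count"] == 1).all()

    def test_missing_experiment_does_not_influence(self):
        """A feature present in one experiment only is ranked on that
        experiment alone, whatever the other experiment's weight."""
        a = pd.Series({"x": 0.6, "y": 0.2})
        b = pd.Series({"y": 0.9})
        for wb in (0.1, 5.0):
            fused = combine_hierarchical(
                ExperimentManifest(
                    [Experiment("a", a, 1.0), Experiment("b", b, wb)]
                )
            )
            assert fused.loc["x", "overall_D"] == pytest.approx(0.6)
            assert fused.loc["x", "evidence_count"] == 1
            assert fused.loc["y", "evidence_count"] == 2

    def test_equal_values_any_weights(self):
        a = pd.Series({"x": 0.5})
        b = pd.Series({"x": 0.5})
        fused = combine_hierarchical(
            ExperimentManifest([Experiment("a", a, 1.3), Experiment("b", b, 0.2)])
        )
        assert fused.loc["x", "overall_D"] == pytest.approx(0.5)

    def test_weighted_two_level_value(self):
        a = pd.Series({"g": 0.9})
        b = pd.Series({"g": 0.3})
        fused = combine_hierarchical(
            ExperimentManifest([Experiment("a", a, 1.0), Experiment("b", b, 2.0)])
        )
        assert fused.loc["g", "overall_D"] == pytest.approx(
            fsum_geometric_mean([0.9, 0.3], [1.0, 2.0])
        )

    def test_empty_manifest_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentManifest([])
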