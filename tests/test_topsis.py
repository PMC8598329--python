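"""Interval grey-number TOPSIS: conversion, normalization, patterns,
distances, assessment degrees, and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greydecision.datasets import (
    PUBLISHED_ASSESSMENT,
    load_example_decision_matrix,
    load_example_distances,
)
from greydecision.decision import DecisionMatrix
from greydecision.errors import (
    DegenerateDistanceError,
    InputError,
    NormalizationError,
)
from greydecision.topsis import (
    GreyDecisionMatrix,
    GreyNumber,
    GreyTopsis,
    LinguisticScale,
    apply_weights,
    distances_to_ideals,
    gia_weights,
    grey_distance,
    ideal_patterns,
    normalize_grey,
    rank_alternatives,
    synthetic_assessment_degree,
    to_grey,
    weight_sensitivity,
)

# endpoints quantized so nonzero differences cannot underflow when squared
intervals = st.tuples(
    st.floats(-100, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
).map(lambda t: GreyNumber(round(t[0], 6), round(t[0], 6) + round(t[1], 6)))


def _grey_matrix(cells, weights=None):
    """cells: dict alternative -> dict criterion -> (lo, hi)."""
    lower = pd.DataFrame({c: {a: cells[a][c][0] for a in cells} for c in next(iter(cells.values()))})
    upper = pd.DataFrame({c: {a: cells[a][c][1] for a in cells} for c in next(iter(cells.values()))})
    w = pd.Series(weights or {c: 1.0 for c in lower.columns})
    return GreyDecisionMatrix(lower, upper, w)


class TestGreyNumber:
    def test_invalid_interval_rejected(self):
        with pytest.raises(InputError):
            GreyNumber(2.0, 1.0)
        with pytest.raises(InputError):
            GreyNumber(0.0, math.inf)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (GreyNumber(0, 0), GreyNumber(0, 0), 0.0),
            (GreyNumber(0, 1), GreyNumber(1, 2), 1.0),
            (GreyNumber(0.2, 0.4), GreyNumber(0.5, 0.8), math.sqrt(0.25 / 2)),
        ],
    )
    def test_distance_known_values(self, a, b, expected):
        assert grey_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(a=intervals, b=intervals, c=intervals)
    def test_distance_is_a_metric(self, a, b, c):
        assert grey_distance(a, b) == pytest.approx(grey_distance(b, a), abs=1e-9)
        assert grey_distance(a, a) == 0.0
        assert (grey_distance(a, b) == 0.0) == (a == b)
        assert grey_distance(a, c) <= grey_distance(a, b) + grey_distance(b, c) + 1e-9


class TestLinguisticScale:
    def test_default_assignments(self):
        scale = LinguisticScale.default()
        assert scale.assign(0.95) == GreyNumber(0.85, 1.0)
        assert scale.assign(0.0) == GreyNumber(0.0, 0.2)
        assert scale.assign(1.0) == GreyNumber(0.85, 1.0)
        # bin edge goes to the higher class
        assert scale.assign(0.45) == GreyNumber(0.45, 0.65)
        assert scale.assign(0.65) == GreyNumber(0.65, 0.85)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            LinguisticScale.default().assign(1.1)

    def test_dict_round_trip(self):
        scale = LinguisticScale.default()
        assert LinguisticScale.from_dict(scale.to_dict()) == scale

    def test_decreasing_intervals_rejected(self):
        with pytest.raises(InputError):
            LinguisticScale(
                labels=("lo", "hi"),
                edges=(0.0, 0.5, 1.0),
                intervals=(GreyNumber(0.5, 1.0), GreyNumber(0.0, 0.5)),
            )


class TestConversionAndNormalization:
    def test_constant_matrix_gives_identical_intervals(self):
        m = DecisionMatrix(pd.DataFrame(0.5, index=["a", "b"], columns=["x", "y"]))
        grey = to_grey(m)
        assert grey.cell("a", "x") == grey.cell("b", "y") == GreyNumber(0.45, 0.65)

    def test_single_benefit_column(self):
        grey = _grey_matrix({"a": {"x": (2, 4)}})
        out = normalize_grey(grey, {"x": "benefit"})
        assert out.cell("a", "x") == GreyNumber(0.5, 1.0)

    def test_single_cost_column_reciprocal(self):
        grey = _grey_matrix({"a": {"x": (2, 4)}})
        out = normalize_grey(grey, {"x": "cost"})
        assert out.cell("a", "x") == GreyNumber(0.5, 1.0)

    def test_two_benefit_intervals(self):
        grey = _grey_matrix({"a": {"x": (1, 2)}, "b": {"x": (2, 4)}})
        out = normalize_grey(grey, {"x": "benefit"})
        assert out.cell("a", "x") == GreyNumber(0.25, 0.5)
        assert out.cell("b", "x") == GreyNumber(0.5, 1.0)

    def test_results_stay_in_unit_interval(self, rng):
        for _ in range(50):
            lo = rng.uniform(0.1, 5.0, size=(4, 3))
            hi = lo + rng.uniform(0.0, 2.0, size=(4, 3))
            grey = GreyDecisionMatrix(
                pd.DataFrame(lo), pd.DataFrame(hi), pd.Series(1.0, index=range(3))
            )
            senses = {c: ("benefit" if c % 2 else "cost") for c in range(3)}
            out = normalize_grey(grey, senses)
            assert (out.lower.to_numpy() >= -1e-12).all()
            assert (out.upper.to_numpy() <= 1 + 1e-12).all()
            assert (out.lower.to_numpy() <= out.upper.to_numpy() + 1e-12).all()

    def test_missing_sense_rejected(self):
        grey = _grey_matrix({"a": {"x": (1, 2), "y": (1, 2)}})
        with pytest.raises(InputError, match="y"):
            normalize_grey(grey, {"x": "benefit"})

    def test_zero_divisor_names_criterion(self):
        grey = _grey_matrix({"a": {"x": (0.0, 1.0)}})
        with pytest.raises(NormalizationError, match="x"):
            normalize_grey(grey, {"x": "cost"})


class TestIdealPatternsAndDistances:
    def test_componentwise_extremes(self):
        grey = _grey_matrix({"a": {"x": (0.2, 0.5)}, "b": {"x": (0.4, 0.6)}})
        ideal, anti = ideal_patterns(grey)
        assert ideal["x"] == GreyNumber(0.4, 0.6)
        assert anti["x"] == GreyNumber(0.2, 0.5)

    def test_single_row_ideal_equals_anti_ideal(self):
        grey = _grey_matrix({"a": {"x": (0.2, 0.5), "y": (0.1, 0.9)}})
        ideal, anti = ideal_patterns(grey)
        assert all(ideal[c] == anti[c] for c in grey.criteria)

    def test_alternative_at_ideal_has_zero_dplus_row(self):
        grey = _grey_matrix(
            {"a": {"x": (0.4, 0.6), "y": (0.5, 0.9)}, "b": {"x": (0.1, 0.2), "y": (0.2, 0.3)}}
        )
        ideal, anti = ideal_patterns(grey)
        d_plus, d_minus = distances_to_ideals(grey, ideal, anti)
        assert (d_plus.loc["a"] == 0).all()
        assert (d_minus.loc["b"] == 0).all()

    def test_triangle_bound_per_criterion(self, rng):
        for _ in range(100):
            lo = rng.uniform(0, 1, size=(3, 4))
            hi = lo + rng.uniform(0, 1, size=(3, 4))
            grey = GreyDecisionMatrix(
                pd.DataFrame(lo), pd.DataFrame(hi), pd.Series(1.0, index=range(4))
            )
            ideal, anti = ideal_patterns(grey)
            d_plus, d_minus = distances_to_ideals(grey, ideal, anti)
            for c in grey.criteria:
                gap = grey_distance(ideal[c], anti[c])
                assert ((d_plus[c] + d_minus[c]) >= gap - 1e-9).all()


class TestAssessmentDegree:
    def test_published_distance_rows(self):
        d_plus, d_minus = load_example_distances()
        assert synthetic_assessment_degree(
            d_plus.loc["unemployment"], d_minus.loc["unemployment"]
        ) == pytest.approx(0.275, abs=5e-4)
        assert synthetic_assessment_degree(
            d_plus.loc["urbanization"], d_minus.loc["urbanization"]
        ) == pytest.approx(0.463, abs=5e-4)

    def test_boundary_cases(self):
        assert synthetic_assessment_degree([0, 0], [1, 2]) == 1.0
        assert synthetic_assessment_degree([1, 2], [0, 0]) == 0.0
        with pytest.raises(DegenerateDistanceError):
            synthetic_assessment_degree([0, 0], [0, 0])

    def test_scale_invariance(self, rng):
        dp = rng.uniform(0, 1, 8)
        dm = rng.uniform(0, 1, 8)
        base = synthetic_assessment_degree(dp, dm)
        assert synthetic_assessment_degree(3.7 * dp, 3.7 * dm) == pytest.approx(base)

    def test_rank_alternatives_published_example(self):
        order = rank_alternatives(PUBLISHED_ASSESSMENT)
        assert order == [
            "hdi",
            "public_health_expenditure",
            "access_to_energy",
            "urbanization",
            "population_growth",
            "unemployment",
        ]

    def test_rank_ties_lexicographic(self):
        assert rank_alternatives({"b": 0.5, "a": 0.5, "c": 0.9}) == ["c", "a", "b"]


class TestGreyTopsisEstimator:
    def test_fit_on_example_matrix(self):
        model = GreyTopsis().fit(load_example_decision_matrix())
        assert set(model.assessment_.index) == set(load_example_decision_matrix().alternatives)
        assert ((model.assessment_ >= 0) & (model.assessment_ <= 1)).all()
        assert model.ranking_ == rank_alternatives(model.assessment_)
        assert (model.d_plus_.to_numpy() >= 0).all()
        assert (model.d_minus_.to_numpy() >= 0).all()

    def test_gia_weights_are_normalized_column_means(self):
        matrix = load_example_decision_matrix()
        w = gia_weights(matrix)
        means = matrix.values.mean(axis=0)
        assert w.to_numpy() == pytest.approx((means / means.sum()).to_numpy())
        model = GreyTopsis(weights="gia").fit(matrix)
        assert model.grey_.weights.to_numpy() == pytest.approx(w.to_numpy())

    def test_assessment_monotone_in_benefit_cell_improvement(self, rng):
        """Raising one crisp benefit cell never lowers that alternative's
        assessment (default discrete scale, all-benefit, equal weights)."""
        checked = 0
        while checked < 200:
            values = rng.uniform(0.05, 0.95, size=(4, 3))
            frame = pd.DataFrame(values, index=list("abcd"), columns=["x", "y", "z"])
            alt = rng.choice(list("abcd"))
            crit = rng.choice(["x", "y", "z"])
            bumped = frame.copy()
            bumped.loc[alt, crit] += (1.0 - bumped.loc[alt, crit]) * rng.uniform(0.1, 1.0)
            try:
                before = GreyTopsis().fit(DecisionMatrix(frame)).assessment_[alt]
                after = GreyTopsis().fit(DecisionMatrix(bumped)).assessment_[alt]
            except DegenerateDistanceError:
                continue
            assert after >= before - 1e-9
            checked += 1

    def test_weight_sensitivity_frequencies(self):
        freq = weight_sensitivity(
            load_example_decision_matrix(), n_perturbations=10, seed=0
        )
        assert freq.to_numpy().sum() == pytest.approx(len(freq.index))
        assert freq.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(freq.index)))

    def test_prenormalized_grey_input_skips_conversion(self):
        grey = _grey_matrix(
            {"a": {"x": (0.2, 0.4), "y": (0.6, 0.8)}, "b": {"x": (0.5, 0.9), "y": (0.1, 0.3)}}
        )
        model = GreyTopsis(convert=False, normalize=False).fit(grey)
        assert model.grey_ is grey
        assert set(model.ranking_) == {"a", "b"}

    def test_apply_weights_scales_columns(self):
        grey = _grey_matrix(
            {"a": {"x": (0.2, 0.4), "y": (0.6, 0.8)}},
            weights={"x": 3.0, "y": 1.0},
        )
        weighted = apply_weights(grey)
        assert weighted.cell("a", "x") == GreyNumber(0.2 * 0.75, 0.4 * 0.75)
        assert weighted.cell("a", "y") == GreyNumber(0.6 * 0.25, 0.8 * 0.25)
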