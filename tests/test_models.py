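"""Classification rules by enumeration and polygon geometry."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periorisk import (AxisScoreVector, CATEGORIES, ValidationError,
                       build_model_spec, category_from_counts, classify,
                       classify_lang_tonetti, classify_modified,
                       polygon_area, risk_area_of)
from periorisk.models import CATEGORY_RANK


def brute_category(scores, rule_id):
    """Independent oracle: recount zones from scratch and apply the printed
    counting clauses directly."""
    m = sum(1 for s in scores if s in (2, 3))
    h = sum(1 for s in scores if s in (4, 5))
    if rule_id == "table_completed":
        if h >= 2:
            return "high"
        return "low" if m + h <= 2 else "moderate"
    if h >= 2:
        return "high"
    return "low" if m + h <= 1 else "moderate"


class TestRiskArea:
    @pytest.mark.parametrize("score,zone", [
        (0, "low"), (1, "low"), (2, "moderate"), (3, "moderate"),
        (4, "high"), (5, "high")])
    def test_zone_banding(self, score, zone):
        assert risk_area_of(score) == zone

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            risk_area_of(6)
        with pytest.raises(ValidationError):
            risk_area_of(-1)


class TestClassificationRules:
    def test_all_zero_low_under_both(self):
        assert classify_modified(
            AxisScoreVector("modified8", [0] * 8)).category == "low"
        assert classify_lang_tonetti(
            AxisScoreVector("lt2003", [0] * 6)).category == "low"

    def test_printed_rule_clauses(self):
        # 3 moderate + 1 high -> moderate
        vec = AxisScoreVector("modified8", [2, 2, 2, 4, 0, 0, 0, 0])
        res = classify_modified(vec)
        assert (res.category, res.n_moderate_axes, res.n_high_axes) == \
            ("moderate", 3, 1)
        # 2 high -> high
        assert classify_modified(
            AxisScoreVector("modified8", [5, 5, 0, 0, 0, 0, 0, 0])
        ).category == "high"
        # at most 2 outside low -> low
        assert classify_modified(
            AxisScoreVector("modified8", [3, 4, 0, 0, 0, 0, 0, 0])
        ).category == "low"

    def test_lt_rule_clauses(self):
        assert classify_lang_tonetti(
            AxisScoreVector("lt2003", [2, 0, 0, 0, 0, 0])).category == "low"
        assert classify_lang_tonetti(
            AxisScoreVector("lt2003", [2, 2, 0, 0, 0, 0])
        ).category == "moderate"
        assert classify_lang_tonetti(
            AxisScoreVector("lt2003", [4, 5, 0, 0, 0, 0])).category == "high"

    def test_lt_exhaustive_enumeration(self):
        """All 6^6 vectors: exactly one category each, matching the oracle."""
        for scores in itertools.product(range(6), repeat=6):
            res = classify_lang_tonetti(AxisScoreVector("lt2003", scores))
            assert res.category == brute_category(scores, "lt_classic")

    def test_modified_exhaustive_over_zone_counts(self):
        """All 6^8 vectors, vectorised: zone counts are computed for the full
        enumeration and every vector's rule decision matches the oracle."""
        grids = np.meshgrid(*[np.arange(6)] * 8, indexing="ij")
        scores = np.stack([g.ravel() for g in grids], axis=1)
        assert scores.shape == (6 ** 8, 8)
        m = ((scores == 2) | (scores == 3)).sum(axis=1)
        h = ((scores == 4) | (scores == 5)).sum(axis=1)
        # rule as a lookup over (m, h), built through the public API
        table = {(mm, hh): category_from_counts(mm, hh, "table_completed")
                 for mm in range(9) for hh in range(9) if mm + hh <= 8}
        cats = np.array([CATEGORY_RANK[table[(mm, hh)]]
                         for mm, hh in zip(m, h)])
        expected = np.where(h >= 2, 2, np.where(m + h <= 2, 0, 1))
        assert (cats == expected).all()
        # every vector got exactly one category
        assert len(cats) == 6 ** 8

    def test_modified_sampled_through_object_api(self):
        """10^5 random vectors through classify_modified match the oracle."""
        rng = np.random.default_rng(0)
        sample = rng.integers(0, 6, size=(100_000, 8))
        for scores in sample:
            res = classify_modified(
                AxisScoreVector("modified8", tuple(int(s) for s in scores)))
            assert res.category == brute_category(scores,
                                                  "table_completed")

    def test_minimal_trigger_counts(self):
        """Smallest k high-only axes giving 'high' is 2; smallest k
        moderate-only axes giving 'moderate' is 3."""
        def min_k(score_value, target):
            for k in range(9):
                scores = [score_value] * k + [0] * (8 - k)
                if classify_modified(AxisScoreVector(
                        "modified8", scores)).category == target:
                    return k
            return None
        assert min_k(5, "high") == 2
        assert min_k(2, "moderate") == 3

    @given(st.lists(st.integers(0, 5), min_size=8, max_size=8),
           st.integers(0, 7))
    @settings(derandomize=True, max_examples=300)
    def test_monotone_in_each_axis(self, scores, axis):
        """Raising one axis score never lowers the category rank."""
        if scores[axis] == 5:
            scores[axis] = 4
        raised = list(scores)
        raised[axis] += 1
        lo = classify_modified(AxisScoreVector("modified8", scores))
        hi = classify_modified(AxisScoreVector("modified8", raised))
        assert CATEGORY_RANK[hi.category] >= CATEGORY_RANK[lo.category]

    @given(st.permutations(list(range(6))))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariance(self, perm):
        base = [5, 4, 3, 2, 1, 0, 0, 2]
        shuffled = [base[i] for i in perm] + base[6:]
        a = classify_modified(AxisScoreVector("modified8", base))
        b = classify_modified(AxisScoreVector("modified8", shuffled))
        assert a.category == b.category

    def test_wrong_model_rejected(self):
        with pytest.raises(ValidationError):
            classify_modified(AxisScoreVector("lt2003", [0] * 6))
        with pytest.raises(ValidationError):
            classify_lang_tonetti(AxisScoreVector("modified8", [0] * 8))

    def test_figure_fixture_patients(self):
        """Published low-risk exemplar (generalized BOP only) is low; the
        high-risk exemplar (BOP 5, pockets >8, 10-19/day smoker) is high."""
        fig2 = AxisScoreVector("modified8", [5, 2, 0, 0, 0, 0, 0, 0])
        assert classify_modified(fig2).category == "low"
        fig4 = AxisScoreVector("modified8", [5, 5, 0, 3, 0, 0, 0, 0])
        res = classify_modified(fig4)
        assert res.n_high_axes >= 2
        assert res.category == "high"


class TestPolygonArea:
    def test_degenerate_zero(self):
        assert polygon_area(AxisScoreVector("modified8", [0] * 8)) == 0.0

    @pytest.mark.parametrize("model_id,n", [("modified8", 8), ("lt2003", 6)])
    @pytest.mark.parametrize("r", [1, 2, 3, 4, 5])
    def test_uniform_matches_closed_form(self, model_id, n, r):
        vec = AxisScoreVector(model_id, [r] * n)
        expected = 0.5 * n * r * r * math.sin(2 * math.pi / n)
        assert polygon_area(vec) == pytest.approx(expected, rel=1e-6)

    def test_spec_anchor_values(self):
        assert polygon_area(AxisScoreVector("modified8", [5] * 8)) == \
            pytest.approx(70.7107, abs=1e-4)
        assert polygon_area(AxisScoreVector("lt2003", [5] * 6)) == \
            pytest.approx(64.9519, abs=1e-4)

    def test_coordinate_monotone(self):
        """Raising any one score never shrinks the area (10^4 random pairs)."""
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            scores = rng.integers(0, 6, size=8)
            axis = int(rng.integers(0, 8))
            raised = scores.copy()
            raised[axis] = min(5, raised[axis] + 1)
            a0 = polygon_area(AxisScoreVector("modified8", scores.tolist()))
            a1 = polygon_area(AxisScoreVector("modified8", raised.tolist()))
            assert a1 >= a0 - 1e-12


class TestModelSpec:
    def test_axis_lists(self, modified8, lt2003):
        assert modified8.n_axes == 8
        assert lt2003.n_axes == 6
        assert set(lt2003.axis_names) < set(modified8.axis_names)
        assert set(modified8.axis_names) - set(lt2003.axis_names) == \
            {"diabetic", "background"}

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            build_model_spec("lt1996")

    def test_classify_dispatch(self):
        assert classify(AxisScoreVector("lt2003", [0] * 6)).category == "low"
        assert classify(
            AxisScoreVector("modified8", [5] * 8)).category == "high"
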