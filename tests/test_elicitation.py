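"""Linguistic scale conversion and expert-panel aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promethee2 import (
    FIVE_POINT_SCALE,
    DomainError,
    ElicitationError,
    ExpertPanel,
    LinguisticScale,
    aggregate_panel,
    from_crisp,
    to_crisp,
)


def make_panel(cells, scale=FIVE_POINT_SCALE):
    """cells: {(alternative, criterion): [label per expert]}"""
    n_experts = len(next(iter(cells.values())))
    rows = [
        (f"E{e+1}", a, c, labels[e])
        for (a, c), labels in cells.items()
        for e in range(n_experts)
    ]
    df = pd.DataFrame(rows, columns=["expert_id", "alternative", "criterion", "label"])
    return ExpertPanel(responses=df, scale=scale)


class TestToCrisp:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("High", 1.000),
            ("Average", 0.666),
            ("Low", 0.333),
            ("Very Low", 0.250),
            ("Null", 0.000),
        ],
    )
    def test_five_point_scale_values(self, label, expected):
        assert to_crisp(label) == expected

    @pytest.mark.parametrize("variant", ["high", "  HIGH  ", "High", "hIgH"])
    def test_matching_is_case_insensitive_and_trimmed(self, variant):
        assert to_crisp(variant) == 1.000

    def test_unknown_label_names_offender_and_allowed_set(self):
        with pytest.raises(ElicitationError, match=r"Medium.*High.*Null"):
            to_crisp("Medium")


class TestFromCrisp:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.000, "High"),  # exact member
            (0.30, "Low"),  # nearest of the five values
            (0.2915, "Low"),  # equidistant from 0.250/0.333: better label wins
            (0.833, "High"),  # equidistant from 0.666/1.000: better label wins
            (0.0, "Null"),
        ],
    )
    def test_nearest_label_with_upward_ties(self, value, expected):
        assert from_crisp(value) == expected

    @pytest.mark.parametrize("value", [-0.1, 1.2])
    def test_out_of_range_value_rejected(self, value):
        with pytest.raises(DomainError):
            from_crisp(value)

    def test_roundtrip_identity_on_scale_values(self):
        for label, value in zip(FIVE_POINT_SCALE.labels, FIVE_POINT_SCALE.values):
            assert from_crisp(value) == label
            assert to_crisp(from_crisp(value)) == value


class TestScaleInvariants:
    def test_values_must_strictly_decrease(self):
        with pytest.raises(ElicitationError):
            LinguisticScale(("A", "B"), (0.5, 0.5))

    def test_values_must_lie_in_unit_interval(self):
        with pytest.raises(ElicitationError):
            LinguisticScale(("A", "B"), (1.5, 0.0))

    def test_lengths_must_match_and_be_at_least_two(self):
        with pytest.raises(ElicitationError):
            LinguisticScale(("A", "B"), (1.0,))
        with pytest.raises(ElicitationError):
            LinguisticScale(("A",), (1.0,))


class TestAggregatePanel:
    def test_single_expert_is_identity_for_all_methods(self):
        cells = {("a1", "c1"): ["High"], ("a1", "c2"): ["Very Low"],
                 ("a2", "c1"): ["Null"], ("a2", "c2"): ["Average"]}
        panel = make_panel(cells)
        for method in ("mode", "mean-of-crisp", "median-of-crisp"):
            dm = aggregate_panel(panel, method=method)
            assert dm.to_frame().loc["a1", "c1"] == 1.000
            assert dm.to_frame().loc["a1", "c2"] == 0.250
            assert dm.to_frame().loc["a2", "c2"] == 0.666

    def test_unanimous_panel_gives_the_common_value(self):
        panel = make_panel({("a1", "c1"): ["Average"] * 7,
                            ("a2", "c1"): ["Average"] * 7})
        for method in ("mode", "mean-of-crisp", "median-of-crisp"):
            dm = aggregate_panel(panel, method=method)
            assert np.all(dm.scores == 0.666)

    def test_mode_takes_majority_label(self):
        panel = make_panel({("a1", "c1"): ["Low", "Low", "High"],
                            ("a2", "c1"): ["Null", "Null", "Null"]})
        dm = aggregate_panel(panel, method="mode")
        assert dm.to_frame().loc["a1", "c1"] == 0.333

    def test_mode_ties_resolve_toward_higher_value(self):
        panel = make_panel({("a1", "c1"): ["Low", "High"],
                            ("a2", "c1"): ["Null", "Very Low"]})
        dm = aggregate_panel(panel, method="mode")
        assert dm.to_frame().loc["a1", "c1"] == 1.000
        assert dm.to_frame().loc["a2", "c1"] == 0.250

    def test_mean_and_median_of_crisp(self):
        panel = make_panel({("a1", "c1"): ["Low", "Low", "High"],
                            ("a2", "c1"): ["Null", "Null", "Null"]})
        mean_dm = aggregate_panel(panel, method="mean-of-crisp")
        assert mean_dm.to_frame().loc["a1", "c1"] == pytest.approx(
            (0.333 + 0.333 + 1.0) / 3
        )
        med_dm = aggregate_panel(panel, method="median-of-crisp")
        assert med_dm.to_frame().loc["a1", "c1"] == 0.333

    def test_method_recorded_in_provenance(self):
        panel = make_panel({("a1", "c1"): ["Low"], ("a2", "c1"): ["High"]})
        dm = aggregate_panel(panel, method="mode")
        assert dm.meta["aggregation"] == "mode"
        assert dm.meta["n_experts"] == 1

    def test_empty_panel_rejected(self):
        df = pd.DataFrame(columns=["expert_id", "alternative", "criterion", "label"])
        with pytest.raises(ElicitationError):
            ExpertPanel(responses=df)

    def test_ragged_panel_rejected(self):
        df = pd.DataFrame(
            [("E1", "a1", "c1", "High"), ("E1", "a2", "c1", "Low"),
             ("E2", "a1", "c1", "High")],
            columns=["expert_id", "alternative", "criterion", "label"],
        )
        with pytest.raises(ElicitationError, match="ragged"):
            ExpertPanel(responses=df)

    def test_unknown_label_in_panel_rejected(self):
        df = pd.DataFrame(
            [("E1", "a1", "c1", "Enormous"), ("E1", "a2", "c1", "Low")],
            columns=["expert_id", "alternative", "criterion", "label"],
        )
        with pytest.raises(ElicitationError, match="Enormous"):
            ExpertPanel(responses=df)

    @given(
        labels=st.lists(
            st.lists(st.sampled_from(FIVE_POINT_SCALE.labels), min_size=3, max_size=3),
            min_size=2,
            max_size=4,
        )
    )
    def test_aggregates_stay_on_or_within_the_scale(self, labels):
        """Mode outputs are scale members; mean/median stay in the hull."""
        cells = {(f"a{i+1}", "c1"): lab for i, lab in enumerate(labels)}
        panel = make_panel(cells)
        mode_dm = aggregate_panel(panel, method="mode")
        assert set(np.ravel(mode_dm.scores)) <= set(FIVE_POINT_SCALE.values)
        for method in ("mean-of-crisp", "median-of-crisp"):
            dm = aggregate_panel(panel, method=method)
            assert np.all(dm.scores >= min(FIVE_POINT_SCALE.values))
            assert np.all(dm.scores <= max(FIVE_POINT_SCALE.values))
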