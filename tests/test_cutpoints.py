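"""Sensitivity/specificity tables, Youden selection and the
specificity-floor rule, checked against exhaustive scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import exhaustive_cutpoint_scan
from mskscreen.cutpoints import (
    CutpointTable,
    select_constrained,
    select_youden,
    sens_spec_table,
)


@st.composite
def score_instances(draw, max_n=120):
    n = draw(st.integers(min_value=4, max_value=max_n))
    scores = draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
    n_cases = draw(st.integers(min_value=1, max_value=n - 1))
    return (
        np.array(scores, dtype=float),
        np.array([1] * n_cases + [0] * (n - n_cases)),
    )


class TestSensSpecTable:
    def test_direct_count_example(self):
        # cases {4,5,2}, controls {1,3,3,6}: at c=4, 2 of 3 cases test
        # positive and 3 of 4 controls test negative
        t = sens_spec_table([4, 5, 2, 1, 3, 3, 6], [1, 1, 1, 0, 0, 0, 0])
        row = t[t["cutpoint"] == 4].iloc[0]
        assert row["sensitivity"] == pytest.approx(2 / 3)
        assert row["specificity"] == pytest.approx(3 / 4)
        assert row["youden_j"] == pytest.approx(2 / 3 + 3 / 4 - 1)  # 0.41667

    def test_perfect_separation_all_rows_perfect(self):
        t = sens_spec_table([8, 8, 0, 0, 0], [1, 1, 0, 0, 0])
        assert (t["sensitivity"] == 1.0).all()
        assert (t["specificity"] == 1.0).all()
        assert (t["youden_j"] == 1.0).all()

    def test_everyone_positive_threshold_is_uninformative(self):
        # all scores >= 1, so c=1 marks everyone positive: J = 0
        t = sens_spec_table([1, 4, 2, 5, 3, 6], [1, 1, 1, 0, 0, 0])
        row = t[t["cutpoint"] == 1].iloc[0]
        assert row["sensitivity"] == 1.0
        assert row["specificity"] == 0.0
        assert row["youden_j"] == pytest.approx(0.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            sens_spec_table([1, 2, 3], [1, 1, 1])

    @given(score_instances())
    def test_monotonicity_in_cutpoint(self, inst):
        s, y = inst
        t = sens_spec_table(s, y)
        assert (np.diff(t["sensitivity"]) <= 1e-12).all()
        assert (np.diff(t["specificity"]) >= -1e-12).all()
        assert t["youden_j"].between(-1, 1).all()
        assert np.allclose(t["youden_j"], t["sensitivity"] + t["specificity"] - 1)


class TestSelectors:
    def test_unique_maximum_perfect_split(self):
        t = sens_spec_table([5, 6, 7, 1, 2, 3, 4], [1, 1, 1, 0, 0, 0, 0])
        assert select_youden(t) == 5
        assert t[t["cutpoint"] == 5]["youden_j"].iloc[0] == 1.0

    @given(score_instances())
    def test_selectors_equal_exhaustive_scan(self, inst):
        s, y = inst
        t = sens_spec_table(s, y)
        want_j, want_c = exhaustive_cutpoint_scan(s, y, range(1, 9), floor=0.7)
        assert select_youden(t) == want_j
        assert select_constrained(t, 0.7) == want_c

    @given(score_instances(max_n=80))
    def test_constrained_never_violates_floor(self, inst):
        s, y = inst
        t = sens_spec_table(s, y)
        for floor in (0.5, 0.7, 0.9):
            sel = select_constrained(t, floor)
            if sel is not None:
                assert t[t["cutpoint"] == sel]["specificity"].iloc[0] >= floor
            else:
                assert (t["specificity"] < floor).all()

    def test_constraint_active_changes_selection(self):
        # hand-built table: global J max at c=2 has spec 0.6; c=3 is the
        # best cut keeping spec >= 0.7
        t = pd.DataFrame(
            {
                "cutpoint": [1, 2, 3, 4],
                "sensitivity": [1.0, 0.9, 0.7, 0.4],
                "specificity": [0.3, 0.6, 0.75, 0.9],
            }
        )
        t["youden_j"] = t["sensitivity"] + t["specificity"] - 1
        assert select_youden(t) == 2
        assert select_constrained(t, 0.7) == 3

    def test_constraint_inactive_matches_youden(self):
        t = pd.DataFrame(
            {
                "cutpoint": [1, 2, 3],
                "sensitivity": [0.9, 0.8, 0.5],
                "specificity": [0.7, 0.8, 0.95],
            }
        )
        t["youden_j"] = t["sensitivity"] + t["specificity"] - 1
        assert select_constrained(t, 0.7) == select_youden(t)

    def test_infeasible_floor_returns_none(self):
        # a control sits at the maximum score, so specificity < 1 at every cut
        t = sens_spec_table([1, 4, 2, 8], [1, 1, 0, 0])
        assert select_constrained(t, 0.999) is None

    def test_tie_breaks_to_lower_cutpoint(self):
        t = pd.DataFrame(
            {
                "cutpoint": [1, 2, 3],
                "sensitivity": [0.9, 0.8, 0.7],
                "specificity": [0.6, 0.7, 0.8],
            }
        )
        t["youden_j"] = [0.5, 0.5, 0.5]
        assert select_youden(t) == 1
        assert select_constrained(t, 0.65) == 2  # lowest feasible tie

    def test_sensitivity_objective_option(self):
        t = pd.DataFrame(
            {
                "cutpoint": [2, 3],
                "sensitivity": [0.9, 0.6],
                "specificity": [0.72, 0.95],
            }
        )
        t["youden_j"] = t["sensitivity"] + t["specificity"] - 1
        assert select_constrained(t, 0.7, objective="youden") == 2
        assert select_constrained(t, 0.8, objective="sensitivity") == 3

    def test_invalid_floor_rejected(self):
        t = sens_spec_table([1, 4], [0, 1])
        with pytest.raises(ValueError):
            select_constrained(t, 1.5)


def test_cutpoint_table_wrapper_consistency():
    s = np.array([4, 5, 2, 7, 1, 3, 3, 6], dtype=float)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    table = CutpointTable.from_scores(s, y)
    assert len(table.rows) == 8
    assert table.selected_youden == select_youden(table.rows)
    sel = select_constrained(table.rows, table.specificity_floor)
    assert table.selected_constrained == sel
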