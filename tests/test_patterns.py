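"""R/F/A classification, summaries, and density grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscperturb.errors import EmptySummaryError, ValidationError
from oscperturb.patterns import (
    build_density_grid,
    classify_pattern,
    summarize_patterns,
)
from oscperturb.workbench import make_fixture


@pytest.mark.parametrize(
    "fr,ar,expected",
    [
        (1.005, 1.003, "R"),   # both below 1%
        (1.02, 1.005, "F"),    # frequency change dominates
        (0.97, 0.50, "A"),     # amplitude change dominates
        (1.01, 1.0, "F"),      # exactly at threshold is not R; df dominates
        (0.99, 1.0, "F"),      # symmetric threshold case below 1
        (1.02, 1.02, "A"),     # tie above threshold goes to A
        (1.02, 0.98, "A"),     # tie with opposite directions
        (1.5, 1.2, "F"),
    ],
)
def test_classification_rule(fr, ar, expected):
    assert classify_pattern(fr, ar) == expected


def test_nonpositive_ratio_rejected():
    with pytest.raises(ValidationError):
        classify_pattern(-0.5, 1.0)
    with pytest.raises(ValidationError):
        classify_pattern(1.0, 0.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    d=st.floats(min_value=1e-6, max_value=0.99),
    ratio=st.floats(min_value=0.2, max_value=5.0),
)
def test_classification_symmetric_in_deviation_direction(d, ratio):
    """(1+d, r) and (1-d, r) classify identically: only |ratio-1| matters."""
    assert classify_pattern(1.0 + d, ratio) == classify_pattern(1.0 - d, ratio)


def test_tiny_table_matches_hand_counts():
    table = make_fixture("tiny_result_table")
    summary = summarize_patterns(table)["tiny"]
    expected_r, expected_f, expected_a = table.attrs["expected_fractions"]
    assert summary.fraction_r == pytest.approx(expected_r)
    assert summary.fraction_f == pytest.approx(expected_f)
    assert summary.fraction_a == pytest.approx(expected_a)
    assert summary.fraction_r + summary.fraction_f + summary.fraction_a == pytest.approx(100.0)
    assert summary.n_ties == 1


def test_all_robust_table():
    table = make_fixture("tiny_result_table").copy()
    table["frequency_ratio"] = 1.0
    table["amplitude_ratio"] = 1.0
    s = summarize_patterns(table)["tiny"]
    assert (s.fraction_r, s.fraction_f, s.fraction_a) == (100.0, 0.0, 0.0)


def test_damped_rows_excluded_from_statistics():
    table = make_fixture("tiny_result_table").copy()
    extra = table.iloc[[0]].copy()
    extra["status"] = "damped"
    extra["frequency_ratio"] = np.nan
    extra["amplitude_ratio"] = np.nan
    table = pd.concat([table, extra], ignore_index=True)
    s = summarize_patterns(table)["tiny"]
    assert s.n_results == 10  # the damped row does not count


def test_summary_of_zero_sustained_rows_raises():
    table = make_fixture("tiny_result_table").copy()
    table["status"] = "damped"
    with pytest.raises(EmptySummaryError):
        summarize_patterns(table)


# ---------------------------------------------------------------------------
# Density grids


def test_point_mass_density_grid():
    table = make_fixture("tiny_result_table").copy()
    table["frequency_ratio"] = 1.0
    table["amplitude_ratio"] = 1.0
    grid = build_density_grid(table)
    assert grid.shape == (100, 100)
    assert grid.grid.max() == pytest.approx(100.0)
    assert np.count_nonzero(grid.grid) == 1
    assert grid.out_of_range_percent == 0.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_density_grid_conserves_total_percentage(seed):
    rng = np.random.default_rng(seed)
    n = 300
    table = pd.DataFrame(
        {
            "model": "synthetic",
            "frequency_ratio": rng.lognormal(0.0, 0.08, n),
            "amplitude_ratio": rng.lognormal(0.0, 0.08, n),
            "status": "sustained",
        }
    )
    grid = build_density_grid(table, bounds=((0.95, 1.05), (0.95, 1.05)))
    assert grid.grid.sum() + grid.out_of_range_percent == pytest.approx(100.0)
    assert grid.shape == (100, 100)


def test_degenerate_bounds_rejected():
    table = make_fixture("tiny_result_table")
    with pytest.raises(ValidationError):
        build_density_grid(table, bounds=((1.0, 1.0), (0.9, 1.1)))


def test_density_colormap_ramp_order():
    table = make_fixture("tiny_result_table")
    grid = build_density_grid(table)
    assert grid.colormap_stops == ("white", "yellow", "red", "black")
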