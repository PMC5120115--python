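"""Instrument scoring, tariff arithmetic and reliability statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from recallmed import (cronbach_alpha, eq5d_utility, load_uk_tariff,
                       rescale_general_health, score_scl10, score_swls,
                       weighted_kappa)
from recallmed.scoring import EQ5D_DIMENSIONS, TariffTable

TARIFF = load_uk_tariff()
ALL_STATES = list(itertools.product([1, 2, 3], repeat=5))


@pytest.mark.parametrize("items,expected", [
    ([1] * 10, 0.0),
    ([4] * 10, 10.0),
    ([3, 3, 3, 3, 3, 2, 2, 2, 2, 2], 5.0),  # sum 25: midpoint of the map
])
def test_scl10_affine_map(items, expected):
    assert score_scl10(items).value == pytest.approx(expected)


@pytest.mark.parametrize("items,expected", [
    ([7, 7, 7], 0.0),
    ([1, 1, 1], 10.0),
    ([4, 4, 4], 5.0),  # sum 12: midpoint of the reversed map
])
def test_swls_reversed_map(items, expected):
    assert score_swls(items).value == pytest.approx(expected)


def test_item_validation_names_the_offender():
    with pytest.raises(ValueError, match="item 3"):
        score_scl10([1, 1, 5, 1, 1, 1, 1, 1, 1, 1])
    with pytest.raises(ValueError, match="SWLS"):
        score_swls([1, 8, 1])
    with pytest.raises(ValueError):
        score_scl10([1.5] * 10)


def test_eq5d_full_health_and_single_decrement():
    assert eq5d_utility("11111", TARIFF) == pytest.approx(1.0)
    expected = (TARIFF.full_health_value - TARIFF.any_dysfunction_constant
                - TARIFF.level2_decrement["MO"])
    assert eq5d_utility("21111", TARIFF) == pytest.approx(expected)


def test_eq5d_matches_independent_summation_on_all_243_states():
    # independent spreadsheet-style oracle over the shipped tariff
    for state in ALL_STATES:
        u = TARIFF.full_health_value
        if max(state) > 1:
            u -= TARIFF.any_dysfunction_constant
        if max(state) == 3:
            u -= TARIFF.worst_level_extra_term
        for dim, lev in zip(EQ5D_DIMENSIONS, state):
            u -= {1: 0.0, 2: TARIFF.level2_decrement[dim],
                  3: TARIFF.level3_decrement[dim]}[lev]
        assert eq5d_utility(state, TARIFF) == pytest.approx(u, abs=1e-12)


def test_eq5d_monotone_and_rescaling_bounded():
    full = eq5d_utility("11111", TARIFF)
    for state in ALL_STATES:
        u = eq5d_utility(state, TARIFF)
        assert u <= full + 1e-12
        # worsening any single dimension never raises utility
        for d in range(5):
            if state[d] < 3:
                worse = list(state)
                worse[d] += 1
                assert eq5d_utility(worse, TARIFF) <= u + 1e-12
        v = rescale_general_health(u, TARIFF).value
        assert 0.0 <= v <= 10.0


def test_rescale_general_health_anchors():
    assert rescale_general_health(TARIFF.full_health_value, TARIFF).value == 0.0
    assert rescale_general_health(TARIFF.min_utility, TARIFF).value == pytest.approx(10.0)
    mid = (TARIFF.full_health_value + TARIFF.min_utility) / 2
    assert rescale_general_health(mid, TARIFF).value == pytest.approx(5.0)
    with pytest.raises(ValueError):
        rescale_general_health(TARIFF.min_utility - 0.1, TARIFF)


def test_tariff_invariants_enforced():
    with pytest.raises(ValueError, match="level-3"):
        TariffTable(1.0, 0.081,
                    dict.fromkeys(EQ5D_DIMENSIONS, 0.2),
                    dict.fromkeys(EQ5D_DIMENSIONS, 0.1),
                    0.269, -0.594)


def test_eq5d_state_parsing_errors():
    for bad in ("1122", "11a23", "11124"):
        with pytest.raises(ValueError):
            eq5d_utility(bad, TARIFF)


def _alpha_bruteforce(x):
    """Element-wise variance-ratio computation, independent of the package."""
    n, k = x.shape
    item_vars = [np.var(x[:, j], ddof=1) for j in range(k)]
    totals = [sum(x[i, :]) for i in range(n)]
    return k / (k - 1) * (1 - sum(item_vars) / np.var(totals, ddof=1))


def test_cronbach_alpha_identical_columns_is_one():
    col = np.array([1.0, 2, 4, 3, 2, 1])
    x = np.column_stack([col] * 5)
    alpha, mean_r = cronbach_alpha(x)
    assert alpha == pytest.approx(1.0)
    assert mean_r == pytest.approx(1.0)


def test_cronbach_alpha_independent_items_near_zero():
    rng = np.random.default_rng(0)
    alpha, mean_r = cronbach_alpha(rng.normal(size=(10_000, 6)))
    assert abs(alpha) < 0.05
    assert abs(mean_r) < 0.02


def test_cronbach_alpha_toy_matrix_matches_bruteforce():
    x = np.array([[1.0, 2, 3], [2, 3, 3], [3, 4, 4], [4, 4, 2]])
    alpha, _ = cronbach_alpha(x)
    assert alpha == pytest.approx(_alpha_bruteforce(x), abs=1e-12)


def test_cronbach_alpha_constant_column_errors():
    x = np.array([[1.0, 2], [1, 3], [1, 4]])
    with pytest.raises(ValueError, match="constant"):
        cronbach_alpha(x)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(arrays(float, (20, 10),
              elements=st.floats(-5, 5, allow_nan=False, width=32)))
def test_cronbach_alpha_property_matches_bruteforce(x):
    x = x + np.arange(20)[:, None] * 0.1  # guard against constant columns
    alpha, _ = cronbach_alpha(x)
    assert alpha == pytest.approx(_alpha_bruteforce(x), rel=1e-9, abs=1e-9)


def test_weighted_kappa_perfect_agreement():
    x = np.array([1, 2, 3, 4, 2, 3])
    assert weighted_kappa(x, x) == pytest.approx(1.0)


def test_weighted_kappa_independent_near_zero():
    rng = np.random.default_rng(1)
    x = rng.integers(1, 5, 10_000)
    y = rng.integers(1, 5, 10_000)
    assert abs(weighted_kappa(x, y)) < 0.03


def test_weighted_kappa_toy_table_matches_hand_formula():
    # 3x3 contingency table [[20, 5, 0], [10, 30, 5], [0, 10, 20]]
    table = np.array([[20, 5, 0], [10, 30, 5], [0, 10, 20]])
    x, y = [], []
    for i in range(3):
        for j in range(3):
            x += [i + 1] * table[i, j]
            y += [j + 1] * table[i, j]
    # brute-force the formula from the table itself
    obs = table / table.sum()
    exp = np.outer(obs.sum(1), obs.sum(0))
    w = np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
    expected = 1 - (w * obs).sum() / (w * exp).sum()
    assert weighted_kappa(x, y) == pytest.approx(expected, abs=1e-12)
    # quadratic scheme differs and is also finite
    kq = weighted_kappa(x, y, weights="quadratic")
    assert np.isfinite(kq) and kq != pytest.approx(expected)


def test_weighted_kappa_no_variation_errors():
    with pytest.raises(ValueError, match="variation"):
        weighted_kappa([1, 1, 1], [1, 1, 1])
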