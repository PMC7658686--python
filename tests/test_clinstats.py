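from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from metafunc import (
    ClinicalTable,
    chi_square_independence,
    cohort_table,
    correlate_with_clinical,
    group_summary,
    normalize_relative,
    one_way_anova,
    spearman_test,
)

from conftest import make_profile


# ------------------------------------------------------------ chi-square


def test_chi_square_cohort_sex_table():
    stat, df, p = chi_square_independence([[10, 10, 9, 7], [5, 12, 6, 6]])
    assert stat == pytest.approx(1.792, abs=5e-4)
    assert df == 3


def test_chi_square_proportional_rows_zero():
    stat, df, _ = chi_square_independence([[10, 20], [5, 10]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_chi_square_diagonal_table():
    stat, df, p = chi_square_independence([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)
    assert df == 1


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_square_independence([[0, 0], [3, 4]])


@given(
    st.tuples(
        st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30)
    )
)
def test_chi_square_matches_2x2_closed_form(cells):
    a, b, c, d = cells
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    stat, df, _ = chi_square_independence([[a, b], [c, d]])
    assert stat == pytest.approx(expected, rel=1e-10)
    assert df == 1


# ----------------------------------------------------------------- ANOVA


def test_anova_hand_computed_example():
    f, df1, df2, p = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert f == pytest.approx(13.5)
    assert (df1, df2) == (1, 4)


def test_anova_identical_groups_f_zero():
    f, *_ = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert f == pytest.approx(0.0, abs=1e-12)


def test_anova_shift_invariance():
    vals = np.array([3.1, 4.0, 2.2, 9.9, 8.5, 7.7, 5.0, 6.1])
    groups = ["a"] * 4 + ["b"] * 4
    f1, *_ = one_way_anova(vals, groups)
    f2, *_ = one_way_anova(vals + 100.0, groups)
    assert f1 == pytest.approx(f2)


def test_anova_single_group_rejected():
    with pytest.raises(ValueError):
        one_way_anova([1, 2, 3], ["a", "a", "a"])


# --------------------------------------------------------- group summary


def test_group_summary_mean_and_sem():
    summ = group_summary([1, 2, 3], ["g", "g", "g"])
    assert summ.at["g", "mean"] == pytest.approx(2.0)
    assert summ.at["g", "sem"] == pytest.approx(1 / np.sqrt(3))


def test_group_summary_constant_group_sem_zero():
    summ = group_summary([5, 5, 5], ["g"] * 3)
    assert summ.at["g", "sem"] == 0.0


def test_group_summary_singleton_sem_undefined():
    summ = group_summary([7.0], ["g"])
    assert summ.at["g", "mean"] == 7.0
    assert np.isnan(summ.at["g", "sem"])


# -------------------------------------------------------------- Spearman


@pytest.mark.parametrize("n", [5, 6, 7])
def test_exact_spearman_p_matches_enumeration_oracle(n):
    rng = np.random.default_rng(n)
    x = rng.permutation(np.arange(1.0, n + 1))
    y = rng.permutation(np.arange(1.0, n + 1))
    r, p = spearman_test(x, y)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = sum(
        abs(stats.spearmanr(x, perm).statistic) >= obs - 1e-12
        for perm in permutations(y)
    )
    assert p == pytest.approx(count / factorial(n))


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(2)
    x = rng.random(30)
    y = x + rng.random(30) * 0.5
    r, p = spearman_test(x, y)
    ref = stats.spearmanr(x, y)
    assert r == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


# -------------------------------------------------- correlation screens


def _screen_inputs(n=20, seed=0):
    rng = np.random.default_rng(seed)
    prof = normalize_relative(make_profile(rng.random((n, 3)) + 0.5, ["G"] * n))
    clinical = ClinicalTable(
        pd.DataFrame({"idx": prof.data["F1"].to_numpy()}, index=prof.data.index),
        prof.group.copy(),
    )
    return prof, clinical


def test_feature_equal_to_index_fully_correlated_and_masked():
    prof, clinical = _screen_inputs()
    screen = correlate_with_clinical(prof, clinical)
    assert screen.r.at["F1", "idx"] == pytest.approx(1.0)
    assert bool(screen.mask.at["F1", "idx"])


def test_null_pairs_masked_near_nominal_rate():
    rng = np.random.default_rng(31)
    n = 25
    prof = make_profile(rng.random((n, 40)), ["G"] * n)
    clinical = ClinicalTable(
        pd.DataFrame(rng.random((n, 25)),
                     columns=[f"i{k}" for k in range(25)],
                     index=prof.data.index),
        prof.group.copy(),
    )
    screen = correlate_with_clinical(prof, clinical, alpha=0.05)
    frac = screen.mask.to_numpy().mean()
    m = screen.mask.size
    assert frac <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / m) + 0.005


def test_missing_values_pairwise_complete_and_short_pairs_flagged():
    prof, clinical = _screen_inputs()
    vals = clinical.data["idx"].to_numpy().copy()
    vals[5:] = np.nan  # only 5 complete observations remain
    clinical.data["short"] = vals
    vals3 = vals.copy()
    vals3[3:] = np.nan  # only 3 -> not assessable
    clinical.data["tiny"] = vals3
    screen = correlate_with_clinical(prof, clinical)
    assert screen.n_obs.at["F1", "short"] == 5
    assert screen.r.at["F1", "short"] == pytest.approx(1.0)
    assert np.isnan(screen.r.at["F1", "tiny"])
    assert not bool(screen.mask.at["F1", "tiny"])


def test_group_subset_and_empty_subset_error(example_dataset):
    rel = normalize_relative(example_dataset.profile)
    screen = correlate_with_clinical(rel, example_dataset.clinical, subset="IBS-D")
    assert bool(screen.mask.at["COG0001", "IBS-SSS"])
    with pytest.raises(KeyError):
        correlate_with_clinical(rel, example_dataset.clinical, subset="nope")


def test_cohort_table_shapes(example_dataset):
    table = cohort_table(example_dataset.clinical)
    assert "F" in table.columns and "p" in table.columns
    assert table.loc["IBS-SSS", "IBS-D_n"] == 22
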