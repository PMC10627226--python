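"""ANOVA, Duncan multiple range test, letters, stars, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ojip import (
    DesignError,
    DomainError,
    correlation_matrix,
    duncan_mrt,
    one_way_anova,
    star_code,
    summarize_treatment_table,
)
from ojip.stats import least_significant_range


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def test_identical_groups_give_f_zero_p_one():
    res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res.f_stat == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_two_group_f_equals_squared_pooled_t():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
    res = one_way_anova(np.concatenate([x, y]), ["a"] * 8 + ["b"] * 8)
    t, p_t = sps.ttest_ind(x, y)  # independent oracle
    assert res.f_stat == pytest.approx(t**2, rel=1e-12)
    assert res.p_value == pytest.approx(p_t, rel=1e-12)


def test_sums_of_squares_conserve():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=30)
    levels = np.repeat(["a", "b", "c"], 10)
    res = one_way_anova(vals, levels)
    ss_total = ((vals - vals.mean()) ** 2).sum()
    assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-12)


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(2)
    groups = [rng.normal(mu, 1, 7) for mu in (0, 0.5, 1.5, 0.2)]
    vals = np.concatenate(groups)
    levels = np.repeat(list("abcd"), 7)
    res = one_way_anova(vals, levels)
    f_ref, p_ref = sps.f_oneway(*groups)
    assert res.f_stat == pytest.approx(f_ref, rel=1e-12)
    assert res.p_value == pytest.approx(p_ref, rel=1e-12)


def test_anova_design_and_degenerate_errors():
    with pytest.raises(DesignError):
        one_way_anova([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(DesignError):
        one_way_anova([1, 2, 3], ["a", "a", "b"])
    with pytest.raises(DomainError):
        one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])  # zero within-var


# ---------------------------------------------------------------------------
# stars
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, stars",
    [(0.0005, "***"), (0.001, "***"), (0.0011, "**"), (0.01, "**"),
     (0.027, "*"), (0.05, "*"), (0.0501, "ns"), (0.283, "ns"), (1.0, "ns")],
)
def test_star_code_inclusive_thresholds(p, stars):
    assert star_code(p) == stars


def test_star_code_domain():
    with pytest.raises(DomainError):
        star_code(-0.1)
    with pytest.raises(DomainError):
        star_code(1.5)


# ---------------------------------------------------------------------------
# Duncan MRT + compact letter display
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=None)
def _oracle_q(span, df_error, alpha):
    # scipy quantile, cached: the oracle's independence is in the span
    # enumeration, not in recomputing the same distribution quantile
    return sps.studentized_range.ppf((1 - alpha) ** (span - 1), span, df_error)


def oracle_significant_pairs(means_desc, df_error, mse, n, alpha=0.05):
    """Exhaustive-span oracle: a pair differs iff every contiguous span
    containing it exceeds that span's least significant range."""
    k = len(means_desc)

    def lsr(span):
        return _oracle_q(span, df_error, alpha) * np.sqrt(mse / n)

    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            ok = all(
                means_desc[a] - means_desc[b] > lsr(b - a + 1)
                for a in range(0, i + 1)
                for b in range(j, k)
            )
            if ok:
                sig.add((i, j))
    return sig


def separated_pairs_from_letters(names_desc, letters):
    """Pairs (by sorted index) sharing no letter."""
    out = set()
    for i in range(len(names_desc)):
        for j in range(i + 1, len(names_desc)):
            if not set(letters[names_desc[i]]) & set(letters[names_desc[j]]):
                out.add((i, j))
    return out


def test_far_separated_means_get_distinct_letters():
    letters = duncan_mrt({"hi": 10.0, "lo": 1.0}, 5, mse=1e-6, df_error=8)
    assert letters == {"hi": "a", "lo": "b"}


def test_equal_means_share_one_letter():
    letters = duncan_mrt({"a": 2.0, "b": 2.0, "c": 2.0}, 5, mse=0.5, df_error=12)
    assert set(letters.values()) == {"a"}


def test_letter_a_sits_on_largest_mean():
    letters = duncan_mrt({"x": 1.0, "y": 9.0, "z": 5.0}, 5, mse=0.01, df_error=12)
    assert letters["y"] == "a"
    assert letters["x"] == "c"


def test_df_error_must_be_positive():
    with pytest.raises(DesignError):
        duncan_mrt({"a": 1, "b": 2}, 5, mse=1.0, df_error=0)


@pytest.mark.parametrize("seed", range(40))
def test_duncan_partition_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 7))
    n = 5
    spread = rng.choice([0.3, 1.0, 3.0])  # mix borderline and clear designs
    means = {f"L{i}": float(rng.normal(0, spread)) for i in range(k)}
    mse = float(rng.uniform(0.2, 2.0))
    df_error = k * (n - 1)
    letters = duncan_mrt(means, n, mse, df_error)
    names_desc = sorted(means, key=lambda s: -means[s])
    means_desc = np.array([means[s] for s in names_desc])
    expected = oracle_significant_pairs(means_desc, df_error, mse, n)
    assert separated_pairs_from_letters(names_desc, letters) == expected


@pytest.mark.parametrize("seed", range(12))
def test_letters_never_split_a_nonsignificant_pair(seed):
    rng = np.random.default_rng(1000 + seed)
    k = int(rng.integers(3, 7))
    means = {f"L{i}": float(rng.normal(0, 1.0)) for i in range(k)}
    mse, n, df_error = 0.8, 5, k * 4
    letters = duncan_mrt(means, n, mse, df_error)
    names_desc = sorted(means, key=lambda s: -means[s])
    means_desc = np.array([means[s] for s in names_desc])
    oracle = oracle_significant_pairs(means_desc, df_error, mse, n)
    for pair in separated_pairs_from_letters(names_desc, letters):
        assert pair in oracle  # never asserts a difference the test denies


def test_unbalanced_uses_harmonic_mean_n():
    means = {"a": 0.0, "b": 1.0}
    mse, df = 0.5, 10
    letters_map = duncan_mrt(means, {"a": 4, "b": 8}, mse, df)
    n_h = 2 / (1 / 4 + 1 / 8)
    lsr = least_significant_range(2, df, mse, n_h)
    expect_split = (1.0 > lsr)
    assert (letters_map["a"] != letters_map["b"]) == expect_split


# ---------------------------------------------------------------------------
# treatment report table
# ---------------------------------------------------------------------------

def test_summarize_treatment_table_layout(small_params):
    report, results = summarize_treatment_table(
        small_params, axis="temperature",
        columns=("phi_Po", "phi_Do", "phi_Eo", "delta_Ro", "PI_abs", "rc_density"),
    )
    assert list(report.columns) == [
        "maturity_group", "level",
        "phi_Po", "phi_Do", "phi_Eo", "delta_Ro", "PI_abs", "rc_density",
    ]
    # per maturity group: 3 level rows + significance + p-value
    assert len(report) == 2 * (3 + 2)
    sig_rows = report[report["level"] == "Significance"]
    assert set(sig_rows["phi_Po"]) <= {"***", "**", "*", "ns"}
    # heat scenario collapses phi_Po: strong effect, so stars for phi_Po
    assert all(s in ("***", "**", "*") for s in sig_rows["phi_Po"])
    # cell means round-trip: first row phi_Po is '0.xxx' + letters
    cell = report.iloc[0]["phi_Po"]
    assert cell[0] == "0" and cell[1] == "."
    assert cell[5:].isalpha() and "a" <= cell[5] <= "e"


def test_summarize_single_level_errors(small_params):
    sub = small_params[small_params["temperature"] == "26/18"]
    with pytest.raises(DesignError):
        summarize_treatment_table(sub, axis="temperature", columns=("phi_Po",))


def test_summarize_respects_column_subset(small_params):
    report, _ = summarize_treatment_table(
        small_params, axis="temperature", columns=("phi_Eo", "phi_Po")
    )
    assert list(report.columns) == ["maturity_group", "level", "phi_Eo", "phi_Po"]


def test_observations_are_replicate_means_by_default(small_params):
    _, res_rep = summarize_treatment_table(
        small_params, axis="temperature", columns=("phi_Po",))
    _, res_all = summarize_treatment_table(
        small_params, axis="temperature", columns=("phi_Po",),
        use_replicate_means=False)
    # same means either way (balanced), different error dfs
    assert res_rep[0].anova.df_error == 3 * 5 - 3
    assert res_all[0].anova.df_error == 3 * 5 * 2 - 3
    for lv, m in res_rep[0].level_means.items():
        assert m == pytest.approx(res_all[0].level_means[lv], rel=1e-12)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def test_phi_do_anticorrelates_exactly_with_phi_po(small_params):
    res = correlation_matrix(small_params, subset=("phi_Po", "phi_Do", "phi_Eo"))
    i, j = res.parameters.index("phi_Po"), res.parameters.index("phi_Do")
    assert res.matrix[i, j] == pytest.approx(-1.0, abs=1e-12)
    assert np.allclose(np.diag(res.matrix), 1.0)


def test_correlation_matches_two_pass_covariance_oracle(small_params):
    subset = ("phi_Po", "phi_Eo", "delta_Ro", "PI_abs")
    res = correlation_matrix(small_params, subset=subset)
    x = small_params[list(res.parameters)].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    d = np.sqrt(np.diag(cov))
    expected = cov / np.outer(d, d)
    np.testing.assert_allclose(res.matrix, expected, atol=1e-12)


def test_correlation_symmetric_psd_and_cluster_ordered(small_params):
    res = correlation_matrix(small_params)
    assert np.allclose(res.matrix, res.matrix.T)
    eig = np.linalg.eigvalsh(res.matrix)
    assert eig.min() > -1e-8
    assert sorted(res.ordering) == list(range(len(res.parameters)))
    frame = res.ordered_frame()
    assert list(frame.index) == [res.parameters[i] for i in res.ordering]


def test_constant_column_dropped_with_warning(small_params):
    df = small_params.copy()
    df["const"] = 1.0
    with pytest.warns(UserWarning, match="const"):
        res = correlation_matrix(df, subset=("phi_Po", "phi_Eo", "const"))
    assert "const" not in res.parameters


def test_correlation_needs_observations():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
    with pytest.raises(DesignError):
        correlation_matrix(df, subset=("a", "b"))
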