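import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cmmnet.cohort import DISEASES, generate_cohort, planted_config
from cmmnet.epi import (
    PrevalenceTable,
    anova_from_summaries,
    anova_oneway,
    bonferroni_pairwise,
    characterize,
    chi_square_test,
    contingency_from_records,
    name_patterns,
    prevalence_table,
)

# Reference four-pattern summaries (sizes and per-pattern counts) used as
# fixed numeric test vectors throughout.
SIZES = np.array([471, 127, 1463, 245])


def _two_col(counts):
    counts = np.asarray(counts)
    return np.column_stack([counts, SIZES - counts])


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_hypertension_table():
    chi2, df, p = chi_square_test(_two_col([245, 46, 658, 88]))
    assert chi2 == pytest.approx(21.492, abs=5e-4)
    assert df == 3
    assert p < 0.001


def test_chi_square_gender_table():
    chi2, df, p = chi_square_test([[191, 48, 870, 63], [280, 79, 593, 182]])
    assert chi2 == pytest.approx(134.041, abs=5e-4)
    assert df == 3


def test_chi_square_proportional_rows_zero():
    chi2, df, p = chi_square_test([[10, 20], [20, 40]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        chi_square_test([[0, 0], [5, 10]])


def test_chi_square_too_small_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        chi_square_test([[1, 2]])


def test_chi_square_against_scipy_random_tables():
    """Independent textbook implementation vs scipy on 200 random tables."""
    rng = np.random.default_rng(0)
    for trial in range(200):
        r = int(rng.integers(2, 6))
        c = int(rng.integers(2, 6))
        table = rng.integers(1, 60, size=(r, c))
        chi2, df, p = chi_square_test(table)
        ref_chi2, ref_p, ref_df, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref_chi2, abs=1e-9)
        assert df == ref_df
        assert p == pytest.approx(ref_p, abs=1e-9)


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_equal_means_f_zero():
    f, df1, df2, p = anova_oneway([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    assert f == pytest.approx(0.0, abs=1e-12)


def test_anova_bmi_summaries():
    f, df1, df2, p = anova_from_summaries(
        SIZES, [31.044, 29.598, 29.130, 29.312], [7.841, 6.802, 7.107, 7.189]
    )
    assert f == pytest.approx(8.369, abs=0.05)
    assert (df1, df2) == (3, 2302)
    assert p < 0.001


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.7, 1, 25)
    f, df1, df2, p_f = anova_oneway([a, b])
    t, p_t = stats.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-9)


def test_anova_raw_and_summary_agree():
    rng = np.random.default_rng(2)
    groups = [rng.normal(m, 2.0, size=n) for m, n in ((0, 12), (1, 20), (0.5, 9))]
    f_raw, df1_raw, df2_raw, p_raw = anova_oneway(groups)
    f_sum, df1_sum, df2_sum, p_sum = anova_from_summaries(
        [len(g) for g in groups],
        [g.mean() for g in groups],
        [g.std(ddof=1) for g in groups],
    )
    assert f_raw == pytest.approx(f_sum, abs=1e-9)
    assert (df1_raw, df2_raw) == (df1_sum, df2_sum)
    assert p_raw == pytest.approx(p_sum, abs=1e-9)


def test_anova_against_scipy():
    rng = np.random.default_rng(3)
    groups = [rng.normal(i, 1.5, size=15 + i) for i in range(4)]
    f, _, _, p = anova_oneway(groups)
    ref = stats.f_oneway(*groups)
    assert f == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_anova_degenerate():
    with pytest.raises(ValueError, match="undefined"):
        anova_oneway([[1.0, 1.0], [1.0, 1.0]])


# ---------------------------------------------------------------------------
# Bonferroni


def test_bonferroni_two_groups_unadjusted():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
    out = bonferroni_pairwise({"a": a, "b": b})
    _, p_raw = stats.ttest_ind(a, b, equal_var=True)
    assert out.loc["a", "b"] == pytest.approx(p_raw)  # m = 1


def test_bonferroni_cap_at_one():
    rng = np.random.default_rng(5)
    groups = {k: rng.normal(0, 1, 15) for k in "abcd"}  # null: 6 pairs
    out = bonferroni_pairwise(groups)
    assert (out.fillna(0).to_numpy() <= 1.0).all()
    # raw p ~ U(0,1) under the null; capping must bite for any p_raw > 1/6
    a, b = groups["a"], groups["b"]
    _, p_raw = stats.ttest_ind(a, b, equal_var=True)
    assert out.loc["a", "b"] == pytest.approx(min(1.0, 6 * p_raw))


def test_bonferroni_small_group_excluded():
    rng = np.random.default_rng(6)
    groups = {"a": rng.normal(size=10), "b": rng.normal(size=10), "tiny": [1.0]}
    with pytest.warns(UserWarning, match="excluded"):
        out = bonferroni_pairwise(groups)
    assert "tiny" not in out.index


def test_bonferroni_planted_shift_simulation():
    """One shifted group among four: only its three pairs significant."""
    hits_shifted, hits_null = 0, 0
    n_pairs_shifted, n_pairs_null = 0, 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        groups = {k: rng.normal(0, 1, 60) for k in "abc"}
        groups["d"] = rng.normal(1.2, 1, 60)  # shifted
        out = bonferroni_pairwise(groups)
        for a in "abc":
            hits_shifted += out.loc[a, "d"] < 0.05
            n_pairs_shifted += 1
        for a, b in (("a", "b"), ("a", "c"), ("b", "c")):
            hits_null += out.loc[a, b] < 0.05
            n_pairs_null += 1
    assert hits_shifted / n_pairs_shifted > 0.95
    assert hits_null / n_pairs_null < 0.15


# ---------------------------------------------------------------------------
# prevalence and naming


def test_prevalence_all_diseased_single_community(small_planted_cohort):
    records = [r for r in small_planted_cohort if r.diseases["hypertension"]]
    prev = prevalence_table(records, [0] * len(records))
    assert prev.prevalence.loc["hypertension", 0] == pytest.approx(1.0)
    assert prev.shares[0] == pytest.approx(1.0)


def test_prevalence_matches_planted_monte_carlo():
    cfg = planted_config(5000, n_groups=4, seed=9)
    records = generate_cohort(cfg)
    labels = [r.planted_group for r in records]
    prev = prevalence_table(records, labels)
    for d in DISEASES:
        for g in range(4):
            n_g = prev.sizes[g]
            p = cfg.disease_prevalence[d][g]
            se = np.sqrt(p * (1 - p) / n_g)
            assert abs(prev.prevalence.loc[d, g] - p) < 4 * se + 0.01


def _reference_prevalence_table():
    sizes = pd.Series({1: 471, 2: 127, 3: 1463, 4: 245})
    prev_vals = pd.DataFrame(
        {
            1: [0.520, 0.701, 0.318, 0.310, 0.200],
            2: [0.362, 0.693, 0.252, 0.307, 0.220],
            3: [0.450, 0.660, 0.283, 0.305, 0.228],
            4: [0.359, 0.612, 0.261, 0.208, 0.139],
        },
        index=list(DISEASES),
    )
    counts = (prev_vals * sizes).round().astype(int)
    return PrevalenceTable(
        counts=counts, prevalence=prev_vals, sizes=sizes, shares=sizes / sizes.sum()
    )


def test_name_patterns_reference_profile():
    names = name_patterns(_reference_prevalence_table())
    assert names == {1: "HPG", 2: "UADCG", 3: "MDHG", 4: "KDLG"}


def test_name_patterns_tie_fallback():
    sizes = pd.Series({0: 10, 1: 10, 2: 10, 3: 10})
    prev_vals = pd.DataFrame(
        {p: [0.5, 0.5, 0.5, 0.5, 0.5] for p in range(4)}, index=list(DISEASES)
    )
    table = PrevalenceTable(
        counts=(prev_vals * sizes).astype(int),
        prevalence=prev_vals,
        sizes=sizes,
        shares=sizes / 40,
    )
    with pytest.warns(UserWarning, match="tie"):
        names = name_patterns(table)
    assert names == {p: f"Pattern-{p}" for p in range(4)}


def test_name_patterns_label_permutation_consistent():
    base = _reference_prevalence_table()
    names = name_patterns(base)
    # permute community labels; name-to-member mapping must follow
    perm = {1: 4, 2: 3, 3: 2, 4: 1}
    permuted = PrevalenceTable(
        counts=base.counts.rename(columns=perm),
        prevalence=base.prevalence.rename(columns=perm),
        sizes=base.sizes.rename(index=perm),
        shares=base.shares.rename(index=perm),
    )
    names_perm = name_patterns(permuted)
    for old, new in perm.items():
        assert names_perm[new] == names[old]


def test_characterize_end_to_end(small_planted_cohort):
    labels = [r.planted_group for r in small_planted_cohort]
    profile = characterize(small_planted_cohort, labels)
    assert profile.prevalence.sizes.sum() == len(small_planted_cohort)
    assert set(profile.disease_tests["variable"]) == set(DISEASES)
    assert "age" in profile.posthoc
    assert len(profile.names) == 4


def test_contingency_from_records(small_planted_cohort):
    labels = [r.planted_group for r in small_planted_cohort]
    table = contingency_from_records(small_planted_cohort, labels, lambda r: r.gender)
    assert table.to_numpy().sum() == len(small_planted_cohort)
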