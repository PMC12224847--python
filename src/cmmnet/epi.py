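"""Per-pattern epidemiological characterization.

Pearson chi-square, one-way ANOVA (raw-data and summary-statistics entry
points) and Bonferroni pairwise t tests are coded from the textbook formulas;
scipy supplies only the tail probabilities.  Rule-based pattern naming mirrors
the disease-prevalence reasoning used to label the four reference patterns.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DISEASES, PatientRecord

__all__ = [
    "PrevalenceTable",
    "PatternProfile",
    "prevalence_table",
    "chi_square_test",
    "contingency_from_records",
    "anova_oneway",
    "anova_from_summaries",
    "bonferroni_pairwise",
    "name_patterns",
    "characterize",
]


@dataclass
class PrevalenceTable:
    """Disease x pattern counts, prevalence fractions, pattern sizes/shares."""

    counts: pd.DataFrame       # diseases x patterns, integer counts
    prevalence: pd.DataFrame   # diseases x patterns, fractions in [0, 1]
    sizes: pd.Series           # pattern -> n members
    shares: pd.Series          # pattern -> fraction of cohort

    @property
    def patterns(self) -> list:
        return list(self.sizes.index)


def prevalence_table(
    records: Sequence[PatientRecord],
    labels: Sequence[int] | Mapping[str, int],
) -> PrevalenceTable:
    """Per-pattern disease counts and prevalences plus pattern shares."""
    if isinstance(labels, Mapping):
        lab = [labels[r.id] for r in records]
    else:
        lab = list(labels)
        if len(lab) != len(records):
            raise ValueError("every record must be assigned a pattern")
    patterns = sorted(set(lab))
    sizes = pd.Series(
        {p: sum(1 for v in lab if v == p) for p in patterns}, name="n"
    )
    counts = pd.DataFrame(0, index=list(DISEASES), columns=patterns)
    for rec, p in zip(records, lab):
        for d in DISEASES:
            if rec.diseases.get(d, False):
                counts.loc[d, p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prevalence = counts / sizes
    total = sizes.sum()
    shares = sizes / total if total else sizes.astype(float)
    return PrevalenceTable(counts=counts, prevalence=prevalence, sizes=sizes, shares=shares)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table (no continuity correction).

    Returns (statistic, df, p).  E = row total * column total / grand total;
    df = (r - 1)(c - 1).  Zero row/column margins are degenerate.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (observed < 0).any():
        raise ValueError("counts must be nonnegative")
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    total = observed.sum()
    expected = np.outer(row, col) / total
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def contingency_from_records(
    records: Sequence[PatientRecord],
    labels: Sequence[int],
    getter,
) -> pd.DataFrame:
    """Level x pattern count table for one categorical variable.

    ``getter`` maps a record to its level (e.g. ``lambda r: r.gender``).
    """
    values = [getter(r) for r in records]
    levels = sorted(set(values), key=str)
    patterns = sorted(set(labels))
    table = pd.DataFrame(0, index=levels, columns=patterns)
    for v, p in zip(values, labels):
        table.loc[v, p] += 1
    return table


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA on raw per-group values.

    Returns (F, df_between, df_within, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("F is undefined: zero within- and between-group variance")
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def anova_from_summaries(
    ns: Sequence[int],
    means: Sequence[float],
    sds: Sequence[float],
) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) summaries.

    SDs are interpreted with the sample (ddof=1) convention:
    SSW = sum (n_i - 1) s_i^2, SSB = sum n_i (m_i - grand mean)^2.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (len(ns) == len(means) == len(sds)) or len(ns) < 2:
        raise ValueError("need matched summaries for at least 2 groups")
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("SDs must be >= 0")
    grand = float((ns * means).sum() / ns.sum())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1 = len(ns) - 1
    df2 = int(ns.sum()) - len(ns)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("F is undefined: zero within- and between-group variance")
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def bonferroni_pairwise(
    groups: Mapping[object, Sequence[float]] | Sequence[Sequence[float]],
) -> pd.DataFrame:
    """All pairwise two-sample pooled-variance t tests, Bonferroni-adjusted.

    Adjusted p = min(1, m * p_raw) with m = number of pairs tested.  Groups
    with n < 2 are excluded with a warning.  Returns a symmetric matrix of
    adjusted p-values (diagonal NaN).
    """
    if not isinstance(groups, Mapping):
        groups = {i: g for i, g in enumerate(groups)}
    usable = {}
    for key, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 2:
            warnings.warn(f"group {key!r} has n < 2; excluded from pairwise tests")
            continue
        usable[key] = arr
    keys = list(usable)
    if len(keys) < 2:
        raise ValueError("need at least 2 usable groups")
    pairs = list(itertools.combinations(keys, 2))
    m = len(pairs)
    out = pd.DataFrame(np.nan, index=keys, columns=keys)
    for a, b in pairs:
        _, p_raw = stats.ttest_ind(usable[a], usable[b], equal_var=True)
        adj = min(1.0, m * float(p_raw))
        out.loc[a, b] = out.loc[b, a] = adj
    return out


# --------------------------------------------------------------------------
# Naming


def name_patterns(prev: PrevalenceTable) -> dict:
    """Deterministic rule-based names for the detected patterns.

    Rules: the pattern with the highest hypertension prevalence is the
    hypertension-predominant group (HPG); the one with the lowest CKD
    prevalence is the kidney-disease-low group (KDLG); the largest remaining
    pattern is the multiple-diseases-high group (MDHG); the final remaining
    pattern is the uric-acid/dyslipidemia group (UADCG).  Any rule collision
    or exact tie falls back to generic "Pattern-k" names.
    """
    patterns = prev.patterns
    fallback = {p: f"Pattern-{p}" for p in patterns}
    if len(patterns) != 4:
        return fallback

    hyp = prev.prevalence.loc["hypertension"]
    ckd = prev.prevalence.loc["ckd"]
    if (hyp == hyp.max()).sum() > 1 or (ckd == ckd.min()).sum() > 1:
        warnings.warn("tie in naming rules; using generic pattern names")
        return fallback
    hpg = hyp.idxmax()
    kdlg = ckd.idxmin()
    if hpg == kdlg:
        warnings.warn("naming rules collide; using generic pattern names")
        return fallback
    rest = [p for p in patterns if p not in (hpg, kdlg)]
    rest_sizes = prev.sizes[rest]
    if (rest_sizes == rest_sizes.max()).sum() > 1:
        warnings.warn("tie in naming rules; using generic pattern names")
        return fallback
    mdhg = rest_sizes.idxmax()
    uadcg = [p for p in rest if p != mdhg][0]
    return {hpg: "HPG", uadcg: "UADCG", mdhg: "MDHG", kdlg: "KDLG"}


@dataclass
class PatternProfile:
    """Full characterization: prevalences, test results, post-hoc, names."""

    prevalence: PrevalenceTable
    disease_tests: pd.DataFrame        # per disease: chi2, df, p
    categorical_tests: pd.DataFrame    # per categorical variable: chi2, df, p
    continuous_tests: pd.DataFrame     # per continuous variable: F, df1, df2, p
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    names: dict = field(default_factory=dict)


_CATEGORICAL_GETTERS = {
    "gender": lambda r: r.gender,
    "marital_status": lambda r: r.marital_status,
    "education": lambda r: r.education,
    "smoking_100": lambda r: int(r.smoking_100),
}


def _continuous_value(record: PatientRecord, name: str) -> float:
    for source in (record.activity_minutes, record.nutrient_intakes, record.biomarkers):
        if name in source:
            return float(source[name])
    return float(getattr(record, name))


def characterize(
    records: Sequence[PatientRecord],
    labels: Sequence[int],
    continuous_vars: Sequence[str] = ("age", "family_pir", "bmi"),
    categorical_vars: Sequence[str] = ("gender", "marital_status", "education", "smoking_100"),
    posthoc: bool = True,
) -> PatternProfile:
    """Assemble the per-pattern profile: prevalences, tests, post-hoc, names.

    Empty patterns are retained in listings but excluded from tests.
    """
    labels = list(labels)
    prev = prevalence_table(records, labels)
    tested = [p for p in prev.patterns if prev.sizes[p] > 0]

    disease_rows = []
    for d in DISEASES:
        with_d = prev.counts.loc[d, tested].to_numpy(dtype=float)
        without = prev.sizes[tested].to_numpy(dtype=float) - with_d
        table = np.vstack([with_d, without]).T  # patterns x {with, without}
        try:
            chi2, df, p = chi_square_test(table)
        except ValueError:
            chi2, df, p = np.nan, 0, np.nan
        disease_rows.append((d, chi2, df, p))
    disease_tests = pd.DataFrame(disease_rows, columns=["variable", "chi2", "df", "p"])

    cat_rows = []
    for name in categorical_vars:
        table = contingency_from_records(records, labels, _CATEGORICAL_GETTERS[name])
        table = table[tested]
        table = table.loc[table.sum(axis=1) > 0]
        try:
            chi2, df, p = chi_square_test(table.to_numpy())
        except ValueError:
            chi2, df, p = np.nan, 0, np.nan
        cat_rows.append((name, chi2, df, p))
    categorical_tests = pd.DataFrame(cat_rows, columns=["variable", "chi2", "df", "p"])

    cont_rows = []
    posthoc_tables: dict[str, pd.DataFrame] = {}
    for name in continuous_vars:
        groups = {
            p: [_continuous_value(r, name) for r, lab in zip(records, labels) if lab == p]
            for p in tested
        }
        group_list = [g for g in groups.values() if len(g) >= 2]
        if len(group_list) < 2:
            cont_rows.append((name, np.nan, 0, 0, np.nan))
            continue
        f, df1, df2, p = anova_oneway(group_list)
        cont_rows.append((name, f, df1, df2, p))
        if posthoc:
            posthoc_tables[name] = bonferroni_pairwise(groups)
    continuous_tests = pd.DataFrame(cont_rows, columns=["variable", "F", "df1", "df2", "p"])

    return PatternProfile(
        prevalence=prev,
        disease_tests=disease_tests,
        categorical_tests=categorical_tests,
        continuous_tests=continuous_tests,
        posthoc=posthoc_tables,
        names=name_patterns(prev),
    )
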