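"""Two-group comparison layer mirroring the cohort-characteristics table.

Test selection follows the presentation convention of the characteristics
table: Welch/pooled t for variables summarized as mean (SD), Wilcoxon
rank-sum for variables summarized as median [IQR], chi-squared with Yates
continuity correction for 2x2 proportions (Fisher's exact test when expected
counts are small), and plain chi-squared for the 3-level DMT contingency
table (the continuity correction applies only at 1 degree of freedom).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable
from .errors import ConfigurationError, DegenerateTableError, InsufficientDataError

TESTS = ("chi2_cc", "chi2", "welch_t", "pooled_t", "wilcoxon", "fisher")


@dataclasses.dataclass
class ComparisonResult:
    """One two-group comparison: summaries, statistic and p-value."""

    variable: str
    test: str
    summary: Mapping[str, str]
    statistic: float
    p_value: float


def _as_2x2(table):
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ConfigurationError(f"table: expected 2x2, got shape {table.shape}")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.number):
        raise ConfigurationError("table: entries must be nonnegative integers")
    return table.astype(np.int64)


def chi_square_2x2_cc(table) -> ComparisonResult:
    """Yates continuity-corrected chi-squared test for a 2x2 table.

    Statistic: ``max(|ad - bc| - n/2, 0)^2 * n / (r1 r2 c1 c2)``, referred to
    the chi-squared distribution with 1 df.
    """
    t = _as_2x2(table)
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    num = max(abs(int(a) * int(d) - int(b) * int(c)) - n / 2.0, 0.0) ** 2 * n
    stat = num / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(sps.chi2.sf(stat, 1))
    return ComparisonResult("table", "chi2_cc", _count_summary(t), float(stat), p)


def chi_square_rxc(table) -> ComparisonResult:
    """Pearson chi-squared for an r x c table (no continuity correction)."""
    t = np.asarray(table, np.int64)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return ComparisonResult("table", "chi2", _count_summary(t), float(stat), float(p))


def fisher_exact_2x2(table) -> ComparisonResult:
    """Fisher's exact test, two-sided by hypergeometric probability mass."""
    t = _as_2x2(table)
    if t.sum() == 0 or (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        # degenerate margins carry no evidence; documented p = 1 convention
        return ComparisonResult("table", "fisher", _count_summary(t), float("nan"), 1.0)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return ComparisonResult("table", "fisher", _count_summary(t), float("nan"), float(p))


def _count_summary(t):
    return {"BA": f"{t[0, 0]}/{t[0].sum()}", "WA": f"{t[1, 0]}/{t[1].sum()}"}


def two_sample_t(x, y, equal_var: bool = False) -> ComparisonResult:
    """Two-sample t test; Welch (default) or pooled-variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("two_sample_t: each group needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    summary = {"BA": f"{x.mean():.2f} ({x.std(ddof=1):.2f})",
               "WA": f"{y.mean():.2f} ({y.std(ddof=1):.2f})"}
    name = "pooled_t" if equal_var else "welch_t"
    return ComparisonResult("", name, summary, float(res.statistic), float(res.pvalue))


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2,
                              equal_var: bool = False) -> ComparisonResult:
    """Same test from per-group summary statistics (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("two_sample_t_from_summary: each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise InsufficientDataError("two_sample_t_from_summary: sds must be > 0")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    summary = {"BA": f"{mean1:.2f} ({sd1:.2f})", "WA": f"{mean2:.2f} ({sd2:.2f})"}
    name = "pooled_t" if equal_var else "welch_t"
    return ComparisonResult("", name, summary, float(res.statistic), float(res.pvalue))


def _midranks(pooled):
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_sum(x, y, exact_limit: int = 12) -> ComparisonResult:
    """Wilcoxon rank-sum test with midranks for ties.

    Exact enumeration of all rank assignments when the combined sample size
    is at most ``exact_limit``; otherwise a normal approximation with
    tie-corrected variance and continuity correction.  Two-sided p-value is
    twice the smaller tail, capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise InsufficientDataError("rank_sum: each group needs n >= 1")
    pooled = np.concatenate([x, y])
    N = n1 + n2
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())

    if N <= exact_limit:
        sums = np.array([ranks[list(c)].sum() for c in combinations(range(N), n1)])
        eps = 1e-9
        p = 2.0 * min(np.mean(sums <= w + eps), np.mean(sums >= w - eps))
        p = min(float(p), 1.0)
    else:
        mu = n1 * (N + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / np.sqrt(var)
            p = min(2.0 * float(sps.norm.sf(max(z, 0.0))), 1.0)

    def iqr(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"

    summary = {"BA": iqr(x), "WA": iqr(y)}
    return ComparisonResult("", "wilcoxon", summary, w, p)


# ---------------------------------------------------------------------------
# table-one assembly

@dataclasses.dataclass
class PlanItem:
    """One characteristics-table row: variable, test and how to summarize."""

    variable: str
    test: str
    label: str | None = None

    def __post_init__(self):
        if self.test not in TESTS:
            raise ConfigurationError(f"test: unknown test {self.test!r}")


def default_variable_plan() -> list[PlanItem]:
    """The 12-row default plan mirroring the characteristics table."""
    return [
        PlanItem("sex", "chi2_cc", "Male, n (%)"),
        PlanItem("disease_duration", "welch_t", "Disease duration (years), mean (SD)"),
        PlanItem("age", "welch_t", "Age (years), mean (SD)"),
        PlanItem("zip_income", "welch_t", "Median zip code income ($), mean (SD)"),
        PlanItem("dmt", "chi2", "DMT type, n (%)"),
        PlanItem("edss", "wilcoxon", "EDSS, median [IQR]"),
        PlanItem("flair_volume", "welch_t", "Total FLAIR lesion volume (mm3), mean (SD)"),
        PlanItem("flair_count", "welch_t", "FLAIR lesion number, mean (SD)"),
        PlanItem("prl_count", "welch_t", "PRL number, mean (SD)"),
        PlanItem("prl_percentage", "welch_t", "Percentage of PRL lesions, mean (SD)"),
        PlanItem("non_prl_volume", "welch_t", "Non-PRL FLAIR lesion volume (mm3), mean (SD)"),
        PlanItem("prl_positive", "chi2_cc", "At least one PRL, n (%)"),
    ]


_DERIVED = {
    "prl_positive": lambda df: (df["prl_count"] >= 1),
    "sex": lambda df: (df["sex"] == "male"),
}


def _binary_table(df, col):
    flags = _DERIVED[col](df) if col in _DERIVED else df[col].astype(bool)
    ba = flags[df["race"] == "BA"]
    wa = flags[df["race"] == "WA"]
    return np.array([[ba.sum(), (~ba).sum()], [wa.sum(), (~wa).sum()]], np.int64)


def table_one(cohort: CohortTable | pd.DataFrame,
              plan: Sequence[PlanItem] | None = None) -> list[ComparisonResult]:
    """Run the per-variable two-group comparisons in plan order."""
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    plan = list(plan) if plan is not None else default_variable_plan()
    results = []
    for item in plan:
        if item.variable not in df.columns and item.variable not in _DERIVED:
            raise ConfigurationError(f"variable_plan: unknown column {item.variable!r}")
        if item.test in ("chi2_cc", "fisher"):
            table = _binary_table(df, item.variable)
            res = chi_square_2x2_cc(table) if item.test == "chi2_cc" \
                else fisher_exact_2x2(table)
        elif item.test == "chi2":
            levels = sorted(df[item.variable].unique())
            table = np.array([
                [(df[(df["race"] == r)][item.variable] == lv).sum() for lv in levels]
                for r in ("BA", "WA")], np.int64)
            res = chi_square_rxc(table)
        else:
            ba = df.loc[df["race"] == "BA", item.variable].to_numpy(float)
            wa = df.loc[df["race"] == "WA", item.variable].to_numpy(float)
            if item.test in ("welch_t", "pooled_t"):
                res = two_sample_t(ba, wa, equal_var=(item.test == "pooled_t"))
            else:
                res = rank_sum(ba, wa)
        res.variable = item.label or item.variable
        results.append(res)
    return results


def table_one_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "variable": [r.variable for r in results],
        "BA": [r.summary.get("BA", "") for r in results],
        "WA": [r.summary.get("WA", "") for r in results],
        "test": [r.test for r in results],
        "statistic": [r.statistic for r in results],
        "p_value": [r.p_value for r in results],
    })


def table_one_markdown(results: Sequence[ComparisonResult]) -> str:
    frame = table_one_frame(results)
    header = "| " + " | ".join(frame.columns) + " |"
    rule = "|" + "|".join(["---"] * len(frame.columns)) + "|"
    lines = [header, rule]
    for _, row in frame.iterrows():
        cells = [str(row["variable"]), str(row["BA"]), str(row["WA"]), str(row["test"]),
                 "" if not np.isfinite(row["statistic"]) else f"{row['statistic']:.4g}",
                 f"{row['p_value']:.4g}"]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
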