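"""Cohort-level statistics on NUMT abundance.

Wraps the standard tests used to compare tumor against matched normal
abundance: paired t on log-transformed proportions, Welch's unequal-
variance t for group contrasts (sex, disease site), Mann-Whitney U for
small ordinal groups (vital status), OLS regression of log2 tumor on log2
blood proportions, the arm-level fold-change-vs-mapped-reads regression
(an aneuploidy check) and the window-level fold-change-vs-GC association.

Degenerate inputs (zero variance where a test needs spread) return a
flagged :class:`TestResult` rather than raising or producing infinities.
No multiple-testing correction is applied by default; a Benjamini-
Hochberg helper is provided for window-level scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GIEMSA_GROUPS


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    tails: str  # 'one' | 'two'
    method: str
    n: int
    n2: int | None = None
    df: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False


def _as_positive(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if np.any(~(a > 0)):
        raise ValueError(f"{name} must be strictly positive for a log transform")
    return a


def paired_t_log(p_t, p_h, tails: str = "two", base: float = 2.0) -> TestResult:
    """Paired t-test on log-transformed proportions.

    The statistic is computed on the per-participant log differences
    (df = n - 1); the log base is immaterial to t and p.  One-tailed p is
    reported for the alternative tumor > healthy.
    """
    a = _as_positive(p_t, "p_t")
    b = _as_positive(p_h, "p_h")
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = (np.log(a) - np.log(b)) / np.log(base)
    n = d.size
    sd = d.std(ddof=1)
    # all differences (numerically) identical: the t statistic is unbounded
    if sd <= 1e-12 * max(abs(d.mean()), 1e-300):
        return TestResult(np.nan, np.nan, tails, "paired t (log)", n, df=n - 1,
                          degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p_two = 2 * stats.t.sf(abs(t), n - 1)
    if tails == "one":
        p = stats.t.sf(t, n - 1)  # H1: tumor > healthy
    else:
        p = p_two
    return TestResult(float(t), float(p), tails, "paired t (log)", n, df=n - 1)


def welch_t(group_a, group_b, tails: str = "two") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return TestResult(np.nan, np.nan, tails, "Welch t", a.size, b.size,
                          degenerate=True)
    t, p_two = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    if tails == "one":
        p = stats.t.sf(t, df)
    else:
        p = p_two
    return TestResult(float(t), float(p), tails, "Welch t", a.size, b.size,
                      df=float(df))


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U (U reported for the first group).

    Exact p for min(n1, n2) <= 8 without ties; tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "two",
                      f"Mann-Whitney U ({method})", a.size, b.size)


def regress_log2(p_t, p_h) -> RegressionResult:
    """OLS of log2 tumor proportion on log2 healthy proportion."""
    y = np.log2(_as_positive(p_t, "p_t"))
    x = np.log2(_as_positive(p_h, "p_h"))
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:  # constant response: flat line, nothing explained
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, x.size)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue**2), float(res.pvalue), x.size)


def arm_aneuploidy_regression(rescaled_arm, mapped_arm) -> RegressionResult:
    """Linear regression of arm-level R' on arm mapped-read count.

    A nonzero slope would indicate that apparent NUMT enrichment tracks
    chromosome-arm dosage (aneuploidy) rather than genuine integration.
    """
    y = np.asarray(rescaled_arm, dtype=float)
    x = np.asarray(mapped_arm, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, x.size)
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue**2), float(res.pvalue), x.size)


def gc_association(rescaled_win, gc_win) -> CorrelationResult:
    """Pearson and Spearman association of window R' with window GC."""
    y = np.asarray(rescaled_win, dtype=float)
    x = np.asarray(gc_win, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, x.size,
                                 degenerate=True)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(float(pr.statistic), float(pr.pvalue),
                             float(sr.statistic), float(sr.pvalue), x.size)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional, for window-level scans)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# tabular summaries


def giemsa_group_summary(
    ratio_records: pd.DataFrame,
    cytobands,
    threshold: float = 4.2,
) -> pd.DataFrame:
    """Distribution of cytoband-level R' per Giemsa stain group.

    Only the five stain groups gneg/gpos25/gpos50/gpos75/gpos100 are
    summarized (acen, gvar and stalk bands are excluded).  Reports n,
    quartiles and mean of R' plus the count of bands at or above the
    fold-change ``threshold`` (default 4.2).  Empty groups are omitted.
    """
    stain_map = {iv.id: iv.attrs.get("stain") for iv in cytobands}
    df = ratio_records.assign(stain=ratio_records["interval_id"].map(stain_map))
    df = df[df["stain"].isin(GIEMSA_GROUPS)]
    rows = []
    for stain in GIEMSA_GROUPS:
        grp = df.loc[df["stain"] == stain, "rescaled"].dropna()
        if grp.empty:
            continue
        q1, med, q3 = np.percentile(grp, [25, 50, 75])
        rows.append(
            {
                "stain": stain,
                "n": int(grp.size),
                "q1": q1,
                "median": med,
                "q3": q3,
                "mean": grp.mean(),
                "n_above_threshold": int((grp >= threshold).sum()),
            }
        )
    return pd.DataFrame(rows)


STRATIFIED_TESTS = {
    "sex": "welch",
    "disease": "welch",
    "vital_status": "mannwhitney",
    "stage": "welch",
}


def stratified_summary(
    cohort: pd.DataFrame,
    by: str,
    value_col: str = "fold_change",
) -> tuple[pd.DataFrame, TestResult | None]:
    """Group medians/ranges of per-sample fold change, plus the group test.

    Welch's t for sex/disease/stage, Mann-Whitney for vital status (as the
    group sizes there are tiny and skewed).  The test is run only for
    exactly two non-empty groups; groups of size 0 are dropped.  Pass
    ``value_col`` pointing at raw proportions to test those instead.
    """
    if by not in cohort.columns:
        raise KeyError(f"covariate {by!r} not in cohort table")
    df = cohort.dropna(subset=[by, value_col])
    summary = (
        df.groupby(by)[value_col]
        .agg(n="size", median="median", min="min", max="max")
        .reset_index()
    )
    summary = summary[summary["n"] > 0]
    test = None
    groups = [g[value_col].to_numpy() for _, g in df.groupby(by)]
    if len(groups) == 2:
        kind = STRATIFIED_TESTS.get(by, "welch")
        if kind == "mannwhitney":
            test = mann_whitney(groups[0], groups[1])
        elif min(len(g) for g in groups) >= 2:
            test = welch_t(groups[0], groups[1])
    return summary, test


def cohort_fold_summary(fold_changes) -> dict[str, float]:
    """Headline cohort numbers: mean of per-sample R_gen and the ratio of
    cohort mean proportions (both conventions are reported)."""
    fc = np.asarray(fold_changes, dtype=float)
    fc = fc[~np.isnan(fc)]
    return {
        "mean_fold_change": float(fc.mean()),
        "median_fold_change": float(np.median(fc)),
        "n": int(fc.size),
    }
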