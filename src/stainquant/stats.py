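"""Nonparametric cohort statistics, efficiency-corrected expression ratios,
and growth-rate arithmetic.

The cohort design is a randomized block: every donor contributes one value
per condition, so donors are the blocking factor.  Condition effects are
tested with the Friedman rank test (>= 3 matched conditions) followed by
paired Wilcoxon signed-rank post-hoc comparisons, both two-sided at
alpha = 0.05.  No multiple-testing correction is applied by default (an
optional Holm adjustment is available in :func:`compare_conditions`).

Expression ratios follow the efficiency-corrected relative-quantification
model: with amplification efficiencies ``E`` (2.0 = perfect doubling per
cycle) and crossing-point differences taken control - sample,

    ratio = E_target ** dCt_target / E_reference ** dCt_reference

and fold changes are these ratios normalised to the matched within-donor
control condition.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """Statistic + p-value of one hypothesis test."""

    statistic: float
    pvalue: float
    n: int
    method: str


def _complete_blocks(data) -> np.ndarray:
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D donors x conditions array")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"friedman_test: dropped {dropped} incomplete donor block(s)")
    return arr[complete]


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic from within-block ranks."""
    n, k = ranks.shape
    colsums = ranks.sum(axis=0)
    ss = float(np.sum((colsums - n * (k + 1) / 2.0) ** 2))
    chisq = 12.0 * ss / (n * k * (k + 1))
    # tie correction: scale by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = n * k * (k * k - 1)
    c = 1.0 - ties / denom
    if c <= 0:
        return 0.0  # every block fully tied: no ranking signal
    return chisq / c


def friedman_test(data, method: str = "approx") -> TestResult:
    """Friedman rank test over a donors x conditions block design.

    ``data`` is a 2-D array (rows = donors, columns = conditions); donors
    with any missing value are dropped listwise.  Within-block ranks use
    mid-ranks for ties.  ``method="approx"`` reports the chi-square
    approximation (df = k - 1); ``method="exact"`` enumerates the
    within-block permutation null distribution (feasible for small cohorts)
    and reports the exact permutation p-value of the same statistic.
    """
    arr = _complete_blocks(data)
    n, k = arr.shape
    if k < 3:
        raise ValueError("friedman_test requires at least 3 conditions")
    if n < 3:
        raise ValueError("friedman_test requires at least 3 complete blocks")
    ranks = np.vstack([sps.rankdata(row) for row in arr])
    stat = _friedman_statistic(ranks)
    if method == "approx":
        p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        return TestResult(stat, min(p, 1.0), n, "friedman-chisq")
    if method == "exact":
        p = _friedman_exact_pvalue(ranks)
        return TestResult(stat, p, n, "friedman-exact")
    raise ValueError(f"unknown method {method!r}")


def _friedman_exact_pvalue(ranks: np.ndarray) -> float:
    """Exact permutation p-value by dynamic programming over column sums.

    All ``k!`` orderings within each block are equally likely under the null;
    the distribution of the column-sum vector is built block by block (ranks
    doubled to stay integral with mid-rank ties).  The tie correction is
    constant across permutations, so the rank sum-of-squares orders
    permutations identically to the corrected statistic.
    """
    n, k = ranks.shape
    r2 = np.round(2 * ranks).astype(np.int64)
    perms = list(itertools.permutations(range(k)))
    dist: dict[tuple, int] = {tuple([0] * k): 1}
    for row in r2:
        new: dict[tuple, int] = {}
        for colsum, count in dist.items():
            for p in perms:
                key = tuple(colsum[j] + int(row[p[j]]) for j in range(k))
                new[key] = new.get(key, 0) + count
        dist = new
    obs = tuple(int(v) for v in r2.sum(axis=0))

    def ss(colsums):
        m = sum(colsums) / k
        return sum((c - m) ** 2 for c in colsums)

    ss_obs = ss(obs)
    total = sum(dist.values())
    ge = sum(c for cs, c in dist.items() if ss(cs) >= ss_obs - 1e-9)
    return ge / total


def wilcoxon_signed_rank(
    paired_a,
    paired_b,
    *,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
) -> TestResult:
    """Paired Wilcoxon signed-rank test on donor-matched values.

    Zero differences are dropped by default (``zero_method="wilcox"``; the
    Pratt treatment is available).  The exact sign-flip distribution is used
    whenever the retained sample is small enough and tie-free (delegated to
    scipy's method selection); with all differences zero the test is
    degenerate and p = 1 is returned with a warning.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"wilcoxon_signed_rank: dropped {dropped} incomplete pair(s)")
    a, b = a[keep], b[keep]
    d = a - b
    if np.all(d == 0):
        warnings.warn("wilcoxon_signed_rank: all differences zero; p = 1")
        return TestResult(0.0, 1.0, int(d.size), "wilcoxon-degenerate")
    res = sps.wilcoxon(a, b, alternative=alternative, zero_method=zero_method,
                       method="auto")
    n_eff = int(np.count_nonzero(d)) if zero_method == "wilcox" else int(d.size)
    return TestResult(float(res.statistic), float(res.pvalue), n_eff, "wilcoxon")


# ---------------------------------------------------------------------------
# Relative expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One qPCR measurement: target and reference crossing points.

    ``efficiency_*`` are per-cycle amplification factors in [1, 2.2]; 2.0 is
    perfect doubling and is the default when efficiencies were not measured.
    """

    gene: str
    ct_target: float
    ct_reference: float
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self):
        for name in ("efficiency_target", "efficiency_reference"):
            e = getattr(self, name)
            if not (1.0 <= e <= 2.2):
                raise ValueError(f"{name} must lie in [1, 2.2], got {e}")
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


def pfaffl_ratio(sample: ExpressionMeasurement, control: ExpressionMeasurement) -> float:
    """Efficiency-corrected expression ratio of ``sample`` relative to ``control``.

    ``E_target ** (Ct_control,target - Ct_sample,target)`` divided by
    ``E_reference ** (Ct_control,ref - Ct_sample,ref)``, using the sample's
    efficiencies.
    """
    dct_target = control.ct_target - sample.ct_target
    dct_ref = control.ct_reference - sample.ct_reference
    return (
        sample.efficiency_target**dct_target
        / sample.efficiency_reference**dct_ref
    )


def fold_change_normalize(
    ratios: pd.DataFrame,
    control_condition: str,
    *,
    value_col: str = "value",
    condition_col: str = "condition",
    match_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Normalise expression ratios to the matched within-donor control.

    Every row's value is divided by the value of the ``control_condition``
    row sharing the same matching keys (by default every column except the
    condition and value columns, e.g. donor / culture system / day / gene).
    Control rows therefore map to exactly 1.  Rows lacking a matched control
    get NaN with a warning.  The result adds a ``fold_change`` column;
    applying the normalisation twice is idempotent.
    """
    df = ratios.copy()
    if match_cols is None:
        match_cols = tuple(c for c in df.columns if c not in (value_col, condition_col))
    controls = df[df[condition_col] == control_condition]
    if controls.duplicated(list(match_cols)).any():
        raise ValueError("multiple control rows for the same matching keys")
    ctrl = controls.set_index(list(match_cols))[value_col]
    keys = pd.MultiIndex.from_frame(df[list(match_cols)])
    matched = ctrl.reindex(keys).to_numpy()
    missing = np.isnan(matched)
    if missing.any():
        warnings.warn(
            f"fold_change_normalize: {int(missing.sum())} row(s) without a "
            "matched control; fold change set to NaN"
        )
    df["fold_change"] = df[value_col].to_numpy() / matched
    return df


def generation_time(n_start: float, n_end: float, elapsed_hours: float) -> float:
    """Population doubling time from two cell counts.

    ``GT = elapsed * ln(2) / (ln(n_end) - ln(n_start))``; without growth the
    generation time is undefined and NaN is returned with a warning.
    """
    if n_start <= 0:
        raise ValueError("n_start must be positive")
    if elapsed_hours <= 0:
        raise ValueError("elapsed_hours must be positive")
    if n_end <= n_start:
        warnings.warn("generation_time: no growth (n_end <= n_start); undefined")
        return float("nan")
    return elapsed_hours * math.log(2.0) / (math.log(n_end) - math.log(n_start))


# ---------------------------------------------------------------------------
# Cohort comparison driver and display helpers
# ---------------------------------------------------------------------------


def compare_conditions(
    cohort: pd.DataFrame,
    *,
    control_condition: str = "control",
    value_col: str = "value",
    condition_col: str = "condition",
    donor_col: str = "donor",
    day_col: str = "day",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Friedman omnibus + Wilcoxon post-hoc tables for one metric.

    Within each day, an omnibus Friedman test across all conditions is
    followed by paired Wilcoxon tests of every condition against the control
    ("star" comparisons); additionally each condition is compared between
    the two days ("hash" comparisons).  Donors missing from a pair are
    dropped listwise.  ``holm=True`` applies a Holm step-down adjustment to
    the post-hoc p-values (off by default).
    """
    rows = []
    days = sorted(cohort[day_col].unique())
    conditions = list(dict.fromkeys(cohort[condition_col]))
    for day in days:
        sub = cohort[cohort[day_col] == day]
        wide = sub.pivot_table(index=donor_col, columns=condition_col,
                               values=value_col, aggfunc="first")
        wide = wide.reindex(columns=[c for c in conditions if c in wide.columns])
        if wide.shape[1] >= 3:
            try:
                fr = friedman_test(wide.to_numpy())
                rows.append({"day": day, "comparison": "omnibus", "test": "friedman",
                             "statistic": fr.statistic, "pvalue": fr.pvalue,
                             "n": fr.n})
            except ValueError as exc:
                warnings.warn(f"friedman omnibus skipped for day {day}: {exc}")
        for cond in conditions:
            if cond == control_condition or cond not in wide.columns:
                continue
            pair = wide[[cond, control_condition]].dropna()
            if len(pair) < 5:
                continue
            res = wilcoxon_signed_rank(pair[cond], pair[control_condition])
            rows.append({"day": day, "comparison": f"{cond} vs {control_condition}",
                         "test": "wilcoxon", "statistic": res.statistic,
                         "pvalue": res.pvalue, "n": res.n})
    if len(days) == 2:
        d1, d2 = days
        for cond in conditions:
            a = cohort[(cohort[day_col] == d1) & (cohort[condition_col] == cond)]
            b = cohort[(cohort[day_col] == d2) & (cohort[condition_col] == cond)]
            merged = a.merge(b, on=donor_col, suffixes=("_a", "_b"))
            if len(merged) < 5:
                continue
            res = wilcoxon_signed_rank(merged[f"{value_col}_a"], merged[f"{value_col}_b"])
            rows.append({"day": f"{d1} vs {d2}", "comparison": cond,
                         "test": "wilcoxon", "statistic": res.statistic,
                         "pvalue": res.pvalue, "n": res.n})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no testable comparisons found in the cohort table")
    if holm:
        posthoc = table["test"] == "wilcoxon"
        table.loc[posthoc, "pvalue_adjusted"] = _holm(table.loc[posthoc, "pvalue"].to_numpy())
        table["significant"] = table.get("pvalue_adjusted", table["pvalue"]) < alpha
    else:
        table["significant"] = table["pvalue"] < alpha
    return table


def _holm(pvalues: np.ndarray) -> np.ndarray:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj


def exclude_extreme_outliers(values) -> np.ndarray:
    """Drop values beyond 3 x IQR from the quartiles (display rule only).

    Statistics always run on the full data; this filter exists solely to
    keep boxplot axes readable and mirrors the usual "extreme outlier"
    definition (Q1 - 3 IQR, Q3 + 3 IQR).
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return v
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return v[(v >= q1 - 3 * iqr) & (v <= q3 + 3 * iqr)]


def cohort_boxplot(
    cohort: pd.DataFrame,
    out_path,
    *,
    value_col: str = "value",
    condition_col: str = "condition",
    day_col: str = "day",
    title: str | None = None,
):
    """Boxplots per condition and day with plot-only extreme-outlier exclusion."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = sorted(cohort[day_col].unique())
    fig, axes = plt.subplots(1, len(days), figsize=(4 * len(days), 4), squeeze=False)
    for ax, day in zip(axes[0], days):
        sub = cohort[cohort[day_col] == day]
        conditions = list(dict.fromkeys(sub[condition_col]))
        data = [
            exclude_extreme_outliers(sub.loc[sub[condition_col] == c, value_col])
            for c in conditions
        ]
        ax.boxplot(data, tick_labels=conditions)
        ax.set_title(f"Day {day}")
        ax.tick_params(axis="x", rotation=75)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
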