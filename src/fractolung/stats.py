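"""Descriptive cohort summaries and paired pre/post comparisons.

The paired comparison of each biomarker uses the Wilcoxon signed-rank test:
zero differences are dropped (Wilcoxon's original convention), tied absolute
differences receive mid-ranks, the exact two-sided p-value is computed from
the full signed-rank distribution for small samples, and a normal
approximation with tie-corrected variance and continuity correction is used
for larger ones.  Raw p-values are reported per metric with no
multiple-testing correction, matching the descriptive presentation of a
three-biomarker panel.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from fractolung.errors import ConfigurationError

#: Default mapping metric name -> (pre column, post column) in a wide cohort
#: table.
DEFAULT_PREPOST_METRICS: dict[str, tuple[str, str]] = {
    "boxfd": ("boxfd_pre", "boxfd_post"),
    "lacunarity": ("lacunarity_pre", "lacunarity_post"),
    "mstfd": ("mstfd_pre", "mstfd_post"),
}


@dataclass
class PairedSample:
    """Matched per-patient pre/post values of one biomarker."""

    pre: np.ndarray
    post: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1:
            raise ConfigurationError("pre and post must be 1D vectors of equal length")
        if len(self.pre) < 1:
            raise ConfigurationError("need at least one pair")


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank result for one paired biomarker."""

    metric_name: str
    n_pairs: int
    n_nonzero: int
    statistic: float  # min(W+, W-)
    w_plus: float
    p_value: float
    method: str  # 'exact' | 'normal-approx' | 'degenerate'
    median_diff: float
    iqr_diff: tuple[float, float]

    def __post_init__(self) -> None:
        q1, q3 = self.iqr_diff
        assert q1 <= self.median_diff <= q3
        assert 0.0 <= self.p_value <= 1.0


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p-value of W+ over all 2^n sign assignments.

    Mid-ranks are multiples of 1/2, so doubling makes them integers and the
    distribution of 2*W+ is built by dynamic programming (the coefficient
    generating function prod_i (1 + x^(2 r_i)) / 2^n).
    """
    r2 = np.rint(2 * ranks).astype(int)
    dp = np.zeros(int(r2.sum()) + 1)
    dp[0] = 1.0
    for r in r2:
        dp[r:] = dp[r:] + dp[:-r]
    dp /= dp.sum()
    w2 = int(round(2 * w_plus))
    p_le = dp[: w2 + 1].sum()
    p_ge = dp[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    sample: PairedSample, exact_threshold: int = 25
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Exact enumeration of the signed-rank distribution when the number of
    non-zero differences is <= ``exact_threshold``; otherwise a normal
    approximation with tie-corrected variance and continuity correction.
    When every difference is zero the result is degenerate with p = 1.
    """
    diffs = sample.post - sample.pre
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    nonzero = diffs[diffs != 0]
    n = len(nonzero)
    if n == 0:
        return PairedTestResult(
            metric_name=sample.metric_name, n_pairs=len(diffs), n_nonzero=0,
            statistic=0.0, w_plus=0.0, p_value=1.0, method="degenerate",
            median_diff=float(med), iqr_diff=(float(q1), float(q3)),
        )
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= exact_threshold:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_counts**3 - tie_counts).sum())
        ) / 48.0
        dev = w_plus - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)  # continuity correction
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal-approx"
    return PairedTestResult(
        metric_name=sample.metric_name, n_pairs=len(diffs), n_nonzero=n,
        statistic=stat, w_plus=w_plus, p_value=p, method=method,
        median_diff=float(med), iqr_diff=(float(q1), float(q3)),
    )


# ---------------------------------------------------------------------------
# Percent rendering
# ---------------------------------------------------------------------------

def render_percent(count: int, total: int, mode: str = "half_up",
                   decimals: int = 1) -> float:
    """Percentage of ``count / total`` rendered to ``decimals`` places.

    Published tables are not always consistent about ties at the rounding
    digit, so three modes are offered: 'half_up' (default), 'half_down', and
    'truncate'.
    """
    if total <= 0:
        raise ConfigurationError("total must be positive")
    pct = decimal.Decimal(count) / decimal.Decimal(total) * 100
    q = decimal.Decimal(1).scaleb(-decimals)
    if mode == "half_up":
        out = pct.quantize(q, rounding=decimal.ROUND_HALF_UP)
    elif mode == "half_down":
        out = pct.quantize(q, rounding=decimal.ROUND_HALF_DOWN)
    elif mode == "truncate":
        out = pct.quantize(q, rounding=decimal.ROUND_DOWN)
    else:
        raise ConfigurationError(f"unknown rounding mode {mode!r}")
    return float(out)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(
    table: pd.DataFrame,
    group_col: str | None = None,
    categorical: tuple[str, ...] = ("sex", "smoking", "lung_disease"),
    continuous: tuple[str, ...] = ("age", "mld_cgy", "v5_pct", "v10_pct", "v20_pct"),
    rounding: str = "half_up",
) -> pd.DataFrame:
    """Baseline-characteristics summary: counts and percentages for
    categorical fields, median (range) for continuous fields, and grade >= 2
    / grade >= 3 pneumonitis event rates.

    Returns a tidy frame with columns group, characteristic, level, count,
    percent, median, range_low, range_high.
    """
    if table.empty:
        raise ConfigurationError("cohort table is empty")
    if "rp_grade" not in table.columns:
        raise ConfigurationError("cohort table lacks an 'rp_grade' column")
    groups = (
        [(g, sub) for g, sub in table.groupby(group_col)]
        if group_col else [("all", table)]
    )
    rows = []
    for gname, sub in groups:
        n = len(sub)
        rows.append({"group": gname, "characteristic": "n", "level": "",
                     "count": n, "percent": 100.0,
                     "median": np.nan, "range_low": np.nan, "range_high": np.nan})
        for col in continuous:
            if col not in sub.columns:
                continue
            vals = sub[col].dropna()
            rows.append({
                "group": gname, "characteristic": col, "level": "",
                "count": len(vals), "percent": np.nan,
                "median": float(vals.median()),
                "range_low": float(vals.min()), "range_high": float(vals.max()),
            })
        for col in categorical:
            if col not in sub.columns:
                continue
            for level, cnt in sub[col].value_counts().sort_index().items():
                rows.append({
                    "group": gname, "characteristic": col, "level": str(level),
                    "count": int(cnt),
                    "percent": render_percent(int(cnt), n, rounding),
                    "median": np.nan, "range_low": np.nan, "range_high": np.nan,
                })
        for grade_cut in (2, 3):
            events = int((sub["rp_grade"] >= grade_cut).sum())
            rows.append({
                "group": gname, "characteristic": f"rp_grade>={grade_cut}",
                "level": "", "count": events,
                "percent": render_percent(events, n, rounding),
                "median": np.nan, "range_low": np.nan, "range_high": np.nan,
            })
    return pd.DataFrame(rows)


def compare_pre_post(
    table: pd.DataFrame,
    metrics: dict[str, tuple[str, str]] | None = None,
    group_col: str | None = None,
    exact_threshold: int = 25,
) -> pd.DataFrame:
    """Paired pre/post comparison per biomarker (and per group if given).

    For each metric: pre median (IQR), post median (IQR), difference
    median (IQR) and the Wilcoxon signed-rank p-value.  IQRs use linearly
    interpolated 25th/75th percentiles.  Rows with a missing pre or post
    value are unpaired and rejected, listing the offending patients.
    """
    metrics = metrics or DEFAULT_PREPOST_METRICS
    groups = (
        [(g, sub) for g, sub in table.groupby(group_col)]
        if group_col else [("all", table)]
    )
    rows = []
    for gname, sub in groups:
        for metric, (pre_col, post_col) in metrics.items():
            if pre_col not in sub.columns or post_col not in sub.columns:
                raise ConfigurationError(
                    f"columns {pre_col!r}/{post_col!r} missing for metric {metric!r}"
                )
            missing = sub[sub[pre_col].isna() | sub[post_col].isna()]
            if not missing.empty:
                ids = (missing["patient_id"].tolist()
                       if "patient_id" in missing.columns
                       else missing.index.tolist())
                raise ConfigurationError(
                    f"unpaired patients for metric {metric!r}: {ids}"
                )
            pre = sub[pre_col].to_numpy(float)
            post = sub[post_col].to_numpy(float)
            res = wilcoxon_signed_rank(
                PairedSample(pre, post, metric), exact_threshold=exact_threshold
            )
            pre_q = np.percentile(pre, [25, 50, 75])
            post_q = np.percentile(post, [25, 50, 75])
            rows.append({
                "group": gname, "metric": metric, "n": len(pre),
                "pre_median": pre_q[1], "pre_q1": pre_q[0], "pre_q3": pre_q[2],
                "post_median": post_q[1], "post_q1": post_q[0], "post_q3": post_q[2],
                "diff_median": res.median_diff,
                "diff_q1": res.iqr_diff[0], "diff_q3": res.iqr_diff[1],
                "statistic": res.statistic, "p_value": res.p_value,
                "method": res.method,
            })
    return pd.DataFrame(rows)


def render_prepost_text(report: pd.DataFrame) -> str:
    """Human-readable rendering of a pre/post comparison report."""
    lines = []
    for g, sub in report.groupby("group"):
        lines.append(f"Group: {g}")
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['metric']:<12} pre {r['pre_median']:.3f} "
                f"({r['pre_q1']:.3f}-{r['pre_q3']:.3f})  "
                f"post {r['post_median']:.3f} "
                f"({r['post_q1']:.3f}-{r['post_q3']:.3f})  "
                f"diff {r['diff_median']:+.3f} "
                f"({r['diff_q1']:+.3f}-{r['diff_q3']:+.3f})  "
                f"p={r['p_value']:.3g} [{r['method']}]"
            )
    return "\n".join(lines)
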