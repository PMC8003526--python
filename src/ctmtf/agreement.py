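"""Agreement between true tumor fractions and estimated tumor genome fractions.

Lin's concordance correlation coefficient (CCC) measures agreement of paired
measurements around the identity line,

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2),

with population (1/n) moments.  The Bland-Altman analysis summarises the
paired differences d = estimate - truth by their mean and limits of
agreement mean(d) +/- k sd(d) (sample sd; k = 2 by default, 1.96 selectable)
plus a least-squares trend fit of the differences on the pair means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float
    k_sd: float


@dataclass
class AgreementReport:
    """CCC and Bland-Altman agreement, overall and per group."""

    ccc_overall: float
    ccc_by_group: dict[str, float]
    ba: BlandAltman
    trend_by_group: dict[str, tuple[float, float]]  # group -> (slope, intercept)
    n: int


def concordance_correlation(truth, estimate) -> float:
    """Lin's CCC with population (1/n) moments."""
    x = np.asarray(truth, dtype=float)
    y = np.asarray(estimate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("truth and estimate must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    vx = x.var()
    vy = y.var()
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both vectors constant and equal")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


def bland_altman(truth, estimate, k_sd: float = 2.0) -> BlandAltman:
    """Mean difference, limits of agreement, and difference-vs-mean trend."""
    x = np.asarray(truth, dtype=float)
    y = np.asarray(estimate, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two 1-D vectors of equal length >= 2")
    d = y - x
    m = (x + y) / 2.0
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(m) > 0:
        slope, intercept = np.polyfit(m, d, 1)
    else:
        slope, intercept = 0.0, mean_diff
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=mean_diff - k_sd * sd,
        loa_high=mean_diff + k_sd * sd,
        trend_slope=float(slope),
        trend_intercept=float(intercept),
        k_sd=float(k_sd),
    )


def agreement_report(
    df: pd.DataFrame,
    truth_col: str = "true_tf",
    estimate_col: str = "tgf",
    group_col: str | None = None,
    k_sd: float = 2.0,
) -> AgreementReport:
    """Overall and per-group agreement for a paired measurement table."""
    x = df[truth_col].to_numpy(float)
    y = df[estimate_col].to_numpy(float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired measurements")
    ccc_groups: dict[str, float] = {}
    trend_groups: dict[str, tuple[float, float]] = {}
    if group_col is not None:
        for g, sub in df.groupby(group_col, sort=True):
            gx = sub[truth_col].to_numpy(float)
            gy = sub[estimate_col].to_numpy(float)
            ccc_groups[str(g)] = concordance_correlation(gx, gy)
            ba_g = bland_altman(gx, gy, k_sd)
            trend_groups[str(g)] = (ba_g.trend_slope, ba_g.trend_intercept)
    return AgreementReport(
        ccc_overall=concordance_correlation(x, y),
        ccc_by_group=ccc_groups,
        ba=bland_altman(x, y, k_sd),
        trend_by_group=trend_groups,
        n=int(x.size),
    )


def compare_estimates(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame | None,
    truth: pd.DataFrame,
    estimate_col: str = "tgf",
    truth_col: str = "true_tf",
    group_col: str | None = None,
    k_sd: float = 2.0,
) -> tuple[AgreementReport, AgreementReport | None, str | None]:
    """Score one or two per-sample estimate tables against known truth.

    Tables are keyed by ``sample_id``; the second table may come from an
    external tool's output.  Returns the two reports and, when both tables
    are present, which one wins on overall CCC ("a" or "b").
    """

    def merged(tbl: pd.DataFrame, name: str) -> pd.DataFrame:
        missing = set(truth["sample_id"]) - set(tbl["sample_id"])
        if missing:
            raise KeyError(
                f"table {name} lacks samples: {', '.join(sorted(missing))}"
            )
        cols = ["sample_id", estimate_col]
        m = truth.merge(tbl[cols], on="sample_id", how="left", suffixes=("", "_est"))
        est = estimate_col if estimate_col + "_est" not in m.columns else estimate_col + "_est"
        m = m.rename(columns={est: "_estimate"})
        return m

    ma = merged(table_a, "a")
    report_a = agreement_report(ma, truth_col, "_estimate", group_col, k_sd)
    if table_b is None:
        return report_a, None, None
    mb = merged(table_b, "b")
    report_b = agreement_report(mb, truth_col, "_estimate", group_col, k_sd)
    winner = "a" if report_a.ccc_overall >= report_b.ccc_overall else "b"
    return report_a, report_b, winner
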