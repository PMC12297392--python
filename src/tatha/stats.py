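"""Cross-validation summary statistics and hypothesis tests.

Per-fold metrics are condensed to mean and sample standard deviation
(n-1 denominator), compared against a peer-baseline mean with a two-sided
one-sample t-test, and checked for normality with the Shapiro-Wilk test
(Royston's AS R94 algorithm, via scipy).  Verdicts use the conventional
0.05 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class StatReport:
    """Mean/SD plus t-test and Shapiro-Wilk results for one metric column."""

    metric: str
    mean: float
    sd: float
    t_stat: float
    p_value: float
    verdict: str
    shapiro_w: float
    shapiro_p: float
    mu0: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1) of a metric column."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(v.mean()), float(v.std(ddof=1))


def one_sample_t_test(values, mu0: float) -> tuple[float, float, str]:
    """Two-sided one-sample t-test of the column mean against ``mu0``.

    Returns (t, p, verdict) where the verdict is "Significant" iff
    p < 0.05.  A zero-variance column has no defined t statistic.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise ValueError("t-test undefined for zero-variance values")
    res = sps.ttest_1samp(v, popmean=mu0)
    verdict = "Significant" if res.pvalue < SIGNIFICANCE_LEVEL else "Not significant"
    return float(res.statistic), float(res.pvalue), verdict


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) via Royston's AS R94."""
    v = np.asarray(values, dtype=np.float64)
    if not (3 <= v.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("W undefined for constant input")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def analyze_folds(folds_df, mu0: float,
                  metrics: tuple = ("accuracy", "dice", "auc")) -> list[StatReport]:
    """Full per-metric statistical panel over a fold-results table."""
    out = []
    for m in metrics:
        col = folds_df[m].to_numpy()
        mean, sd = summarize(col)
        t, p, verdict = one_sample_t_test(col, mu0)
        w, wp = shapiro_wilk(col)
        out.append(StatReport(metric=m, mean=mean, sd=sd, t_stat=t,
                              p_value=p, verdict=verdict,
                              shapiro_w=w, shapiro_p=wp, mu0=mu0))
    return out
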