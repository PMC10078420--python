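"""Evaluation statistics for quantitative-map validation.

Accuracy/precision summaries, Bland-Altman agreement with 95% limits, a
single-outlier Grubbs test, Levene's homogeneity-of-variance test, a nested-F
homogeneity-of-regression (ANCOVA) test for merging two calibration runs, and
Pearson's r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "accuracy_precision",
    "bland_altman",
    "grubbs_test",
    "levene_test",
    "homogeneity_of_regression",
    "pearson_r2",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary: bias, spread and 95% limits of agreement."""

    bias: float
    sd: float
    lower: float   # bias - 1.96 sd
    upper: float   # bias + 1.96 sd
    p_zero_bias: float
    relative: bool

    def __post_init__(self):
        assert abs(self.lower - (self.bias - 1.96 * self.sd)) < 1e-9
        assert abs(self.upper - (self.bias + 1.96 * self.sd)) < 1e-9


def accuracy_precision(estimates, estimate_sds, reference):
    """Mean accuracy and precision across samples, in percent.

    ``accuracy = mean(estimate / reference) * 100`` and
    ``precision = mean(sd / estimate) * 100``.  Returns
    ``(accuracy, accuracy_sd, precision, precision_sd)`` where the sd terms
    are the across-sample spreads of the per-sample ratios.
    """
    est = np.asarray(estimates, dtype=float)
    sds = np.asarray(estimate_sds, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if not (len(est) == len(sds) == len(ref)):
        raise ValueError("inputs must have equal lengths")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    acc = est / ref * 100.0
    prec = sds / est * 100.0
    return (
        float(acc.mean()),
        float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        float(prec.mean()),
        float(prec.std(ddof=1)) if len(prec) > 1 else 0.0,
    )


def bland_altman(a, b, relative: bool = False) -> AgreementReport:
    """Agreement between paired measurements ``a`` (method) and ``b`` (truth).

    Differences are ``a - b``, expressed in percent of ``b`` when
    ``relative``; the report carries the mean difference (bias), its s.d.,
    the 95% limits of agreement and a one-sample t-test p-value against zero
    bias.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must have matching lengths")
    if a.size < 2:
        raise ValueError("at least 2 pairs are required")
    d = (a - b) / b * 100.0 if relative else a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd > 0:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p = 1.0 if bias == 0 else 0.0
    return AgreementReport(
        bias=bias, sd=sd, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd,
        p_zero_bias=p, relative=relative,
    )


def grubbs_test(values, significance: float = 0.05):
    """Two-sided single-outlier Grubbs test.

    Returns the index of the detected outlier, or ``None``.  The statistic
    ``G = max|x - mean| / s`` is compared with the critical value
    ``((n-1)/sqrt(n)) sqrt(t² / (n - 2 + t²))`` at ``t = t_{alpha/(2n), n-2}``.
    Applied at most once (single-outlier form).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    if not 0 < significance < 1:
        raise ValueError("significance must lie in (0, 1)")
    s = x.std(ddof=1)
    if s == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = dev[idx] / s
    n = len(x)
    t = stats.t.ppf(1 - significance / (2 * n), n - 2)
    G_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    return idx if G > G_crit else None


def levene_test(groups, center: str = "mean"):
    """Levene's test for homogeneity of variances across groups.

    ``center='mean'`` is the classical form; ``center='median'`` the
    Brown-Forsythe variant.  Returns ``(statistic, p)``.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 observations")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]) and all(a.std() == 0 for a in arrays):
        return 0.0, 1.0
    res = stats.levene(*arrays, center=center)
    return float(res.statistic), float(res.pvalue)


def homogeneity_of_regression(x1, y1, x2, y2):
    """Nested-F test: one pooled line versus separate lines per dataset.

    Used to decide whether two calibration runs (e.g. heating and cooling)
    share a common linear relation and may be merged; merging is conventional
    only when ``p >= 0.05``.  Returns ``(F, p)`` for the 2-parameter
    restriction (equal slope and intercept).
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    if len(x1) < 3 or len(x2) < 3:
        raise ValueError("each dataset needs at least 3 points")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("degenerate (constant-x) dataset")

    def rss(x, y):
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_sep = rss(x1, y1) + rss(x2, y2)
    xp, yp = np.concatenate([x1, x2]), np.concatenate([y1, y2])
    rss_pool = rss(xp, yp)
    n = len(xp)
    df_num, df_den = 2, n - 4
    if df_den <= 0:
        raise ValueError("not enough points for the nested comparison")
    eps = 1e-12 * max(float(yp @ yp), 1.0)
    if rss_sep <= eps:
        return (0.0, 1.0) if rss_pool <= eps else (float("inf"), 0.0)
    F = (rss_pool - rss_sep) / df_num / (rss_sep / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), p


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(stats.pearsonr(x, y).statistic ** 2)


def bland_altman_plot(a, b, relative: bool = False, ax=None, label=None):
    """Draw a Bland-Altman plot; returns ``(report, ax)``."""
    import matplotlib.pyplot as plt

    report = bland_altman(a, b, relative=relative)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mean = (a + b) / 2.0
    diff = (a - b) / b * 100.0 if relative else a - b
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=18, label=label)
    for v, style in ((report.bias, "-"), (report.lower, "--"), (report.upper, "--")):
        ax.axhline(v, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference" + (" (%)" if relative else ""))
    return report, ax
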