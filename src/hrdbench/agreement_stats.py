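"""Score-level agreement statistics for method comparison.

Bland-Altman limits of agreement, coefficient of variation, Spearman rank
correlation, and percent-agreement (PPA/NPA/OPA) threshold sweeps — the
standard battery for comparing a candidate HRD assay's scores against a
reference series.

Differences are oriented as (test - reference) throughout, so a positive
bias means the test method overcalls.  Undefined quantities (empty class,
zero variance) are reported as ``None`` rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, its dispersion, and the 95% limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    bias_ci95: tuple[float, float]
    loa_low_ci95: tuple[float, float]
    loa_high_ci95: tuple[float, float]
    t_p: float | None
    n: int
    orientation: str = "test - reference"


@dataclass(frozen=True)
class AgreementTable:
    """2x2 classification agreement at one score threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppa(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def npa(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def opa(self) -> float | None:
        return (self.tp + self.tn) / self.n if self.n else None


def bland_altman(
    test: Sequence[float], reference: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman agreement between paired score series.

    bias = mean(test - reference); LoAs = bias +/- 1.96 * sample SD.  The
    95% CI of the bias uses the t distribution with n-1 df; the LoA CIs use
    the standard error sd*sqrt(1/n + 1.96^2 / (2(n-1))).  ``t_p`` is the
    one-sample t-test p-value of the differences against zero (None when
    the differences have zero variance).
    """
    x = np.asarray(test, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("Bland-Altman requires at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    tq = stats.t.ppf(0.975, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1 / n + 1.96**2 / (2 * (n - 1)))
    if sd == 0:
        t_p = None
    else:
        t_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci95=(bias - tq * se_bias, bias + tq * se_bias),
        loa_low_ci95=(loa_low - tq * se_loa, loa_low + tq * se_loa),
        loa_high_ci95=(loa_high - tq * se_loa, loa_high + tq * se_loa),
        t_p=t_p,
        n=n,
    )


def cv(values: Sequence[float]) -> float | None:
    """Coefficient of variation in percent: sample SD / mean * 100.

    Undefined (None) when the mean is zero; requires at least two values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv requires at least two values")
    mean = x.mean()
    if mean == 0:
        return None
    return float(x.std(ddof=1) / mean * 100)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (average ranks for ties); None if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired series must have equal length")
    if x.size < 3:
        raise ValueError("rank correlation requires at least three pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def percent_agreement(
    ref_scores: Sequence[float],
    test_scores: Sequence[float],
    threshold: float,
    positive_rule: str = "ge",
) -> AgreementTable:
    """Tabulate HRD-positive/negative agreement at one score threshold.

    Both series are classified with the same rule (default: positive when
    score >= threshold); the reference classification defines the truth for
    TP/FP/TN/FN.
    """
    ref = np.asarray(ref_scores, dtype=float)
    test = np.asarray(test_scores, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("paired series must have equal length")
    if positive_rule == "ge":
        rp, tp_ = ref >= threshold, test >= threshold
    elif positive_rule == "gt":
        rp, tp_ = ref > threshold, test > threshold
    else:
        raise ValueError("positive_rule must be 'ge' or 'gt'")
    return AgreementTable(
        threshold=threshold,
        tp=int(np.sum(rp & tp_)),
        fp=int(np.sum(~rp & tp_)),
        tn=int(np.sum(~rp & ~tp_)),
        fn=int(np.sum(rp & ~tp_)),
    )


def sweep(
    ref_scores: Sequence[float],
    test_scores: Sequence[float],
    thresholds: Sequence[float],
    positive_rule: str = "ge",
) -> list[AgreementTable]:
    """Percent agreement across a grid of score thresholds."""
    return [
        percent_agreement(ref_scores, test_scores, t, positive_rule) for t in thresholds
    ]
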