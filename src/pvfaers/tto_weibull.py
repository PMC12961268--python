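"""Time-to-onset analysis: medians, Weibull shape-parameter test, histograms.

Time to onset (TTO) is the number of days from the first administration of a
target drug to the adverse event.  Onset profiles are summarised by the
sample median with interquartile range and by a two-parameter Weibull
maximum-likelihood fit: the shape parameter beta and its 95% CI classify the
hazard over time as *early failure* (decreasing hazard, CI entirely below 1),
*wear-out* (increasing hazard, CI entirely above 1) or *random* (CI contains
1, approximately constant hazard).

The MLE is computed by profiling the likelihood over the shape: given beta,
the scale alpha has the closed form (mean(x^beta))^(1/beta), and the profile
score equation in beta is solved by bracketing + Brent root finding.
Confidence intervals are Wald intervals on the log-parameters from the
observed information matrix, exponentiated back so the bounds stay positive.
Censoring is out of scope: only reports with complete start and event dates
contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import optimize, stats

from .faers_io import Report, full_date

__all__ = [
    "TTOSample",
    "TTOExclusion",
    "WeibullFit",
    "OnsetHistogram",
    "DegenerateSampleError",
    "extract_tto",
    "median_iqr",
    "fit_weibull",
    "classify_failure_type",
    "onset_histogram",
    "compare_tto",
    "HISTOGRAM_BINS",
]


class DegenerateSampleError(ValueError):
    """Sample unusable for a Weibull fit (all values identical, or too few)."""


@dataclass(frozen=True)
class TTOSample:
    report_id: str
    tto_days: int
    exposure: str = ""
    term_set: str = ""

    def __post_init__(self) -> None:
        if self.tto_days < 1:
            raise ValueError("tto_days must be >= 1")


@dataclass(frozen=True)
class TTOExclusion:
    report_id: str
    reason: str


@dataclass
class WeibullFit:
    """Two-parameter Weibull MLE with Wald CIs and failure-type class."""

    n: int
    scale_alpha: float
    scale_ci: tuple[float, float]
    shape_beta: float
    shape_ci: tuple[float, float]
    median_days: float
    iqr: tuple[float, float]
    failure_type: str
    converged: bool = True


@dataclass
class OnsetHistogram:
    """Counts and percentages in onset bins 1-30 / 31-90 / 91-180 / >180 days."""

    labels: tuple
    counts: tuple
    percentages: tuple
    n: int


# ---------------------------------------------------------------------------
# TTO extraction
# ---------------------------------------------------------------------------

def extract_tto(report: Report,
                target_classes: Sequence[str] = ("glp1ra",),
                exposure: str = "",
                term_set: str = "") -> Union[TTOSample, TTOExclusion]:
    """TTO = event date minus the earliest complete therapy start date among
    drugs of the target classes.

    Exclusions (partial/missing dates, non-positive interval) are returned as
    data, not raised.
    """
    event = full_date(report.event_date)
    if event is None:
        return TTOExclusion(report.report_id, "partial date")
    starts = [full_date(d.therapy_start_date) for d in report.drugs
              if d.class_tag in target_classes]
    starts = [s for s in starts if s is not None]
    if not starts:
        return TTOExclusion(report.report_id, "partial date")
    tto = (event - min(starts)).days
    if tto <= 0:
        return TTOExclusion(report.report_id, "non-positive TTO")
    return TTOSample(report.report_id, tto, exposure=exposure, term_set=term_set)


# ---------------------------------------------------------------------------
# Median / IQR
# ---------------------------------------------------------------------------

def median_iqr(samples: Sequence[float]) -> tuple[float, float, float]:
    """Median with 25th and 75th percentiles by linear interpolation."""
    values = np.asarray([s.tto_days if isinstance(s, TTOSample) else s
                         for s in samples], dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr requires at least one sample")
    med, q25, q75 = np.percentile(values, [50, 25, 75])
    return float(med), float(q25), float(q75)


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------

def _shape_score(beta: float, x: np.ndarray, logx: np.ndarray) -> float:
    # profile score equation for the shape: 1/beta + mean(log x)
    #   - sum(x^beta log x)/sum(x^beta) = 0
    xb = np.exp(beta * logx)
    return 1.0 / beta + logx.mean() - float((xb * logx).sum() / xb.sum())


def _loglik(log_alpha: float, log_beta: float, x: np.ndarray, logx: np.ndarray) -> float:
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = (x / alpha) ** beta
    return float(x.size * (math.log(beta) - beta * math.log(alpha))
                 + (beta - 1) * logx.sum() - z.sum())


def fit_weibull(samples: Sequence[float]) -> WeibullFit:
    """Two-parameter Weibull MLE (no censoring) with Wald CIs on log-parameters.

    Requires n >= 3 and at least two distinct values.  Raises
    :class:`DegenerateSampleError` otherwise and ``RuntimeError`` on
    non-convergence.
    """
    x = np.asarray([s.tto_days if isinstance(s, TTOSample) else s
                    for s in samples], dtype=float)
    if x.size < 3:
        raise DegenerateSampleError(f"need >= 3 observations, got {x.size}")
    if (x <= 0).any():
        raise ValueError("TTO values must be positive")
    if np.unique(x).size < 2:
        raise DegenerateSampleError("all values identical; shape not identifiable")
    logx = np.log(x)

    # bracket the root of the profile score; the score is decreasing in beta
    lo, hi = 1e-3, 1.0
    while _shape_score(hi, x, logx) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("Weibull MLE failed to bracket the shape root "
                               f"(score at beta={hi/2:.1f} still positive)")
    beta = float(optimize.brentq(_shape_score, lo, hi, args=(x, logx), xtol=1e-12))
    alpha = float(np.exp(beta * logx).mean() ** (1.0 / beta))

    # observed information on (log alpha, log beta) by central differences
    la, lb = math.log(alpha), math.log(beta)
    h = 1e-5

    def ll(p):
        return _loglik(p[0], p[1], x, logx)

    hess = np.empty((2, 2))
    p0 = np.array([la, lb])
    for i in range(2):
        for j in range(2):
            pp = p0.copy(); pp[i] += h; pp[j] += h
            pm = p0.copy(); pm[i] += h; pm[j] -= h
            mp = p0.copy(); mp[i] -= h; mp[j] += h
            mm = p0.copy(); mm[i] -= h; mm[j] -= h
            hess[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * h * h)
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular information matrix: {exc}") from exc
    if (np.diag(cov) <= 0).any():
        raise RuntimeError("information matrix not positive definite at the MLE")
    se_la, se_lb = np.sqrt(np.diag(cov))
    scale_ci = (math.exp(la - 1.96 * se_la), math.exp(la + 1.96 * se_la))
    shape_ci = (math.exp(lb - 1.96 * se_lb), math.exp(lb + 1.96 * se_lb))

    med, q25, q75 = median_iqr(x)
    return WeibullFit(
        n=int(x.size),
        scale_alpha=alpha, scale_ci=scale_ci,
        shape_beta=beta, shape_ci=shape_ci,
        median_days=med, iqr=(q25, q75),
        failure_type=classify_failure_type(beta, shape_ci[0], shape_ci[1]),
    )


def classify_failure_type(shape_beta: float, ci_low: float, ci_high: float) -> str:
    """Hazard classification from the shape parameter and its 95% CI.

    ``early`` when the CI lies entirely below 1 (decreasing hazard),
    ``wear_out`` when entirely above 1 (increasing hazard), ``random``
    otherwise (CI contains 1).
    """
    if not (0 < ci_low <= shape_beta <= ci_high):
        raise ValueError(
            f"invalid CI: need 0 < {ci_low} <= {shape_beta} <= {ci_high}")
    if ci_high < 1:
        return "early"
    if ci_low > 1:
        return "wear_out"
    return "random"


# ---------------------------------------------------------------------------
# Onset histogram
# ---------------------------------------------------------------------------

#: (label, low, high) with inclusive bounds; the last bin is open-ended.
HISTOGRAM_BINS = (
    ("1-30", 1, 30),
    ("31-90", 31, 90),
    ("91-180", 91, 180),
    (">180", 181, None),
)


def onset_histogram(samples: Sequence[float]) -> OnsetHistogram:
    """Bin TTO values into 1-30 / 31-90 / 91-180 / >180 days."""
    values = np.asarray([s.tto_days if isinstance(s, TTOSample) else s
                         for s in samples], dtype=float)
    if values.size == 0:
        raise ValueError("onset_histogram requires at least one sample")
    counts = []
    for _, low, high in HISTOGRAM_BINS:
        mask = values >= low if high is None else (values >= low) & (values <= high)
        counts.append(int(mask.sum()))
    n = int(values.size)
    return OnsetHistogram(
        labels=tuple(label for label, _, _ in HISTOGRAM_BINS),
        counts=tuple(counts),
        percentages=tuple(round(100.0 * c / n, 2) for c in counts),
        n=n,
    )


def compare_tto(samples_a: Sequence[float], samples_b: Sequence[float]) -> float:
    """Two-sided rank-sum (Mann-Whitney U) p-value comparing two TTO samples."""
    to_arr = lambda s: np.asarray(
        [v.tto_days if isinstance(v, TTOSample) else v for v in s], dtype=float)
    return float(stats.mannwhitneyu(to_arr(samples_a), to_arr(samples_b),
                                    alternative="two-sided").pvalue)
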