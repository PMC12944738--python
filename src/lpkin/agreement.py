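"""Method-comparison statistics for paired two-method measurements.

Implements the agreement battery used to compare a vision-based
measurement against a reference device on the same trials: Pearson
correlation with interpretation bands, Bland–Altman bias and 95% limits of
agreement with confidence intervals, a paired t-test, the paired Cohen's d
effect size (mean of differences over their SD), and Deming
errors-in-variables regression with an assumed error-variance ratio
(lambda = 1 by default) and jackknife confidence intervals.

Fixed bias is flagged when the Deming intercept CI excludes zero;
proportional bias when the slope CI excludes one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "pearson_with_band",
    "bland_altman",
    "paired_t",
    "cohens_d",
    "cohens_d_from_loa",
    "deming",
    "agreement_report",
    "correlation_band",
    "effect_size_band",
]

Z_95 = 1.96  # conventional normal quantile defining the limits of agreement


@dataclass(frozen=True)
class PairedMeasurements:
    """Equal-length paired values from two methods, in the same unit."""

    method_a: np.ndarray
    method_b: np.ndarray
    indicator: str = ""
    load_group: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=float)
        b = np.asarray(self.method_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError("method_a and method_b must be equal-length 1-D")
        if a.size < 3:
            raise InsufficientDataError(
                f"need at least 3 pairs, got {a.size}"
            )
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValidationError("missing or non-finite pairs are not allowed")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)

    @property
    def n(self) -> int:
        return int(self.method_a.size)

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b


@dataclass
class AgreementReport:
    """All agreement statistics for one indicator x load group."""

    indicator: str
    load_group: str
    n: int
    pearson_r: float
    pearson_band: str
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    t_stat: float
    p_value: float
    cohens_d: float
    cohens_d_band: str
    deming_slope: float
    deming_intercept: float
    deming_slope_ci: tuple[float, float]
    deming_intercept_ci: tuple[float, float]
    lambda_ratio: float
    fixed_bias: bool
    proportional_bias: bool

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, tuple):
                out[key] = [float(v) for v in value]
            elif isinstance(value, (np.floating, np.integer)):
                out[key] = float(value)
            else:
                out[key] = value
        return out


def correlation_band(r: float) -> str:
    """Interpretation band for |r|: very strong >= 0.9 down to very weak < 0.3."""
    m = abs(r)
    if m >= 0.9:
        return "very strong"
    if m >= 0.7:
        return "strong"
    if m >= 0.5:
        return "moderate"
    if m >= 0.3:
        return "weak"
    return "very weak"


def effect_size_band(d: float) -> str:
    """Interpretation band for |d|; |d| >= 0.8 is treated as large."""
    m = abs(d)
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def pearson_with_band(pairs: PairedMeasurements) -> tuple[float, str]:
    """Sample Pearson correlation and its interpretation band (on |r|)."""
    r = float(stats.pearsonr(pairs.method_a, pairs.method_b).statistic)
    return r, correlation_band(r)


def bland_altman(
    pairs: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float], dict]:
    """Bland–Altman bias, SD of differences, limits of agreement, and CIs.

    Differences are method_a - method_b.  LoA = bias +/- 1.96 * SD (sample
    SD, n-1).  The bias CI uses the t distribution; each LoA CI uses the
    standard approximate standard error
    ``SD * sqrt(1/n + 1.96^2 / (2 (n - 1)))`` with the same t quantile.
    """
    d = pairs.differences
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - Z_95 * sd, bias + Z_95 * sd)
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + Z_95**2 / (2.0 * (n - 1)))
    cis = {
        "bias": (bias - tq * se_bias, bias + tq * se_bias),
        "loa_lower": (loa[0] - tq * se_loa, loa[0] + tq * se_loa),
        "loa_upper": (loa[1] - tq * se_loa, loa[1] + tq * se_loa),
    }
    return bias, sd, loa, cis


def paired_t(pairs: PairedMeasurements) -> tuple[float, float]:
    """Two-sided paired t-test on the differences (n - 1 df).

    Identical methods (all differences zero) give t = 0, p = 1 by the
    static-limit convention rather than the 0/0 indeterminate form.
    """
    d = pairs.differences
    if d.std(ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(pairs.method_a, pairs.method_b)
    return float(res.statistic), float(res.pvalue)


def cohens_d(pairs: PairedMeasurements) -> tuple[float, str]:
    """Paired Cohen's d: mean of differences over their sample SD.

    Zero-variance differences (e.g. an exact constant offset) admit no
    finite standardised effect and raise :class:`DegenerateDataError`.
    """
    d = pairs.differences
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("zero-variance differences: d is undefined")
    value = float(d.mean() / sd)
    return value, effect_size_band(value)


def cohens_d_from_loa(bias: float, loa_lower: float, loa_upper: float) -> float:
    """Paired Cohen's d recovered from Bland–Altman summary values.

    The SD of differences follows from the width of the limits of
    agreement, ``sd = (loa_upper - loa_lower) / (2 * 1.96)``; the effect
    size is then evaluated through :func:`cohens_d` on a minimal
    three-pair set whose differences have exactly that mean and SD, so the
    module's own convention (not a shortcut formula) produces the value.
    """
    sd = (loa_upper - loa_lower) / (2.0 * Z_95)
    if sd <= 0.0:
        raise DegenerateDataError("limits of agreement have zero width")
    diffs = np.array([bias - sd, bias, bias + sd])
    d, _ = cohens_d(PairedMeasurements(diffs, np.zeros(3)))
    return d


def _deming_point(
    x: np.ndarray, y: np.ndarray, lambda_ratio: float
) -> tuple[float, float]:
    """Closed-form Deming estimate of y on x with error-variance ratio lambda."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2)) / (x.size - 1)
    syy = float(np.sum((y - ym) ** 2)) / (x.size - 1)
    sxy = float(np.sum((x - xm) * (y - ym))) / (x.size - 1)
    if sxy == 0.0:
        raise DegenerateDataError("zero covariance: Deming slope is undefined")
    slope = (syy - lambda_ratio * sxx
             + np.sqrt((syy - lambda_ratio * sxx) ** 2
                       + 4.0 * lambda_ratio * sxy**2)) / (2.0 * sxy)
    intercept = ym - slope * xm
    return float(slope), float(intercept)


def deming(
    pairs: PairedMeasurements,
    lambda_ratio: float = 1.0,
    alpha: float = 0.05,
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Deming regression of method_a on method_b with jackknife CIs.

    With lambda = 1 (equal error variance in both methods) this is
    orthogonal regression.  Confidence intervals come from leave-one-out
    jackknife standard errors with a t quantile on n - 2 degrees of
    freedom; the procedure is deterministic given the data.
    """
    x = pairs.method_b
    y = pairs.method_a
    n = pairs.n
    slope, intercept = _deming_point(x, y, lambda_ratio)

    mask = np.ones(n, dtype=bool)
    loo = np.empty((n, 2))
    for i in range(n):
        mask[i] = False
        loo[i] = _deming_point(x[mask], y[mask], lambda_ratio)
        mask[i] = True
    var = (n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0)
    se_slope, se_intercept = np.sqrt(var)
    tq = stats.t.ppf(1 - alpha / 2, n - 2)
    slope_ci = (slope - tq * se_slope, slope + tq * se_slope)
    intercept_ci = (intercept - tq * se_intercept, intercept + tq * se_intercept)
    return slope, intercept, slope_ci, intercept_ci


def agreement_report(
    pairs: PairedMeasurements,
    lambda_ratio: float = 1.0,
    alpha: float = 0.05,
) -> AgreementReport:
    """Run the full agreement battery on one paired set."""
    r, r_band = pearson_with_band(pairs)
    bias, sd, loa, cis = bland_altman(pairs, alpha)
    t_stat, p_value = paired_t(pairs)
    if sd == 0.0 and bias == 0.0:
        # identical methods: no difference at all, effect size is zero
        d, d_band = 0.0, effect_size_band(0.0)
    else:
        d, d_band = cohens_d(pairs)
    slope, intercept, slope_ci, intercept_ci = deming(pairs, lambda_ratio, alpha)
    return AgreementReport(
        indicator=pairs.indicator,
        load_group=pairs.load_group,
        n=pairs.n,
        pearson_r=r,
        pearson_band=r_band,
        bias=bias,
        bias_ci=cis["bias"],
        sd_diff=sd,
        loa_lower=loa[0],
        loa_upper=loa[1],
        loa_lower_ci=cis["loa_lower"],
        loa_upper_ci=cis["loa_upper"],
        t_stat=t_stat,
        p_value=p_value,
        cohens_d=d,
        cohens_d_band=d_band,
        deming_slope=slope,
        deming_intercept=intercept,
        deming_slope_ci=slope_ci,
        deming_intercept_ci=intercept_ci,
        lambda_ratio=lambda_ratio,
        fixed_bias=not (intercept_ci[0] <= 0.0 <= intercept_ci[1]),
        proportional_bias=not (slope_ci[0] <= 1.0 <= slope_ci[1]),
    )
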