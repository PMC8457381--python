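"""Method-comparison statistics for validating the pressure-gradient model.

Implements the validation protocol used to compare a candidate gradient
estimate against the invasive catheter reference: Bland-Altman agreement
(bias, SD of differences, limits of agreement at +/- 1.96 SD), one-way
random-effects intraclass correlation ICC(1) per McGraw & Wong, normality-
gated paired and two-group comparisons, severity-grading concordance at the
64-mmHg threshold, and Pearson correlation with the standard error of
estimate of the method-vs-method regression.

Difference convention throughout: reference minus candidate, i.e. the
model's prediction error is TPG_catheter - TPG_CT; a positive bias means
the candidate underestimates the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model_core import SEVERITY_THRESHOLD_MMHG, grade_severity

__all__ = [
    "BlandAltmanResult",
    "ICCResult",
    "ComparisonResult",
    "SubgroupComparison",
    "ConcordanceResult",
    "CorrelationResult",
    "bland_altman",
    "icc_oneway",
    "paired_comparison",
    "subgroup_error_comparison",
    "grading_concordance",
    "correlation_and_see",
]

_LOA_MULTIPLIER = 1.96  # limits of agreement at mean +/- 1.96 SD
_WILCOXON_EXACT_MAX_N = 25


def _paired_arrays(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors")
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("inputs must be pairwise complete and finite")
    return xa, ya


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float  # bias, mmHg
    sd_diff: float  # SD of differences (n-1 denominator), mmHg
    loa_lower: float  # mean_diff - 1.96 sd_diff
    loa_upper: float  # mean_diff + 1.96 sd_diff
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    n_subjects: int
    k_raters: int


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "t" or "wilcoxon"
    statistic: float
    p: float
    mean_diff: float


@dataclass(frozen=True)
class SubgroupComparison:
    test_used: str  # "two_sample_t" or "mann_whitney"
    group_means: tuple  # mmHg, in label order (group 0, group 1)
    statistic: float
    p: float


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_a_only: int  # graded above threshold by method a only
    n_b_only: int
    pct_concordant: float  # rounded to one decimal
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    see: float  # standard error of estimate, mmHg


def bland_altman(x, y) -> BlandAltmanResult:
    """Agreement between paired measurements via differences ``x - y``.

    Pass the reference method first (e.g. catheter) and the candidate second
    so the bias reads as the candidate's mean prediction error.  The SD uses
    the sample (n-1) denominator and the limits of agreement are
    mean +/- 1.96 SD.
    """
    xa, ya = _paired_arrays(x, y, min_n=2)
    d = xa - ya
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - _LOA_MULTIPLIER * sd,
        loa_upper=mean + _LOA_MULTIPLIER * sd,
        n=int(d.size),
    )


def icc_oneway(ratings) -> ICCResult:
    """One-way random-effects intraclass correlation, ICC(1).

    ``ratings`` is a complete n_subjects x k_raters matrix.  From the
    one-way ANOVA decomposition,

        ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW)

    with MSB the between-subject and MSW the within-subject mean square.
    When both mean squares are zero (all entries identical) the coefficient
    is undefined and NaN is returned with a warning.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects-by-raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(m)):
        raise ValidationError("ratings matrix must be complete (no missing values)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        warnings.warn("ICC(1) undefined: zero between- and within-subject variance", stacklevel=2)
        return ICCResult(icc=float("nan"), n_subjects=n, k_raters=k)
    return ICCResult(icc=float((msb - msw) / denom), n_subjects=n, k_raters=k)


def paired_comparison(x, y, alpha: float = 0.05) -> ComparisonResult:
    """Paired two-sample comparison with a Shapiro-Wilk normality gate.

    The Shapiro-Wilk test on the paired differences decides the branch: a
    paired-samples t-test when normality is not rejected at ``alpha``,
    otherwise the Wilcoxon signed-rank test (exact distribution for
    n <= 25, normal approximation with continuity correction above).
    Constant differences gate to the Wilcoxon branch; all-zero differences
    return p = 1 with a warning (no evidence of a difference).
    """
    xa, ya = _paired_arrays(x, y, min_n=3)
    d = xa - ya
    mean_diff = float(d.mean())
    if np.ptp(d) == 0:
        # Shapiro-Wilk is undefined on a constant sample
        if np.all(d == 0):
            warnings.warn("all paired differences are zero", stacklevel=2)
            return ComparisonResult("wilcoxon", float("nan"), 1.0, mean_diff)
        normal = False
    else:
        normal = stats.shapiro(d).pvalue > alpha
    if normal:
        res = stats.ttest_rel(xa, ya)
        return ComparisonResult("t", float(res.statistic), float(res.pvalue), mean_diff)
    method = "exact" if d.size <= _WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(xa, ya, method=method, correction=(method == "approx"))
    return ComparisonResult("wilcoxon", float(res.statistic), float(res.pvalue), mean_diff)


def subgroup_error_comparison(
    errors, groups, alpha: float = 0.05, test: Optional[str] = None
) -> SubgroupComparison:
    """Compare prediction errors between two patient subgroups.

    ``errors`` are per-patient reference-minus-candidate differences (mmHg);
    ``groups`` are binary labels.  Shapiro-Wilk on each group gates between
    an unpaired two-sample t-test (both groups normal) and the Mann-Whitney
    U-test; pass ``test="two_sample_t"`` or ``test="mann_whitney"`` to
    bypass the gate.  Groups must each contain at least 2 patients.
    """
    e = np.asarray(errors, dtype=float)
    g = np.asarray(groups)
    if e.ndim != 1 or g.shape != e.shape:
        raise ValidationError("errors and groups must be 1-D vectors of equal length")
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"expected exactly 2 group labels, got {labels.size}")
    g0 = e[g == labels[0]]
    g1 = e[g == labels[1]]
    if g0.size < 2 or g1.size < 2:
        raise ValidationError("each subgroup needs at least 2 patients")
    means = (float(g0.mean()), float(g1.mean()))

    def _normal(sample: np.ndarray) -> bool:
        if np.ptp(sample) == 0:
            return False
        return stats.shapiro(sample).pvalue > alpha

    if test is not None and test not in ("two_sample_t", "mann_whitney"):
        raise ValidationError(f"unknown test override {test!r}")
    use_t = test == "two_sample_t" if test else (_normal(g0) and _normal(g1))
    if use_t:
        res = stats.ttest_ind(g0, g1)
        return SubgroupComparison("two_sample_t", means, float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
    return SubgroupComparison("mann_whitney", means, float(res.statistic), float(res.pvalue))


def grading_concordance(
    tpg_a, tpg_b, threshold: float = SEVERITY_THRESHOLD_MMHG
) -> ConcordanceResult:
    """Severity-grading concordance of two methods at a maximum-TPG threshold.

    Each patient's gradient is graded above/below the threshold per method;
    the 2x2 cross-tabulation yields the count of concordant patients, the
    discordant counts per direction, and the concordant percentage rounded
    to one decimal.
    """
    a, b = _paired_arrays(tpg_a, tpg_b, min_n=1)
    above_a = np.array([grade_severity(v, threshold).is_above for v in a])
    above_b = np.array([grade_severity(v, threshold).is_above for v in b])
    concordant = int(np.sum(above_a == above_b))
    a_only = int(np.sum(above_a & ~above_b))
    b_only = int(np.sum(~above_a & above_b))
    pct = round(100.0 * concordant / a.size, 1)
    return ConcordanceResult(concordant, a_only, b_only, pct, int(a.size))


def correlation_and_see(x, y) -> CorrelationResult:
    """Pearson correlation plus standard error of estimate.

    The SEE is the residual standard deviation sqrt(SS_res / (n - 2)) of the
    simple linear regression of ``y`` on ``x`` — the spread of one method
    around its linear prediction from the other.  Zero variance in either
    vector is a validation error.
    """
    xa, ya = _paired_arrays(x, y, min_n=3)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined: zero variance in x or y")
    r, p = stats.pearsonr(xa, ya)
    fit = stats.linregress(xa, ya)
    resid = ya - (fit.intercept + fit.slope * xa)
    see = float(np.sqrt(np.sum(resid**2) / (xa.size - 2)))
    return CorrelationResult(r=float(r), p=float(p), see=see)
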