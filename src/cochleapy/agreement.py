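"""Test-retest agreement statistics for repeated measurement series.

Implements the reliability plan used in intraobserver imaging studies:
normality gating (Shapiro-Wilk plus Lilliefors-corrected
Kolmogorov-Smirnov), paired t-tests between series, a repeated-measures
ANOVA / Friedman omnibus across modalities, the two-way
absolute-agreement single-measures intraclass correlation with its
F-based (McGraw-Wong) confidence interval, Cronbach's alpha, and
Bland-Altman analysis against a clinically acceptable margin.

The ICC here is the "two-way mixed model, absolute agreement, single
measures" coefficient; its point estimate coincides with the two-way
random-effects ICC(A,1), only the inferential interpretation differs.
Interpretation categories follow the Cicchetti-style bands
(unacceptable / fair / good / excellent), with lower bounds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import ParameterError, UndefinedStatisticError

ALPHA_LEVEL = 0.05

#: Clinically acceptable divergence for CDL_OC between test series (mm).
CDL_CLINICAL_MARGIN_MM = 1.5
#: Clinically acceptable divergence for the inter-electrode distance (mm),
#: derived from the CDL margin by proportional rescaling (see
#: :func:`derive_ied_margin`).
IED_CLINICAL_MARGIN_MM = 0.09

#: Differences below this (mm) are numerical noise, not disagreement;
#: paired contracts treat them as exact ties.
NUMERICAL_TIE_ATOL = 1e-9

ICC_BANDS = ((0.75, "excellent"), (0.6, "good"), (0.4, "fair"))
ALPHA_BANDS = ((0.9, "excellent"), (0.8, "good"), (0.7, "fair"))


@dataclass
class PairedSeries:
    """An n x k matrix of one scalar measurement over k matched test series."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("PairedSeries.values must be a 2D (n x k) array")
        if self.values.shape[1] < 2:
            raise ParameterError("need at least k = 2 series")
        if np.isnan(self.values).any():
            raise ParameterError("PairedSeries does not allow missing cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _as_matrix(data: PairedSeries | np.ndarray) -> np.ndarray:
    if isinstance(data, PairedSeries):
        return data.values
    return PairedSeries(np.asarray(data, dtype=float)).values


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def _mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA decomposition: (MS_rows, MS_cols, MS_error, n, k)."""
    n, k = x.shape
    if n < 3:
        raise ParameterError("need at least 3 subjects for variance-component estimates")
    grand = x.mean()
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        n,
        k,
    )


def icc_two_way_mixed_absolute_single(data: PairedSeries | np.ndarray) -> float:
    """Two-way mixed-model, absolute-agreement, single-measures ICC.

    From the subjects x series mean squares::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Raises
    ------
    UndefinedStatisticError
        If the table has zero total variance (the coefficient is then
        indeterminate, not 0 or 1).
    """
    x = _as_matrix(data)
    msr, msc, mse, n, k = _mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.allclose(x, x.flat[0]):
        raise UndefinedStatisticError(
            "ICC is undefined for a table with zero total variance"
        )
    return float((msr - mse) / denom)


def icc_confidence_interval(
    data: PairedSeries | np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """F-based confidence interval for the absolute-agreement
    single-measures ICC (McGraw-Wong construction with Satterthwaite
    degrees of freedom)."""
    if not (0.0 < level < 1.0):
        raise ParameterError("confidence level must lie in (0, 1)")
    x = _as_matrix(data)
    icc = icc_two_way_mixed_absolute_single(x)
    msr, msc, mse, n, k = _mean_squares(x)
    alpha = 1.0 - level
    if mse <= 0:
        # Perfect within-subject agreement: the interval degenerates at 1
        # from below via the F limit; guard the division explicitly.
        fj = np.inf
    else:
        fj = msc / mse
    a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    vn = (n - 1) * (k - 1) * a**2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    with np.errstate(invalid="ignore", over="ignore"):
        v = vn / vd if np.isfinite(fj) else (n - 1) * (k - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    low = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    high = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    low, high = float(min(low, icc)), float(max(high, icc))
    return max(low, -1.0), min(high, 1.0)


def classify_icc(value: float) -> str:
    """Cicchetti band for an ICC: unacceptable < 0.4 <= fair < 0.6 <= good
    < 0.75 <= excellent (lower bounds inclusive)."""
    for cut, name in ICC_BANDS:
        if value >= cut:
            return name
    return "unacceptable"


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------

def cronbach_alpha(data: PairedSeries | np.ndarray) -> float:
    """Internal-consistency alpha over the k series:
    ``(k/(k-1)) * (1 - sum_j var(col_j) / var(row sums))`` with n-1
    denominators."""
    x = _as_matrix(data)
    if x.shape[0] < 2:
        raise ParameterError("need at least 2 subjects for Cronbach's alpha")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError(
            "Cronbach's alpha is undefined when row sums have zero variance"
        )
    item_var = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def classify_alpha(value: float) -> str:
    """Band for Cronbach's alpha: unacceptable < 0.7 <= fair < 0.8 <= good
    < 0.9 <= excellent (lower bounds inclusive)."""
    for cut, name in ALPHA_BANDS:
        if value >= cut:
            return name
    return "unacceptable"


# ---------------------------------------------------------------------------
# Paired and omnibus tests
# ---------------------------------------------------------------------------

def paired_t_test(data: PairedSeries | np.ndarray) -> float:
    """Two-sided paired t-test between the two series; returns the p-value.

    Degenerate contracts: all-zero differences give p = 1; zero-variance
    differences with a non-zero mean give p = 0.
    """
    x = _as_matrix(data)
    if x.shape[1] != 2:
        raise ParameterError("paired t-test requires exactly k = 2 series")
    d = x[:, 0] - x[:, 1]
    if np.ptp(d) <= NUMERICAL_TIE_ATOL:
        return 1.0 if abs(d.mean()) <= NUMERICAL_TIE_ATOL else 0.0
    return float(sps.ttest_rel(x[:, 0], x[:, 1]).pvalue)


@dataclass
class NormalityDecision:
    """Outcome of the combined normality gate."""

    decision: str  # "parametric" | "nonparametric"
    shapiro_p: float
    ks_p: float
    #: KS variant used: one-sample vs a normal with estimated parameters
    #: (Lilliefors correction).
    ks_variant: str = "lilliefors"

    @property
    def parametric(self) -> bool:
        return self.decision == "parametric"


def normality_gate(samples, alpha: float = ALPHA_LEVEL) -> NormalityDecision:
    """Joint Shapiro-Wilk + Kolmogorov-Smirnov (Lilliefors) normality gate.

    The sample is treated as parametric only when *both* tests fail to
    reject at ``alpha``.  A constant (zero-variance) sample is routed
    nonparametric by contract.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 3:
        raise ParameterError("normality gate needs at least 3 observations")
    if np.ptp(x) == 0.0:
        return NormalityDecision("nonparametric", shapiro_p=0.0, ks_p=0.0)
    sw_p = float(sps.shapiro(x).pvalue)
    if len(x) >= 4:
        ks_p = float(lilliefors(x, dist="norm")[1])
        variant = "lilliefors"
    else:
        # Lilliefors small-sample tables start at n = 4; fall back to the
        # plain KS test against the fitted normal.
        ks_p = float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
        variant = "ks_fitted"
    decision = "parametric" if (sw_p >= alpha and ks_p >= alpha) else "nonparametric"
    return NormalityDecision(decision, shapiro_p=sw_p, ks_p=ks_p, ks_variant=variant)


@dataclass
class OmnibusResult:
    method: str  # "rm_anova" | "friedman"
    statistic: float
    p_value: float
    gates: list[NormalityDecision] = field(default_factory=list)


def _rm_anova(x: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on an n x k matrix: F and p for the
    condition effect against the subject x condition residual."""
    msr, msc, mse, n, k = _mean_squares(x)
    del msr
    if mse <= 0:
        if msc <= 0:
            return 0.0, 1.0  # zero effect, zero residual: no evidence
        return np.inf, 0.0
    f_stat = msc / mse
    p = float(sps.f.sf(f_stat, k - 1, (n - 1) * (k - 1)))
    return float(f_stat), p


def omnibus_modality_test(
    columns, alpha: float = ALPHA_LEVEL
) -> OmnibusResult:
    """Omnibus comparison of matched measurement columns (one per
    modality): repeated-measures ANOVA when every column passes the
    normality gate, otherwise the Friedman test."""
    cols = [np.asarray(c, dtype=float).ravel() for c in columns]
    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise ParameterError(f"columns are not subject-matched: lengths {sorted(lengths)}")
    if len(cols) < 2:
        raise ParameterError("omnibus test needs at least 2 columns")
    x = np.column_stack(cols)
    gates = [normality_gate(c, alpha=alpha) for c in cols]
    method = "rm_anova" if all(g.parametric for g in gates) else "friedman"
    if np.ptp(x - x.mean(axis=1, keepdims=True)) <= NUMERICAL_TIE_ATOL:
        return OmnibusResult(method, 0.0, 1.0, gates)  # no within-subject effect
    if method == "rm_anova":
        stat, p = _rm_anova(x)
    else:
        stat, p = sps.friedmanchisquare(*cols)
    return OmnibusResult(method, float(stat), float(p), gates)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement between two series against a clinical margin.

    ``bias`` is the mean of (series 1 - series 2); the limits of agreement
    are ``bias +/- 1.96 * sd_diff``; subjects whose absolute difference
    exceeds ``clinical_margin`` are counted as clinically relevant
    outliers.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    clinical_margin: float
    n_outliers: int
    outlier_ids: list
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(
    data: PairedSeries | np.ndarray,
    clinical_margin: float,
    subject_ids=None,
) -> BlandAltmanResult:
    """Bland-Altman analysis of two matched series (k = 2)."""
    x = _as_matrix(data)
    if x.shape[1] != 2:
        raise ParameterError("Bland-Altman requires exactly k = 2 series")
    if clinical_margin <= 0:
        raise ParameterError("clinical_margin must be > 0")
    d = x[:, 0] - x[:, 1]
    m = x.mean(axis=1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    ids = list(subject_ids) if subject_ids is not None else list(range(len(d)))
    outliers = [ids[i] for i in np.flatnonzero(np.abs(d) > clinical_margin)]
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        clinical_margin=float(clinical_margin),
        n_outliers=len(outliers),
        outlier_ids=outliers,
        means=m,
        diffs=d,
    )


def derive_ied_margin(
    cdl_margin: float = CDL_CLINICAL_MARGIN_MM,
    nominal_pitch: float = 2.1,
    reference_cdl: float = 35.0,
) -> float:
    """Rescale the clinically acceptable CDL margin to a per-interval
    inter-electrode-distance margin: ``cdl_margin * pitch / reference_cdl``,
    rounded to 2 decimals.  With the FLEX28 pitch of 2.1 mm and a 35 mm
    reference duct length, the 1.5 mm CDL margin maps to 0.09 mm."""
    if cdl_margin <= 0 or nominal_pitch <= 0 or reference_cdl <= 0:
        raise ParameterError("all margin inputs must be > 0")
    return round(cdl_margin * nominal_pitch / reference_cdl, 2)


# ---------------------------------------------------------------------------
# Combined reliability summary
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    """ICC, Cronbach's alpha, and the paired series comparison for one
    measurement block."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_category: str
    alpha: float
    alpha_category: str
    t_p_value: float
    significant: bool  # series differ at p < 0.05
    icc_significant: bool  # CI excludes 0


def reliability_summary(
    data: PairedSeries | np.ndarray, level: float = 0.95
) -> ReliabilityResult:
    """ICC with CI and category, Cronbach's alpha with category, and the
    paired t-test between the two series (k = 2 only for the t-test)."""
    x = _as_matrix(data)
    icc = icc_two_way_mixed_absolute_single(x)
    lo, hi = icc_confidence_interval(x, level=level)
    alpha = cronbach_alpha(x)
    t_p = paired_t_test(x) if x.shape[1] == 2 else float("nan")
    return ReliabilityResult(
        icc=icc,
        icc_ci_low=lo,
        icc_ci_high=hi,
        icc_category=classify_icc(icc),
        alpha=alpha,
        alpha_category=classify_alpha(alpha),
        t_p_value=t_p,
        significant=bool(t_p < ALPHA_LEVEL),
        icc_significant=bool(lo > 0.0),
    )
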