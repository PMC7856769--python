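"""Method-agreement and split-mouth statistics.

Bland-Altman agreement (mean difference and critical difference, i.e. the
1.96·SD half-width of the limits of agreement), intraclass correlation for
repeated measurements, Wilcoxon signed-rank and paired t tests, and
ordinary least-squares regression with adjusted R².

Conventions fixed here because the underlying literature leaves them open:
the critical difference is 1.96 × the sample SD (n−1) of the paired
differences; the ICC is the two-way, absolute-agreement, single-measurement
form ICC(2,1); the regression R² is the adjusted R² (which, unlike the
plain R², can be negative for uninformative predictors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import StatsError


@dataclass
class AgreementReport:
    """Bland-Altman agreement summary (optionally with an ICC attached)."""

    mean_difference: float
    critical_difference: float
    limits: tuple[float, float]
    n_pairs: int
    icc: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.critical_difference < 0:
            raise StatsError("critical difference must be >= 0")

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "critical_difference": self.critical_difference,
            "limits_of_agreement": list(self.limits),
            "n_pairs": self.n_pairs,
            "icc": self.icc,
            "unit": self.unit,
        }

    def to_records(self) -> list[dict]:
        rows = [
            {"quantity": "mean_difference", "value": self.mean_difference, "unit": self.unit},
            {"quantity": "critical_difference", "value": self.critical_difference, "unit": self.unit},
            {"quantity": "loa_lower", "value": self.limits[0], "unit": self.unit},
            {"quantity": "loa_upper", "value": self.limits[1], "unit": self.unit},
            {"quantity": "n_pairs", "value": self.n_pairs, "unit": ""},
        ]
        if self.icc is not None:
            rows.append({"quantity": "icc", "value": self.icc, "unit": ""})
        return rows


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    slope: float | None = None
    intercept: float | None = None
    adj_r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p_value": self.p_value, "n": self.n, "method": self.method}
        for k in ("slope", "intercept", "adj_r_squared"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def bland_altman(a, b, unit: str = "") -> AgreementReport:
    """Agreement between paired measurements: d = a − b.

    mean_difference = mean(d); critical_difference = 1.96 × sample SD(d)
    (n−1 denominator); limits = mean ± critical."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("inputs must be equal-length 1-D arrays")
    if a.size < 2:
        raise StatsError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    crit = 1.96 * sd
    return AgreementReport(
        mean_difference=mean,
        critical_difference=crit,
        limits=(mean - crit, mean + crit),
        n_pairs=int(a.size),
        unit=unit,
    )


def icc(ratings) -> float:
    """ICC(2,1): two-way, absolute agreement, single measurement.

    ``ratings`` is an (n subjects × k repeats) table with no missing cells.
    Computed from the standard mean-squares decomposition:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError("need at least 2 subjects and 2 repeats")
    if not np.all(np.isfinite(x)):
        raise StatsError("ratings must be finite (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise StatsError("zero total variance: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise StatsError("degenerate ratings: ICC undefined")
    return float((msr - mse) / denom)


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment), ties are
    mid-ranked; the exact null distribution is used for n ≤ 25 without
    ties, otherwise the normal approximation with continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("inputs must be equal-length 1-D arrays")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise StatsError("all paired differences are zero")
    if nz.size < 5:
        raise StatsError("need at least 5 nonzero differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"), alternative="two-sided", method=method
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(nz.size),
        method=f"wilcoxon-signed-rank ({method})",
    )


def paired_t(a, b) -> TestResult:
    """Two-sided paired t test (one-sample t on the differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StatsError("need equal-length 1-D arrays with n >= 3")
    d = a - b
    if np.all(d == d[0]) and d[0] != 0:
        # constant nonzero shift: t is infinite only when SD is 0
        pass
    if d.std(ddof=1) == 0:
        if d[0] == 0:
            return TestResult(statistic=0.0, p_value=1.0, n=int(a.size), method="paired-t")
        raise StatsError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(a, b)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n=int(a.size), method="paired-t")


def linear_fit(x, y) -> TestResult:
    """OLS fit y = slope·x + intercept with slope test and adjusted R²."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatsError("need equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("x is constant: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TestResult(
        statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
        method="ols-linear-regression",
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
    )
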