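"""Agreement and repeatability statistics for paired strain measurements.

Implements the comparison toolbox used for method-agreement and scan/re-scan
studies: Pearson correlation with ordinal grading, zero-intercept linear
regression with a t-based confidence interval, two-way ANOVA intraclass
correlation (absolute agreement, single measurement) with an F-based CI and
graded reliability, within-subject coefficient of variation, minimal
detectable change, and Bland-Altman limits of agreement.

Grading bands (left-open, per convention): Pearson r above 0.8 very strong,
above 0.7 good, above 0.6 moderate, above 0.3 fair, otherwise poor; ICC
below 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, above 0.9 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

_R_BANDS = [(0.8, "very strong"), (0.7, "good"), (0.6, "moderate"), (0.3, "fair")]
_ICC_GRADES = ["poor", "moderate", "good", "excellent"]


@dataclass
class PairedMeasurements:
    """Two equal-length measurement sequences on the same subjects."""

    a: np.ndarray
    b: np.ndarray
    subjects: list | None = None
    units: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("need two equal-length 1-D sequences")
        if len(self.a) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("non-finite values in input")

    @property
    def n(self) -> int:
        return len(self.a)


def grade_r(r: float) -> str:
    for lo, name in _R_BANDS:
        if r > lo:
            return name
    return "poor"


def grade_icc(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def pearson_r(pairs: PairedMeasurements) -> tuple[float, str]:
    """Product-moment correlation with its ordinal grade."""
    if np.ptp(pairs.a) == 0 or np.ptp(pairs.b) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    r = float(sps.pearsonr(pairs.a, pairs.b).statistic)
    return r, grade_r(r)


def zero_intercept_regression(pairs: PairedMeasurements,
                              conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Through-origin least squares: slope = sum(xy)/sum(x^2), CI from the
    through-origin standard error with n-1 degrees of freedom."""
    x, y = pairs.a, pairs.b
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("regressor is identically zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    dof = pairs.n - 1
    s2 = float(np.sum(resid**2)) / dof
    se = np.sqrt(s2 / sxx)
    t = sps.t.ppf(0.5 + conf / 2, dof)
    return slope, (slope - t * se, slope + t * se)


def icc_agreement(pairs: PairedMeasurements, conf: float = 0.95,
                  include_lower: bool = False) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, from the two-way ANOVA mean squares, with the F-based CI.

    The reported grade spans the point estimate and the CI upper bound
    (e.g. "good to excellent"); ``include_lower`` extends the span to the
    CI lower bound as well.
    """
    if pairs.n < 5:
        import warnings
        warnings.warn("fewer than 5 subjects: ICC estimate is unstable")
    data = np.stack([pairs.a, pairs.b], axis=1)  # subjects x raters
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)  # between raters
    sse = np.sum((data - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1 - conf
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isinf(a):
        lo, hi = 1.0, 1.0
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    grades = [grade_icc(icc), grade_icc(min(hi, 1.0))]
    if include_lower:
        grades.append(grade_icc(max(lo, 0.0)))
    order = {g: i for i, g in enumerate(_ICC_GRADES)}
    lo_g = min(grades, key=lambda g: order[g])
    hi_g = max(grades, key=lambda g: order[g])
    grade = lo_g if lo_g == hi_g else f"{lo_g} to {hi_g}"
    return {"icc": float(icc), "ci": (float(lo), float(hi)), "grade": grade}


def cov_repeatability(pairs: PairedMeasurements) -> float:
    """Within-subject coefficient of variation (%): SD of the paired
    differences / sqrt(2), over the magnitude of the grand mean."""
    grand = np.mean(np.concatenate([pairs.a, pairs.b]))
    if grand == 0:
        raise ValueError("zero grand mean")
    ws_sd = np.std(pairs.a - pairs.b, ddof=1) / np.sqrt(2)
    return float(ws_sd / abs(grand) * 100.0)


def minimal_detectable_change(sd_first_scan: float, icc: float) -> dict:
    """SEM = SD * sqrt(1 - ICC); MDC = SEM * sqrt(2) * 1.96."""
    if not 0 <= icc <= 1:
        raise ValueError("ICC must lie in [0, 1]")
    if sd_first_scan < 0:
        raise ValueError("SD must be non-negative")
    sem = sd_first_scan * np.sqrt(1 - icc)
    return {"sem": float(sem), "mdc": float(sem * np.sqrt(2) * 1.96)}


def bland_altman(pairs: PairedMeasurements) -> dict:
    """Mean difference and limits of agreement (mean +/- 1.96 SD of the
    differences), plus the per-pair means/differences for plotting."""
    d = pairs.a - pairs.b
    m = (pairs.a + pairs.b) / 2
    md = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return {"mean_diff": md, "loa": (md - 1.96 * sd, md + 1.96 * sd),
            "sd_diff": sd, "means": m, "diffs": d}


def bland_altman_plot(pairs: PairedMeasurements, path) -> None:
    """Write a Bland-Altman scatter (per-pair mean vs difference) with the
    bias and limits of agreement to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res["means"], res["diffs"], s=18, color="tab:blue")
    ax.axhline(res["mean_diff"], color="red", label="bias")
    for lim in res["loa"]:
        ax.axhline(lim, color="black", linestyle=":")
    ax.set_xlabel(f"mean {pairs.units}".strip())
    ax.set_ylabel(f"difference {pairs.units}".strip())
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class AgreementReport:
    """Full statistical comparison of two paired measurement sets."""

    n: int
    r: float
    r_grade: str
    slope: float
    slope_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    icc_grade: str
    cov_percent: float
    sem: float
    mdc: float
    mean_diff: float
    loa: tuple[float, float]
    units: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    r, rg = pearson_r(pairs)
    slope, ci = zero_intercept_regression(pairs)
    icc = icc_agreement(pairs)
    cov = cov_repeatability(pairs)
    md = minimal_detectable_change(float(np.std(pairs.a, ddof=1)), icc["icc"])
    ba = bland_altman(pairs)
    return AgreementReport(
        n=pairs.n, r=r, r_grade=rg, slope=slope, slope_ci=ci,
        icc=icc["icc"], icc_ci=icc["ci"], icc_grade=icc["grade"],
        cov_percent=cov, sem=md["sem"], mdc=md["mdc"],
        mean_diff=ba["mean_diff"], loa=ba["loa"], units=pairs.units,
    )
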