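"""Agreement and BMI-dependence statistics.

The battery mirrors a typical SUV-normalization comparison study: Bland-Altman
agreement against a reference standard, ordinary least squares and Pearson
correlation of SUV against BMI, paired and unpaired t tests, one-way ANOVA
across normalization methods, a Kolmogorov-Smirnov normality check, and the
coefficient of variation as a cross-subject consistency measure.

Conventions fixed here and relied on by the report tables:

* Bland-Altman bias is mean(reference - test); limits of agreement are
  bias -/+ 2*SD (two whole standard deviations, not 1.96).
* The KS test is against a normal with the *sample* mean and SD, without the
  Lilliefors small-sample correction; its p-values are conservative.
* BMI categories use half-open bins [0,18.5), [18.5,25), [25,30), [30,inf)
  named underweight / normal / overweight / obese.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
_BMI_EDGES = (18.5, 25.0, 30.0)

SUV_METHODS = ("bw", "dixon", "james", "janma")
LEAN_METHODS = ("dixon", "james", "janma")


@dataclass
class BlandAltmanResult:
    """Agreement between a reference and a test series: bias = mean(ref-test),
    sd = sample SD of differences, limits of agreement = bias -/+ 2 sd."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def _as_arrays(*seqs) -> list[np.ndarray]:
    return [np.asarray(s, dtype=np.float64) for s in seqs]


def bland_altman(reference, test) -> BlandAltmanResult:
    """Bland-Altman agreement of ``test`` against ``reference``."""
    ref, tst = _as_arrays(reference, test)
    if ref.shape != tst.shape:
        raise ValueError(f"length mismatch: {ref.size} vs {tst.size}")
    if ref.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = ref - tst
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 2 * sd, bias + 2 * sd, int(ref.size))


def linear_regression(x, y, fit_intercept: bool = True) -> RegressionResult:
    """Ordinary least squares of y on x with two-sided slope p-value.

    With ``fit_intercept=False`` the line is forced through the origin and r
    is the uncentered correlation (sign of the slope).
    """
    x, y = _as_arrays(x, y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise FitError("need at least 3 points")
    if np.ptp(x) == 0:
        raise FitError("x is constant; slope undefined")
    if fit_intercept:
        res = sps.linregress(x, y)
        return RegressionResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            r_squared=float(res.rvalue) ** 2,
            p_value=float(res.pvalue),
            n=n,
        )
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    se = np.sqrt(ss_res / (n - 1) / sxx)
    if se > 0:
        t = slope / se
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    else:
        p = 0.0
    r = float(np.sign(slope) * np.sqrt(max(r2, 0.0)))
    return RegressionResult(slope, 0.0, r, r2, float(p), n)


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-distribution p-value."""
    x, y = _as_arrays(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t(a, b) -> tuple[float, float]:
    """Paired two-sided t test; errors on zero difference variance."""
    a, b = _as_arrays(a, b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("difference variance is zero; paired t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def unpaired_t(a, b) -> tuple[float, float]:
    """Equal-variance two-sample t test, two-sided."""
    a, b = _as_arrays(a, b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups degenerate; t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F and p across two or more independent groups."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs at least 2 observations")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def ks_normal(x) -> tuple[float, float]:
    """One-sample KS statistic against Normal(sample mean, sample SD)."""
    (x,) = _as_arrays(x)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; KS test undefined")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(d), float(p)


def coefficient_of_variation(x) -> float:
    """Sample SD (n-1) divided by the mean."""
    (x,) = _as_arrays(x)
    m = x.mean()
    if m == 0:
        raise ValueError("zero mean; CV undefined")
    return float(x.std(ddof=1) / m)


def bmi_categorize(bmi: float) -> str:
    """BMI category on half-open bins; bin edges go to the upper category."""
    if bmi <= 0:
        raise ValueError(f"bmi must be > 0, got {bmi}")
    for name, edge in zip(BMI_CATEGORIES, _BMI_EDGES):
        if bmi < edge:
            return name
    return BMI_CATEGORIES[-1]


# --------------------------------------------------------------------------
# report tables
# --------------------------------------------------------------------------


def lbm_agreement_table(df: pd.DataFrame) -> pd.DataFrame:
    """Agreement of lean-fraction methods against the DXA reference.

    ``df`` needs columns ``sex`` and per-method lean fractions (percent)
    ``frac_dxa``, ``frac_dixon``, ``frac_james``, ``frac_janma``. One row per
    (group, method) with mean, SD, bias +/- 2 SD (DXA minus method), paired-t
    p and Pearson r against DXA — a cohort-agreement summary table.
    """
    rows = []
    for group, sub in (("F", df[df.sex == "F"]), ("M", df[df.sex == "M"]), ("all", df)):
        if len(sub) < 3:
            continue
        ref = sub["frac_dxa"].to_numpy()
        for method in LEAN_METHODS:
            est = sub[f"frac_{method}"].to_numpy()
            ba = bland_altman(ref, est)
            t, p = paired_t(ref, est)
            r, _ = pearson_corr(ref, est)
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "n": len(sub),
                    "reference_mean": ref.mean(),
                    "mean": est.mean(),
                    "sd": est.std(ddof=1),
                    "bias": ba.bias,
                    "bias_2sd": 2 * ba.sd,
                    "paired_t_p": p,
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(rows)


def build_suv_bmi_table(measurements: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per organ x statistic x method summary of SUV and its BMI dependence.

    ``measurements`` needs columns subject_id, organ, statistic, suv_bw,
    suv_dixon, suv_james, suv_janma; ``subjects`` needs subject_id and bmi.
    Each row carries mean, SD, CV, the OLS slope of SUV on BMI, Pearson r and
    p, plus two one-way ANOVA p-values per organ x statistic: across all four
    methods and across the three lean methods.
    """
    df = measurements.merge(subjects[["subject_id", "bmi"]], on="subject_id")
    rows = []
    for (organ, statistic), sub in df.groupby(["organ", "statistic"], sort=True):
        if len(sub) < 3:
            continue
        series = {m: sub[f"suv_{m}"].to_numpy() for m in SUV_METHODS}
        anova_all = one_way_anova([series[m] for m in SUV_METHODS])[1]
        anova_lean = one_way_anova([series[m] for m in LEAN_METHODS])[1]
        bmi = sub["bmi"].to_numpy()
        for method in SUV_METHODS:
            vals = series[method]
            reg = linear_regression(bmi, vals)
            r, p = pearson_corr(bmi, vals)
            rows.append(
                {
                    "organ": organ,
                    "statistic": statistic,
                    "method": method,
                    "n": len(sub),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "cv": coefficient_of_variation(vals),
                    "slope_bmi": reg.slope,
                    "r_bmi": r,
                    "p_bmi": p,
                    "anova_p_all": anova_all,
                    "anova_p_lean": anova_lean,
                }
            )
    return pd.DataFrame(rows)


def bmi_subgroup_table(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame,
    organ: str = "liver",
    statistic: str = "mean",
) -> pd.DataFrame:
    """Liver-style SUV by BMI category with unpaired-t p against 'normal'.

    One row per (category, method): n, mean, SD, and the two-sided
    equal-variance t-test p-value versus the normal-BMI group (NaN for the
    normal group itself or when a group is too small).
    """
    df = measurements.merge(subjects[["subject_id", "bmi"]], on="subject_id")
    df = df[(df.organ == organ) & (df.statistic == statistic)].copy()
    df["category"] = df["bmi"].map(bmi_categorize)
    rows = []
    for method in SUV_METHODS:
        col = f"suv_{method}"
        normal = df.loc[df.category == "normal", col].to_numpy()
        for category in BMI_CATEGORIES:
            vals = df.loc[df.category == category, col].to_numpy()
            if vals.size == 0:
                continue
            if category == "normal" or vals.size < 2 or normal.size < 2:
                p = np.nan
            else:
                p = unpaired_t(vals, normal)[1]
            rows.append(
                {
                    "organ": organ,
                    "statistic": statistic,
                    "method": method,
                    "category": category,
                    "n": int(vals.size),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "p_vs_normal": p,
                }
            )
    return pd.DataFrame(rows)
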