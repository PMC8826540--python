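"""Agreement statistics for method comparison.

Pearson r, MAE, RMSE, nRMSE (normalized by the reference range), least-squares
regression of estimated on reference with slope tests, Bland-Altman bias and
1.96-SD limits of agreement, and one-way ANOVA for unbalanced group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["AgreementStats", "agreement", "anova_oneway"]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between an estimator and a reference, one subject per entry."""

    n: int
    r: float
    mae: float
    rmse: float
    nrmse: float                 # RMSE / (max(ref) - min(ref)); NaN if ref constant
    slope: float                 # least squares of est on ref
    intercept: float
    slope_p: float               # two-sided, H0: slope = 0 (Wald t-test)
    slope_eq1_p: float           # two-sided, H0: slope = 1 (equality line)
    bias: float                  # mean(est - ref)
    sd_diff: float
    loa_low: float               # bias - 1.96 sd_diff
    loa_high: float              # bias + 1.96 sd_diff
    pct_outside_loa: float       # % strictly outside either limit

    def summary(self) -> str:
        return "\n".join([
            f"n               {self.n}",
            f"Pearson r       {self.r:8.3f}",
            f"MAE             {self.mae:8.3f}",
            f"RMSE            {self.rmse:8.3f}",
            f"nRMSE           {self.nrmse:8.3%}",
            f"slope           {self.slope:8.3f}  (P[slope=0]={self.slope_p:.3g}, "
            f"P[slope=1]={self.slope_eq1_p:.3g})",
            f"intercept       {self.intercept:8.3f}",
            f"bias            {self.bias:8.3f}",
            f"LoA             ({self.loa_low:.1f}, {self.loa_high:.1f})",
            f"outside LoA     {self.pct_outside_loa:8.1f} %",
        ])


def agreement(est, ref) -> AgreementStats:
    """Compute the full agreement panel between estimates and references."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValidationError("est and ref must be 1-D arrays of equal length")
    n = len(est)
    if n < 3:
        raise ValidationError("need at least 3 paired values")

    diff = est - ref
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    ref_range = float(np.max(ref) - np.min(ref))
    if ref_range == 0.0:
        warnings.warn("reference is constant: nRMSE undefined (NaN)")
        nrmse = float("nan")
        r = float("nan")
        slope = intercept = slope_p = slope_eq1_p = float("nan")
    else:
        nrmse = rmse / ref_range
        if np.std(est) == 0.0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(est, ref).statistic)
        fit = stats.linregress(ref, est)
        slope, intercept = float(fit.slope), float(fit.intercept)
        slope_p = float(fit.pvalue)
        if fit.stderr > 0:
            t1 = (fit.slope - 1.0) / fit.stderr
            slope_eq1_p = float(2.0 * stats.t.sf(abs(t1), n - 2))
        else:
            slope_eq1_p = float(slope == 1.0)

    bias = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    loa_low = bias - LOA_MULTIPLIER * sd_diff
    loa_high = bias + LOA_MULTIPLIER * sd_diff
    outside = np.sum((diff < loa_low) | (diff > loa_high))
    return AgreementStats(
        n=n, r=r, mae=mae, rmse=rmse, nrmse=nrmse,
        slope=slope, intercept=intercept, slope_p=slope_p,
        slope_eq1_p=slope_eq1_p, bias=bias, sd_diff=sd_diff,
        loa_low=loa_low, loa_high=loa_high,
        pct_outside_loa=100.0 * outside / n)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p for >= 2 groups of unequal sizes."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
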