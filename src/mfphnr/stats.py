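"""Case-control statistics: summaries, normative limits, ANOVA, regressions.

Implements the analysis surface of a macular structure-function study:

* group means/SDs per region and measure;
* two-group one-way ANOVA, both from raw values and from summary statistics
  (the summary form lets a patient table be compared against a published
  control mean/SD/n when raw control data are not deposited);
* control-derived one-sided lower 95% normative limits and strict
  below-limit abnormality classification;
* ordinary least squares regression of functional on structural values with
  t-based 95% CIs and R^2, and Pearson correlation;
* eccentricity/sector trend fits with a group interaction term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class NormativeLimits:
    """Per-(region_type, region, measure) lower limits with provenance."""

    limits: dict[tuple[str, str, str], float]
    n_controls: Optional[int]
    method: str  # "computed" | "supplied"

    def limit_for(self, region_type: str, region: str, measure: str) -> float:
        key = (region_type, region, measure)
        if key not in self.limits:
            raise KeyError(f"no normative limit for {key}")
        return self.limits[key]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    n: int


@dataclass
class TrendFit:
    group: str
    slope: float       # per unit region index
    intercept: float   # fitted value at the first level (index 0)
    n: int


def group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) per group/region_type/region/measure."""
    g = cohort.groupby(["group", "region_type", "region", "measure"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        raise ValueError("every group/region cell needs at least 2 eyes")
    return out


def anova_oneway(a: Sequence[float], b: Sequence[float]
                 ) -> tuple[float, tuple[int, int], float]:
    """Classical two-group one-way ANOVA: F, (1, n-2), p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) + len(b) < 3:
        raise ValueError("need at least 3 observations in total")
    F, p = sps.f_oneway(a, b)
    return float(F), (1, len(a) + len(b) - 2), float(p)


def anova_from_summary(m1: float, s1: float, n1: int,
                       m2: float, s2: float, n2: int
                       ) -> tuple[float, tuple[int, int], float]:
    """Two-group one-way ANOVA from summary statistics.

    F = (n1 n2 / (n1 + n2)) (m1 - m2)^2 / s2_pooled with the usual pooled
    variance; identical to the raw-data F when the summaries come from the
    raw data.  Zero pooled variance with unequal means yields F = inf.
    """
    if n1 + n2 < 3 or min(n1, n2) < 1:
        raise ValueError("need n1 + n2 >= 3")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    df = (1, n1 + n2 - 2)
    pooled = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled == 0:
        if m1 == m2:
            return 0.0, df, 1.0
        return math.inf, df, 0.0
    F = (n1 * n2 / (n1 + n2)) * (m1 - m2) ** 2 / pooled
    p = float(sps.f.sf(F, *df))
    return float(F), df, p


def normative_limit_from_summary(mean: float, sd: float, n: int) -> float:
    """One-sided lower 95% confidence bound of the control mean:
    mean - t(0.975, n-1) * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("need at least 2 controls")
    return float(mean - sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))


def compute_normative_limits(control_summary: pd.DataFrame) -> NormativeLimits:
    """Limits computed from a control summary table (mean/sd/n per region)."""
    limits = {}
    n_controls = None
    for r in control_summary.itertuples():
        limits[(r.region_type, r.region, r.measure)] = \
            normative_limit_from_summary(r.mean, r.sd, int(r.n))
        n_controls = int(r.n)
    return NormativeLimits(limits=limits, n_controls=n_controls, method="computed")


def supplied_normative_limits(table: pd.DataFrame,
                              n_controls: Optional[int] = None) -> NormativeLimits:
    """Pass-through of externally supplied limits (column ``limit``)."""
    limits = {(r.region_type, r.region, r.measure): float(r.limit)
              for r in table.itertuples()}
    return NormativeLimits(limits=limits, n_controls=n_controls, method="supplied")


def classify_abnormal(values: Sequence[float], limit: float
                      ) -> tuple[np.ndarray, int, float]:
    """Strictly-below-limit classification: flags, count, percentage.

    A value exactly at the limit is normal.  Percentage is returned at full
    precision; report layers round to 1 dp.
    """
    values = np.asarray(values, float)
    flags = values < limit
    n_ab = int(flags.sum())
    return flags, n_ab, 100.0 * n_ab / len(values)


def morphofunctional_regression(rad: Sequence[float], gcl: Sequence[float]
                                ) -> RegressionResult:
    """OLS of functional (RAD, dependent) on structural (GCL-T, independent)
    values, with a t-based 95% CI on the slope and R^2 = squared Pearson r."""
    rad, gcl = np.asarray(rad, float), np.asarray(gcl, float)
    if len(rad) != len(gcl) or len(rad) < 3:
        raise ValueError("need paired values, n >= 3")
    if np.std(gcl) == 0:
        raise ValueError("independent variable has zero variance")
    X = sm.add_constant(gcl)
    fit = sm.OLS(rad, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        ci_low=float(ci[1, 0]), ci_high=float(ci[1, 1]),
        r2=float(fit.rsquared), p=float(fit.pvalues[1]), n=len(rad))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, R^2 and the t-transform p-value (n-2 df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired values, n >= 3")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def trend_fit(values: Sequence[float], region_index: Sequence[float],
              groups: Sequence[str]) -> tuple[dict[str, TrendFit], float]:
    """Per-group linear trends across unit-coded region levels, plus the
    p-value of the group x index interaction in the pooled model.

    With balanced complete data the per-group slope equals the slope fitted
    to the group's level means.
    """
    values = np.asarray(values, float)
    x = np.asarray(region_index, float)
    groups = np.asarray(groups)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 region levels")
    labels = list(dict.fromkeys(groups))  # preserve first-appearance order
    fits = {}
    for lab in labels:
        m = groups == lab
        slope, intercept = np.polyfit(x[m], values[m], 1)
        fits[lab] = TrendFit(group=str(lab), slope=float(slope),
                             intercept=float(intercept), n=int(m.sum()))
    interaction_p = math.nan
    if len(labels) == 2:
        ind = (groups == labels[1]).astype(float)
        X = np.column_stack([np.ones_like(x), x, ind, x * ind])
        fit = sm.OLS(values, X).fit()
        interaction_p = float(fit.pvalues[3])
    return fits, interaction_p


# --- report formatting -------------------------------------------------------

def format_p(p: float, floor: float = 0.001) -> str:
    """Publication-style p formatting: values below the floor print '<floor'."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3f}"
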