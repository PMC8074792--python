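"""Group statistics: one-way ANOVA, Tukey's HSD, and linear regression.

Replicate-level values (one number per independent experiment) are compared
across treatment groups with a fixed-effects one-way ANOVA followed by
Tukey's honestly-significant-difference test (Tukey-Kramer form for
unbalanced groups); dose-response style relationships are summarized with
ordinary least squares, reporting R^2 and the slope p value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "one_way_anova",
    "tukey_hsd",
    "linear_regression",
]

SIGNIFICANCE_LEVEL = 0.05


def _validate_groups(groups: dict[str, np.ndarray], min_per_group: int = 1):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < min_per_group:
            raise ValueError(f"group {label!r} needs >= {min_per_group} values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        out[str(label)] = arr
    return out


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    The p value comes from the F distribution with (k-1, N-k) degrees of
    freedom. When every value is identical the test is degenerate; F = 0 and
    p = 1 are returned with the ``degenerate`` flag set.
    """
    data = _validate_groups(groups)
    samples = list(data.values())
    k = len(samples)
    n_total = sum(s.size for s in samples)
    grand = np.concatenate(samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ss_between = sum(s.size * (s.mean() - grand.mean()) ** 2 for s in samples)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
    if ss_within == 0:
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = SIGNIFICANCE_LEVEL) -> pd.DataFrame:
    """All-pairs Tukey HSD with studentized-range adjusted p values.

    Unbalanced groups use the Tukey-Kramer standard error. Returns one row
    per unordered pair with the mean difference (a - b), the adjusted p and a
    significance flag at ``alpha``.
    """
    data = _validate_groups(groups, min_per_group=2)
    labels = list(data)
    result = sps.tukey_hsd(*data.values())
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_adj = float(np.clip(result.pvalue[i, j], 0.0, 1.0))
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "difference": float(data[labels[i]].mean() - data[labels[j]].mean()),
                "p_adjusted": p_adj,
                "significant": bool(p_adj < alpha),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with R^2 and the slope-vs-zero p value.

    R^2 is the squared Pearson correlation; the p value tests slope != 0 with
    the t distribution on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    r_squared = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    p = 1.0 if np.isnan(fit.pvalue) else float(fit.pvalue)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        p_value=p,
        n=int(x.size),
    )
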