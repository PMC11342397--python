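"""Two-sample comparison: Student's t-test and Cohen's d with 95% CI.

The effect-size confidence interval uses the large-sample normal
approximation SE = sqrt((na+nb)/(na*nb) + d^2/(2*(na+nb))); a
noncentral-t interval is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonReport", "two_sample_t", "cohens_d_ci", "compare_descriptors", "effect_label"]


def effect_label(d: float) -> str:
    """Conventional |d| cut points: <0.2 negligible, [0.2,0.5) small,
    [0.5,0.8) medium, >=0.8 large."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def two_sample_t(a, b, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test; ``pooled`` (Student) or ``welch``.

    Zero variance in both samples with equal means is reported as
    (t=0, p=1) rather than NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(
        np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    )


def cohens_d_ci(
    a, b, level: float = 0.95, method: str = "normal"
) -> tuple[float, tuple[float, float], str]:
    """Pooled-SD Cohen's d with confidence interval and magnitude label."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("both samples need n >= 2")
    sp = _pooled_sd(a, b)
    if sp == 0:
        d = 0.0
    else:
        d = float((a.mean() - b.mean()) / sp)
    if method == "normal":
        se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
        zq = sps.norm.ppf(0.5 + level / 2)
        lo, hi = d - zq * se, d + zq * se
    elif method == "noncentral-t":
        nc = d * np.sqrt(na * nb / (na + nb))
        df = na + nb - 2
        alpha = 1 - level
        lo_nc = _nct_bound(nc, df, 1 - alpha / 2)
        hi_nc = _nct_bound(nc, df, alpha / 2)
        scale = np.sqrt((na + nb) / (na * nb))
        lo, hi = lo_nc * scale, hi_nc * scale
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return d, (float(lo), float(hi)), effect_label(d)


def _nct_bound(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality parameter nc with P(T_{df,nc} <= t_obs) = prob."""
    from scipy.optimize import brentq

    # the t statistic scatters around nc with sd ~1, so a +-8 bracket is ample
    lo, hi = t_obs - 8.0, t_obs + 8.0
    return float(brentq(lambda nc: sps.nct.cdf(t_obs, df, nc) - prob, lo, hi))


@dataclass
class ComparisonReport:
    """Full two-sample summary for one descriptor."""

    descriptor: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    p_value: float
    d: float
    d_ci_low: float
    d_ci_high: float
    label: str

    def as_dict(self) -> dict:
        return asdict(self)


def compare_descriptors(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    columns: list[str] | None = None,
    variant: str = "pooled",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Row-per-descriptor comparison of two per-frame descriptor tables."""
    if columns is None:
        columns = [
            c
            for c in table_a.columns
            if c in table_b.columns
            and c != "frame"
            and pd.api.types.is_numeric_dtype(table_a[c])
            and not pd.api.types.is_bool_dtype(table_a[c])
        ]
    reports = []
    for col in columns:
        a = table_a[col].dropna().to_numpy(dtype=np.float64)
        b = table_b[col].dropna().to_numpy(dtype=np.float64)
        t, p = two_sample_t(a, b, variant=variant)
        d, (lo, hi), label = cohens_d_ci(a, b, level=ci_level)
        reports.append(
            ComparisonReport(
                descriptor=col,
                n_a=len(a),
                n_b=len(b),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t=t,
                p_value=p,
                d=d,
                d_ci_low=lo,
                d_ci_high=hi,
                label=label,
            ).as_dict()
        )
    return pd.DataFrame(reports)
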