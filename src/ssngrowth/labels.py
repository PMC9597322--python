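"""Growth / non-growth labelling and univariate group comparison.

A nodule is labelled *growth* when its mass increases by at least 25%
within one year.  The relative mass increase over the actual inter-exam
interval is annualized linearly:

    y = ((M_t - M_{t-1}) / M_{t-1}) * (365 / dt_days)

and compared inclusively against the threshold (y >= 0.25 is growth).
The annualized rate y is also the regression target of the growth
prediction model; the loss-weighting cutoff used there (r = 0.1) is a
separate constant and is *not* the class threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import DAYS_PER_YEAR

__all__ = [
    "GROWTH_THRESHOLD",
    "annualized_mass_rate",
    "growth_label",
    "compare_groups",
]

#: mass must increase by at least this fraction per year to count as growth
GROWTH_THRESHOLD = 0.25


def annualized_mass_rate(prev_mass: float, curr_mass: float,
                         dt_days: float) -> float:
    """Relative mass increase rescaled linearly to a 365-day interval."""
    if prev_mass <= 0:
        raise ValueError("previous mass must be positive")
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    return (curr_mass - prev_mass) / prev_mass * (DAYS_PER_YEAR / dt_days)


def growth_label(y: float, threshold: float = GROWTH_THRESHOLD) -> bool:
    """True when the annualized mass rate meets the growth criterion."""
    if not np.isfinite(y):
        raise ValueError("annualized rate must be finite")
    return bool(y >= threshold)


def compare_groups(table: pd.DataFrame, by: str = "growth_label",
                   yates: bool = False) -> pd.DataFrame:
    """Univariate comparison of every column between two label groups.

    Continuous columns get median (Q1, Q3) per group and a two-sided
    Welch t-test; categorical (non-numeric or boolean) columns get
    per-level counts and a chi-square test on the contingency table
    (without continuity correction by default).
    """
    if by not in table.columns:
        raise KeyError(f"grouping column {by!r} not in table")
    levels = pd.unique(table[by])
    if len(levels) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    g0 = table[table[by] == levels[0]]
    g1 = table[table[by] == levels[1]]
    rows = []
    for col in table.columns:
        if col == by:
            continue
        s0, s1 = g0[col], g1[col]
        numeric = pd.api.types.is_numeric_dtype(table[col]) and \
            not pd.api.types.is_bool_dtype(table[col])
        if numeric:
            stat, p = _welch(s0.to_numpy(float), s1.to_numpy(float))
            rows.append({
                "variable": col, "kind": "continuous",
                f"{levels[0]}": _mqq(s0), f"{levels[1]}": _mqq(s1),
                "statistic": stat, "p_value": p,
            })
        else:
            ct = pd.crosstab(table[by], table[col])
            stat, p = chi_square(ct.to_numpy(), yates=yates)
            rows.append({
                "variable": col, "kind": "categorical",
                f"{levels[0]}": "/".join(str(v) for v in ct.loc[levels[0]]),
                f"{levels[1]}": "/".join(str(v) for v in ct.loc[levels[1]]),
                "statistic": stat, "p_value": p,
            })
    return pd.DataFrame(rows)


def _mqq(s: pd.Series) -> str:
    q1, med, q3 = np.percentile(s.to_numpy(float), [25, 50, 75])
    return f"{med:.4g} ({q1:.4g}, {q3:.4g})"


def _welch(a, b):
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) \
            and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chi_square(observed: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a contingency table."""
    observed = np.asarray(observed, float)
    if observed.min() < 0:
        raise ValueError("counts must be non-negative")
    res = stats.chi2_contingency(observed, correction=yates)
    return float(res.statistic), float(res.pvalue)
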