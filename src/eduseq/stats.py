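"""Shared group-comparison statistics: two-way ANOVA, Fisher's LSD, Tukey HSD.

The figure-legend statistics of the experiments this package quantifies are a
two-way fixed-effects ANOVA followed by either Fisher's Least Significant
Difference test (fiber rates) or Tukey's multiple-comparison test (fraction
data).  Fisher's LSD is implemented in its classical, unprotected form:
pairwise t-tests that reuse the pooled error mean square of the ANOVA.  Tukey
p-values come from the studentized-range distribution with the number of
groups as the range parameter.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "significance_tier",
    "anova_two_way",
    "lsd_pairwise",
    "tukey_pairwise",
]

_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    """Map a p-value to the star notation used in the figure legends."""
    if np.isnan(p):
        return "NA"
    for cutoff, stars in _TIERS:
        if p < cutoff:
            return stars
    return "ns"


def _group_stats(data: pd.DataFrame, response: str, by: list[str]):
    g = data.groupby(by, observed=True)[response]
    return g.mean(), g.count()


def anova_two_way(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> tuple[pd.DataFrame, float, int]:
    """Two-way fixed-effects ANOVA with interaction (type-II sums of squares).

    Returns ``(table, mse, df_resid)`` where ``mse`` is the pooled error mean
    square reused by the pairwise procedures.  If the design is degenerate —
    either factor has a single level or a cell is empty — the analysis falls
    back to a one-way ANOVA on the crossed grouping with a warning.
    """
    data = data[[response, factor_a, factor_b]].dropna()
    levels_a = data[factor_a].nunique()
    levels_b = data[factor_b].nunique()
    cells = data.groupby([factor_a, factor_b], observed=True)[response].count()
    degenerate = (
        levels_a < 2
        or levels_b < 2
        or len(cells) < levels_a * levels_b
        or (cells < 1).any()
    )
    if degenerate:
        warnings.warn(
            "degenerate two-way design (single-level factor or empty cell); "
            "falling back to one-way ANOVA on the crossed grouping",
            stacklevel=2,
        )
        data = data.assign(_cell=data[factor_a].astype(str) + ":" + data[factor_b].astype(str))
        model = ols(f"Q('{response}') ~ C(_cell)", data=data).fit()
        table = sm.stats.anova_lm(model, typ=1)
    else:
        model = ols(
            f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data
        ).fit()
        table = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_resid = int(model.df_resid)
    return table, mse, df_resid


def lsd_pairwise(
    data: pd.DataFrame,
    response: str,
    by: list[str],
    mse: float,
    df_resid: int,
) -> pd.DataFrame:
    """Fisher's LSD: unprotected pairwise t-tests on the pooled error MS.

    For groups i, j with means m_i, m_j and sizes n_i, n_j,

        t = (m_i - m_j) / sqrt(MSE * (1/n_i + 1/n_j))

    referred to a t distribution with the ANOVA residual degrees of freedom.
    """
    means, counts = _group_stats(data, response, by)
    rows = []
    for gi, gj in combinations(means.index, 2):
        diff = means[gi] - means[gj]
        se = np.sqrt(mse * (1.0 / counts[gi] + 1.0 / counts[gj]))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_resid))
        rows.append(
            {
                "group1": gi if isinstance(gi, str) else ":".join(map(str, gi)),
                "group2": gj if isinstance(gj, str) else ":".join(map(str, gj)),
                "diff": float(diff),
                "se": float(se),
                "t": float(t),
                "p": p,
                "tier": significance_tier(p),
            }
        )
    return pd.DataFrame(rows)


def tukey_pairwise(
    data: pd.DataFrame,
    response: str,
    by: list[str],
    mse: float,
    df_resid: int,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons on the pooled error MS.

    The studentized-range statistic ``q = |m_i - m_j| / sqrt(MSE/2 *
    (1/n_i + 1/n_j))`` is referred to the studentized-range distribution with
    range parameter equal to the number of groups, which controls the
    family-wise error rate across all pairs.
    """
    means, counts = _group_stats(data, response, by)
    k = len(means)
    rows = []
    for gi, gj in combinations(means.index, 2):
        diff = means[gi] - means[gj]
        se = np.sqrt(mse / 2.0 * (1.0 / counts[gi] + 1.0 / counts[gj]))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "group1": gi if isinstance(gi, str) else ":".join(map(str, gi)),
                "group2": gj if isinstance(gj, str) else ":".join(map(str, gj)),
                "diff": float(diff),
                "q": float(q),
                "p": p,
                "tier": significance_tier(p),
            }
        )
    return pd.DataFrame(rows)
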