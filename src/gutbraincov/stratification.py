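"""Dysbiosis stratification and group comparisons of cognition / mood.

Subjects with obesity are split at the median of the fitted microbial
balance: values above the obese-group median define the gut-dysbiosis
stratum, values at or below it the no-dysbiosis stratum (the tie rule
is configurable).  Cognitive and mood scores are then compared between
strata with a two-sample t test (pooled variance by default) or, with
covariates, an ANCOVA on the group indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["STRATA", "stratify_by_median", "compare_groups", "GroupComparison"]

STRATA = ("non-obese", "obese-no-dysbiosis", "obese-dysbiosis")


def stratify_by_median(
    pheno: pd.DataFrame,
    balance_column: str = "balance_value",
    ties_to: str = "no-dysbiosis",
) -> pd.DataFrame:
    """Assign obese subjects to dysbiosis strata by the obese-group median.

    The median is computed over obese subjects only; obese subjects with
    a balance strictly above it become ``obese-dysbiosis``, the rest
    ``obese-no-dysbiosis`` (``ties_to='dysbiosis'`` flips the boundary
    subjects).  Non-obese subjects are untouched.  Returns a copy with a
    ``stratum`` column; the median used is stored in
    ``df.attrs['balance_median']``.
    """
    if ties_to not in ("no-dysbiosis", "dysbiosis"):
        raise ValueError("ties_to must be 'no-dysbiosis' or 'dysbiosis'")
    out = pheno.copy()
    obese = out["obesity"].to_numpy() == "obese"
    if not obese.any():
        raise ValueError("no obese subjects to stratify")
    bal = out.loc[obese, balance_column].to_numpy(float)
    if np.any(~np.isfinite(bal)):
        raise ValueError("balance_value missing for some obese subjects")
    med = float(np.median(bal))
    if ties_to == "no-dysbiosis":
        dys = bal > med
    else:
        dys = bal >= med
    stratum = np.where(obese, "obese-no-dysbiosis", "non-obese")
    stratum[np.flatnonzero(obese)[dys]] = "obese-dysbiosis"
    out["stratum"] = stratum
    out.attrs["balance_median"] = med
    return out


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p: float
    df: float
    means: dict        # group -> (mean, sd, n)
    variable: str
    groups: tuple[str, str]
    adjusted_for: tuple[str, ...] = ()


def compare_groups(
    pheno: pd.DataFrame,
    variable: str,
    groups: tuple[str, str],
    group_column: str = "stratum",
    covariates: list[str] | None = None,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample comparison of ``variable`` between two strata.

    Without covariates: independent-samples t test (pooled variance by
    default, Welch with ``equal_var=False``).  With covariates: ANCOVA —
    an OLS of the variable on the group indicator plus covariates, with
    the reported t/p from the group coefficient.  The sign convention is
    ``groups[1] - groups[0]``.
    """
    sel = pheno[pheno[group_column].isin(groups)].dropna(subset=[variable])
    a = sel.loc[sel[group_column] == groups[0], variable].to_numpy(float)
    b = sel.loc[sel[group_column] == groups[1], variable].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError(f"{variable!r} is constant in both groups")
    means = {
        g: (float(v.mean()), float(v.std(ddof=1)), len(v))
        for g, v in zip(groups, (a, b))
    }
    if not covariates:
        res = stats.ttest_ind(b, a, equal_var=equal_var)
        df = len(a) + len(b) - 2 if equal_var else float(res.df)
        return GroupComparison(float(res.statistic), float(res.pvalue), float(df),
                               means, variable, tuple(groups))
    ind = (sel[group_column] == groups[1]).astype(float).to_numpy()
    X = sm.add_constant(np.column_stack([ind, sel[covariates].to_numpy(float)]))
    fit = sm.OLS(sel[variable].to_numpy(float), X).fit()
    return GroupComparison(float(fit.tvalues[1]), float(fit.pvalues[1]),
                           float(fit.df_resid), means, variable, tuple(groups),
                           tuple(covariates))
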