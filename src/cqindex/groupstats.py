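"""Group-comparison machinery: two-way factorial ANOVA (Type II sums of
squares), Benjamini–Hochberg adjustment, per-stratum Welch post-hoc
contrasts, and percent-change reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_DEGENERATE_RTOL = 1e-9


@dataclass
class AnovaResult:
    """Two-way ANOVA table with BH-adjusted term p-values."""

    terms: pd.DataFrame  # columns: term, F, p, p_adj, ss, df
    factors: dict        # factor name -> number of levels
    n_obs: int
    degenerate: bool = False


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    adjust_terms: bool = True,
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction, Type II sums of squares.

    Type II handles unbalanced designs (unequal replicate counts) and
    reduces to the classical balanced decomposition otherwise.  Every
    factor-level cell must be non-empty.  When within-cell variance is
    exactly zero the F ratios are degenerate: terms with zero sum of
    squares report F = 0, terms with positive sum of squares F = inf, and
    the result is flagged.
    """
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [data[factor_a].unique(), data[factor_b].unique()], names=[factor_a, factor_b]
    )
    empty = full.difference(counts.index)
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty)}")

    model = ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    tss = float(((data[response] - data[response].mean()) ** 2).sum())
    degenerate = resid_ss <= _DEGENERATE_RTOL * max(tss, 1.0)
    names = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    rows = []
    for raw, term in names.items():
        ss = float(table.loc[raw, "sum_sq"])
        df = float(table.loc[raw, "df"])
        if degenerate:
            zero = ss <= _DEGENERATE_RTOL * max(tss, 1.0)
            F = 0.0 if zero else np.inf
            p = 1.0 if zero else 0.0
        else:
            F = float(table.loc[raw, "F"])
            p = float(table.loc[raw, "PR(>F)"])
        rows.append({"term": term, "ss": ss, "df": df, "F": F, "p": p})
    terms = pd.DataFrame(rows)
    terms["p_adj"] = bh_adjust(terms["p"]) if adjust_terms else terms["p"]
    return AnovaResult(
        terms=terms,
        factors={factor_a: data[factor_a].nunique(), factor_b: data[factor_b].nunique()},
        n_obs=len(data),
        degenerate=degenerate,
    )


def posthoc_by_stratum(
    data: pd.DataFrame,
    response: str,
    arm_factor: str,
    stratum_factor: str,
    arm_order: tuple | None = None,
) -> pd.DataFrame:
    """Per-stratum Welch two-sample contrasts with BH across strata.

    Within each level of ``stratum_factor`` (e.g. each day) the two arms
    are compared by Welch's unequal-variance t-test; the family of
    p-values across strata is BH-adjusted.  Strata that do not contain
    exactly two arms are skipped with a warning.
    """
    rows = []
    for stratum, g in data.groupby(stratum_factor, sort=True):
        arms = sorted(g[arm_factor].unique()) if arm_order is None else list(arm_order)
        present = [a for a in arms if (g[arm_factor] == a).any()]
        if len(present) != 2:
            logger.warning("stratum %r has %d arm(s); skipped", stratum, len(present))
            continue
        a, b = present
        va = g.loc[g[arm_factor] == a, response].dropna().to_numpy(float)
        vb = g.loc[g[arm_factor] == b, response].dropna().to_numpy(float)
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append(
            {
                "stratum": stratum,
                "contrast": f"{a} - {b}",
                "estimate": float(va.mean() - vb.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["stratum", "contrast", "estimate", "t", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"])
    else:
        out["p_adj"] = []
    return out


def percent_change(
    expr: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    gene: str,
    div: int,
    arm_col: str = "treatment",
) -> float:
    """Percent change of arm_a over arm_b for one gene at one day:
    100 × (mean_a / mean_b − 1)."""
    sub = expr[(expr["gene"] == gene) & (expr["div"] == div)]
    means = {}
    for arm in (arm_a, arm_b):
        v = sub.loc[sub[arm_col] == arm, "value"].dropna()
        if v.empty:
            raise ValueError(f"no measurements for {gene} at DIV{div} in arm {arm!r}")
        means[arm] = v.mean()
    if means[arm_b] == 0:
        raise ValueError(f"zero denominator group mean for {gene} at DIV{div}")
    return float(100.0 * (means[arm_a] / means[arm_b] - 1.0))
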