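"""Independent brute-force oracles for every statistic the package computes.

Each function here works from the explicit textbook definition — raw-sum
formulas, dummy design matrices solved by least squares, the hand-executed
Benjamini–Hochberg step-up — and never calls the package under test.
Distribution tail functions (t, F) come from scipy.stats; everything that
constitutes the statistic is spelled out.
"""

import numpy as np
import pandas as pd
from scipy import stats


def pearson_r_p(x, y):
    """Pearson r from the raw-sum formula; two-sided p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(r), float(p)


def ols_slope(x, y):
    """Slope from the 2x2 normal equations solved explicitly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    return float(np.linalg.solve(A, b)[1])


def welch_t_p(a, b):
    """Welch's unequal-variance t and two-sided p, textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def bh_stepup(p):
    """BH step-up by the definition: sort, p_(i)·m/i, enforce monotone from
    the top rank down, cap at 1, restore input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def _dummies(values):
    levels = pd.unique(pd.Series(values).sort_values())
    return np.column_stack([(np.asarray(values) == lv).astype(float)
                            for lv in levels[1:]])


def _sse(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_interaction_F(day, arm, y):
    """F-test of the day×arm term from nested design-matrix least squares."""
    day = np.asarray(day, float)
    y = np.asarray(y, float)
    g = _dummies(arm)
    ones = np.ones_like(day)[:, None]
    X_red = np.hstack([ones, day[:, None], g])
    X_full = np.hstack([X_red, day[:, None] * g])
    sse_full, sse_red = _sse(X_full, y), _sse(X_red, y)
    df_resid = len(y) - X_full.shape[1]
    F = (sse_red - sse_full) / (sse_full / df_resid)
    return float(F), float(stats.f.sf(F, 1, df_resid))


def two_way_anova_typ2(data, response, fa, fb):
    """Type II F and p for both main effects and the interaction, from
    residual-SS comparisons of nested dummy-coded models."""
    y = data[response].to_numpy(float)
    A = _dummies(data[fa])
    B = _dummies(data[fb])
    AB = np.column_stack([A[:, i] * B[:, j]
                          for i in range(A.shape[1]) for j in range(B.shape[1])])
    ones = np.ones((len(y), 1))
    sse_ab = _sse(np.hstack([ones, A, B]), y)
    sse_a = _sse(np.hstack([ones, A]), y)
    sse_b = _sse(np.hstack([ones, B]), y)
    X_full = np.hstack([ones, A, B, AB])
    sse_full = _sse(X_full, y)
    df_resid = len(y) - X_full.shape[1]
    mse = sse_full / df_resid
    out = {}
    for term, ss, df in [
        (fa, sse_b - sse_ab, A.shape[1]),
        (fb, sse_a - sse_ab, B.shape[1]),
        (f"{fa}:{fb}", sse_ab - sse_full, AB.shape[1]),
    ]:
        F = (ss / df) / mse
        out[term] = (float(F), float(stats.f.sf(F, df, df_resid)))
    return out
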