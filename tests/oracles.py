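"""Hand-coded statistical oracles, independent of the package implementation.

Everything here is written from first principles (explicit sums, normal
equations, textbook ANOVA decompositions) so package routines can be checked
against a second derivation rather than against themselves.
"""

from __future__ import annotations

import math

import numpy as np


def ols_line(x, y) -> tuple[float, float]:
    """Slope/intercept of y on x via the explicit normal-equation sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc * xc).sum() * (yc * yc).sum()))


def anova_oneway(samples) -> tuple[float, int, int]:
    """One-way ANOVA F via the textbook SS decomposition.

    Returns (F, df_between, df_within).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(all_vals) - len(samples)
    return float((ss_between / df_b) / (ss_within / df_w)), df_b, df_w


def levene_mean_centered(x, y) -> float:
    """Classic Levene F: one-way ANOVA on |deviation from group mean|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f, _, _ = anova_oneway([np.abs(x - x.mean()), np.abs(y - y.mean())])
    return f


def cohens_d(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


def ancova_group_f(deltas, ages, groups) -> tuple[float, int, int]:
    """Partial F for the group factor in delta ~ age + group, by explicit
    least squares on the two nested design matrices."""
    d = np.asarray(deltas, dtype=float)
    a = np.asarray(ages, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups))
    n = len(d)

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        resid = d - X @ beta
        return float(resid @ resid), X.shape[1]

    X_red = np.column_stack([np.ones(n), a])
    cols = [np.ones(n), a] + [(groups == lev).astype(float) for lev in levels[1:]]
    X_full = np.column_stack(cols)
    ssr_red, _ = ssr(X_red)
    ssr_full, p_full = ssr(X_full)
    df_b = len(levels) - 1
    df_w = n - p_full
    f = ((ssr_red - ssr_full) / df_b) / (ssr_full / df_w)
    return float(f), df_b, df_w
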