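"""Accuracy metrics and statistical comparisons for brain-age predictions.

Conventions used throughout:

* R-squared is the *squared Pearson correlation* between chronological and
  predicted age, not 1 - SSE/SST.  This makes it invariant under affine
  transformations of the predictions — which is exactly why a pure
  rescaling adjustment leaves R-squared unchanged while it can degrade MAE.
* Variance-equality testing uses the classic Levene statistic (one-way
  ANOVA on absolute deviations from the group *means*); a median-centered
  Brown-Forsythe variant is available via ``center="median"``.
* Bootstrap intervals are seeded percentile intervals (not BCa), and the
  paired bootstrap comparison of two methods' MAEs resamples subjects with
  replacement so that both methods see the same resampled subjects.
* All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InsufficientDataError, PairingError

__all__ = [
    "AccuracyReport",
    "AnovaTukeyResult",
    "accuracy_metrics",
    "bootstrap_mae_comparison",
    "levene_variance_test",
    "group_anova_tukey",
    "cohens_d",
    "mean_delta_ci",
]


@dataclass(frozen=True)
class AccuracyReport:
    """Prediction-accuracy summary: MAE/RMSE/R2 (years, years,
    dimensionless), delta-age Pearson correlation with two-sided p, and the
    mean delta with a seeded percentile-bootstrap 95% CI."""

    mae: float
    rmse: float
    r2: float
    delta_age_r: float
    delta_age_p: float
    mean_delta: float
    mean_delta_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["mean_delta_ci"] = list(self.mean_delta_ci)
        return d


@dataclass(frozen=True)
class AnovaTukeyResult:
    """One-way ANOVA over groups with Tukey HSD post-hoc pairwise tests."""

    anova_f: float
    anova_df: tuple[int, int]  # (between, within)
    anova_p: float
    tukey: pd.DataFrame = field(repr=False)  # group1, group2, meandiff, p_adj, reject

    def to_dict(self) -> dict:
        return {
            "anova_f": self.anova_f,
            "anova_df": list(self.anova_df),
            "anova_p": self.anova_p,
            "tukey": self.tukey.to_dict(orient="records"),
        }


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired vectors must share one length; got {a.shape} vs {b.shape}")
    return a, b


def accuracy_metrics(
    ages: Sequence[float],
    predicted: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> AccuracyReport:
    """Compute the standard accuracy panel for one prediction arm."""
    age, pred = _paired(ages, predicted)
    if len(age) < 3:
        raise InsufficientDataError("accuracy metrics need at least 3 subjects")
    delta = pred - age
    mae = float(np.mean(np.abs(delta)))
    rmse = float(np.sqrt(np.mean(delta**2)))
    r2 = float(stats.pearsonr(age, pred).statistic ** 2) if np.ptp(pred) > 0 else 0.0
    if np.ptp(delta) > 0:
        dr = stats.pearsonr(age, delta)
        delta_age_r, delta_age_p = float(dr.statistic), float(dr.pvalue)
    else:  # constant delta: no age trend by construction
        delta_age_r, delta_age_p = 0.0, 1.0
    mean_delta, ci = mean_delta_ci(delta, n_boot=n_boot, seed=seed)
    return AccuracyReport(
        mae=mae,
        rmse=rmse,
        r2=r2,
        delta_age_r=delta_age_r,
        delta_age_p=delta_age_p,
        mean_delta=mean_delta,
        mean_delta_ci=ci,
        n=len(age),
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_mae_comparison(
    abs_errors_a: Sequence[float],
    abs_errors_b: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Paired bootstrap comparison of two methods' MAEs on the same subjects.

    Subjects are resampled with replacement; each resample yields both
    methods' MAEs and their difference.  Returns the two-sided p-value
    ``2 * min(P(diff <= 0), P(diff >= 0))`` with a ``+1/(n_boot+1)``
    continuity guard (so p is never exactly 0), and the 95% percentile CI
    of each method's MAE.
    """
    a, b = _paired(abs_errors_a, abs_errors_b)
    if n_boot < 100:
        raise InsufficientDataError("n_boot must be >= 100")
    n = len(a)
    if n == 0:
        raise InsufficientDataError("empty error vectors")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    mae_a = np.abs(a)[idx].mean(axis=1)
    mae_b = np.abs(b)[idx].mean(axis=1)
    diff = mae_a - mae_b
    p_low = (np.count_nonzero(diff <= 0) + 1) / (n_boot + 1)
    p_high = (np.count_nonzero(diff >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    ci_a = tuple(float(q) for q in np.percentile(mae_a, [2.5, 97.5]))
    ci_b = tuple(float(q) for q in np.percentile(mae_b, [2.5, 97.5]))
    return float(p), ci_a, ci_b


def levene_variance_test(
    x: Sequence[float],
    y: Sequence[float],
    center: str = "mean",
) -> tuple[float, float]:
    """Levene's test of variance equality between two samples.

    ``center="mean"`` is the classic Levene statistic; ``"median"`` gives
    the Brown-Forsythe variant.  Returns (F, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    f, p = stats.levene(x, y, center=center)
    return float(f), float(p)


def group_anova_tukey(
    deltas: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA of deltas by group plus Tukey HSD pairwise table.

    Degrees of freedom are (groups - 1, n - groups); the Tukey table has
    one row per unordered group pair with the family-wise adjusted p.
    """
    d = np.asarray(deltas, dtype=float)
    g = pd.Series(groups, dtype="object")
    counts = g.value_counts()
    if len(counts) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise InsufficientDataError("every group needs at least 2 observations")
    samples = [d[(g == lev).to_numpy()] for lev in sorted(counts.index)]
    f, p = stats.f_oneway(*samples)
    df_between = len(samples) - 1
    df_within = len(d) - len(samples)
    tk = pairwise_tukeyhsd(d, g.to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]].rename(
        columns={"p-adj": "p_adj"}
    )
    # recompute adjusted p at full precision (the summary rounds)
    tukey["meandiff"] = tk.meandiffs
    tukey["p_adj"] = tk.pvalues
    tukey["reject"] = tk.reject
    return AnovaTukeyResult(
        anova_f=float(f),
        anova_df=(df_between, df_within),
        anova_p=float(p),
        tukey=tukey,
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD, with
    (n-1)-weighted pooling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise InsufficientDataError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def mean_delta_ci(
    deltas: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Sample mean of the deltas with a seeded percentile-bootstrap 95% CI."""
    d = np.asarray(deltas, dtype=float)
    if len(d) < 3:
        raise InsufficientDataError("mean-delta CI needs at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot_means = d[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(d.mean()), (float(lo), float(hi))
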