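"""Bias-adjustment schemes for brain-age predictions.

Brain-age regressors trained on noisy features systematically overestimate
young subjects and underestimate old ones (regression dilution), so the
delta (predicted minus chronological age) trends negatively with age.  Three
remedies are implemented:

* **Offset scheme** (``proposed``): regress the training deltas on
  chronological age (slope alpha, intercept beta); for a subject of age
  Omega, subtract the offset ``alpha * Omega + beta`` from the raw
  prediction.  Yields a per-subject bias-free brain age.
* **Rescaling scheme** (``cole``): regress the raw training predictions on
  chronological age; rescale each prediction as
  ``(predicted_raw - beta) / alpha``.  Also removes the age trend, but
  dividing by an attenuated slope (|alpha| < 1) inflates the residual
  variance by 1/alpha**2.
* **Covariate method** (:func:`le_group_test`): compare groups on delta in a
  linear model that includes chronological age as a covariate.  A
  group-level procedure only — it yields no per-subject corrected value.

Both per-subject schemes are fitted on a training prediction set (by
default out-of-fold cross-validated predictions, recorded in
``fit_provenance``) and then applied, frozen, to independent test sets;
refitting on test data would leak the test ages' bias into the correction.
On the fitting set itself, ordinary-least-squares residual orthogonality
makes the adjusted delta exactly uncorrelated with age under either scheme.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    SchemeMismatchError,
    UnstableAdjustmentError,
)
from .io import validate_predictions

__all__ = [
    "OffsetModel",
    "LeGroupTestResult",
    "fit_offset_model",
    "apply_proposed",
    "apply_cole",
    "apply_scheme",
    "le_group_test",
    "DEFAULT_SLOPE_FLOOR",
]

SCHEMES = ("proposed", "cole")

#: Minimum |slope| accepted by the rescaling scheme; below this the division
#: in the adjustment would blow up variance without bound.
DEFAULT_SLOPE_FLOOR = 0.05


@dataclass(frozen=True)
class OffsetModel:
    """Fitted slope/intercept of a bias line, tagged with its scheme.

    For ``scheme="proposed"`` the line is delta-on-age; for
    ``scheme="cole"`` it is predicted-on-age.  ``r`` is the Pearson
    correlation of the fitted relation (diagnostic only).
    """

    scheme: str
    slope: float
    intercept: float
    n_train: int
    fit_provenance: str
    r: float = float("nan")

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise SchemeMismatchError(f"unknown scheme {self.scheme!r}")
        if self.n_train < 2:
            raise DegenerateDataError("offset model requires n_train >= 2")

    def usable_for_adjustment(self, slope_floor: float = DEFAULT_SLOPE_FLOOR) -> bool:
        """Whether the model can safely be applied.  The rescaling scheme
        divides by the slope, so it needs |slope| >= slope_floor."""
        if self.scheme == "cole":
            return abs(self.slope) >= slope_floor
        return True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "OffsetModel":
        text = str(source)
        try:
            if isinstance(source, Path) or Path(text).exists():
                text = Path(text).read_text(encoding="utf-8")
        except OSError:
            pass  # not a path; treat as a JSON payload
        return cls(**json.loads(text))


def fit_offset_model(predictions: pd.DataFrame, scheme: str) -> OffsetModel:
    """OLS fit of the scheme's bias line on a prediction set.

    ``proposed`` regresses delta on age; ``cole`` regresses predicted_raw
    on age.  Requires at least two distinct ages.
    """
    if scheme not in SCHEMES:
        raise SchemeMismatchError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    validate_predictions(predictions)
    age = predictions["age"].to_numpy(dtype=float)
    if len(age) < 2 or np.ptp(age) == 0:
        raise DegenerateDataError("offset fit needs >= 2 distinct ages")
    y = predictions["delta" if scheme == "proposed" else "predicted_raw"].to_numpy(
        dtype=float
    )
    fit = stats.linregress(age, y)
    provs = predictions["provenance"].unique()
    return OffsetModel(
        scheme=scheme,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_train=len(age),
        fit_provenance=provs[0] if len(provs) == 1 else "mixed",
        r=float(fit.rvalue),
    )


def _adjusted_frame(
    predictions: pd.DataFrame, predicted_adjusted: np.ndarray, scheme: str
) -> pd.DataFrame:
    out = predictions.copy()
    out["predicted_adjusted"] = predicted_adjusted
    out["delta_adjusted"] = predicted_adjusted - out["age"].to_numpy(dtype=float)
    out["scheme"] = scheme
    return out


def apply_proposed(predictions: pd.DataFrame, model: OffsetModel) -> pd.DataFrame:
    """Subtract the per-subject offset ``slope * age + intercept`` from the
    raw prediction."""
    if model.scheme != "proposed":
        raise SchemeMismatchError(
            f"apply_proposed requires a 'proposed' model, got {model.scheme!r}"
        )
    validate_predictions(predictions)
    age = predictions["age"].to_numpy(dtype=float)
    offset = model.slope * age + model.intercept
    adjusted = predictions["predicted_raw"].to_numpy(dtype=float) - offset
    return _adjusted_frame(predictions, adjusted, "proposed")


def apply_cole(
    predictions: pd.DataFrame,
    model: OffsetModel,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> pd.DataFrame:
    """Rescale raw predictions as ``(predicted_raw - intercept) / slope``."""
    if model.scheme != "cole":
        raise SchemeMismatchError(
            f"apply_cole requires a 'cole' model, got {model.scheme!r}"
        )
    if not model.usable_for_adjustment(slope_floor):
        raise UnstableAdjustmentError(
            f"|slope| = {abs(model.slope):.4g} is below the floor {slope_floor}; "
            "rescaling would inflate variance without bound"
        )
    validate_predictions(predictions)
    adjusted = (
        predictions["predicted_raw"].to_numpy(dtype=float) - model.intercept
    ) / model.slope
    return _adjusted_frame(predictions, adjusted, "cole")


def apply_scheme(
    predictions: pd.DataFrame,
    model: OffsetModel | None,
    scheme: str,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> pd.DataFrame:
    """Dispatch on scheme name; ``"none"`` passes raw predictions through
    (adjusted columns mirror the raw ones)."""
    if scheme == "none":
        raw = validate_predictions(predictions)["predicted_raw"].to_numpy(dtype=float)
        return _adjusted_frame(predictions, raw, "none")
    if model is None:
        raise SchemeMismatchError(f"scheme {scheme!r} requires a fitted OffsetModel")
    if scheme == "proposed":
        return apply_proposed(predictions, model)
    if scheme == "cole":
        return apply_cole(predictions, model, slope_floor)
    raise SchemeMismatchError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class LeGroupTestResult:
    """Covariate-adjusted group comparison of brain-age deltas.

    F statistic, degrees of freedom and p-value for the group factor in the
    linear model ``delta ~ group + age``, plus group means evaluated at the
    pooled mean age.  Group-level only: no per-subject corrected values.
    """

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    adjusted_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "adjusted_means": dict(self.adjusted_means),
        }


def le_group_test(
    deltas: Sequence[float],
    ages: Sequence[float],
    groups: Sequence[str],
) -> LeGroupTestResult:
    """ANCOVA-style group comparison: delta on group indicators plus
    chronological age as covariate.

    Requires at least two groups with at least two subjects each.  Reports
    the partial F test of the group factor and covariate-adjusted group
    means (group intercepts evaluated at the pooled mean age).
    """
    d = np.asarray(deltas, dtype=float)
    a = np.asarray(ages, dtype=float)
    g = pd.Series(groups, dtype="object")
    if not (len(d) == len(a) == len(g)):
        raise InsufficientDataError("deltas, ages and groups must share one length")
    counts = g.value_counts()
    if len(counts) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"groups with < 2 subjects: {small}")

    levels = sorted(counts.index)
    dummies = pd.get_dummies(pd.Categorical(g, categories=levels), drop_first=True)
    X_full = sm.add_constant(
        pd.DataFrame({"age": a}).join(dummies.set_axis(g.index)).astype(float)
    )
    full = sm.OLS(d, X_full).fit()
    reduced = sm.OLS(d, sm.add_constant(pd.DataFrame({"age": a}).astype(float))).fit()

    df_between = len(levels) - 1
    df_within = int(full.df_resid)
    num = (reduced.ssr - full.ssr) / df_between
    den = full.ssr / df_within
    f_stat = float(num / den)
    p_value = float(stats.f.sf(f_stat, df_between, df_within))

    mean_age = float(a.mean())
    base = float(full.params["const"] + full.params["age"] * mean_age)
    adjusted_means = {levels[0]: base}
    for lev in levels[1:]:
        adjusted_means[lev] = base + float(full.params[lev])
    return LeGroupTestResult(
        f_stat=f_stat,
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        adjusted_means=adjusted_means,
    )
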