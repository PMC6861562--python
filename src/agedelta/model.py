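"""Brain-age regression: fit, predict, and cross-validated out-of-fold
predictions.

Chronological age is the regression target and the regional features are the
predictors.  The primary backend is epsilon-insensitive support-vector
regression with a linear kernel and the standard defaults (C = 1.0,
epsilon = 0.1), fitted on features standardized by training-set mean/SD;
an ordinary-least-squares backend is available so downstream
bias-adjustment tests do not depend on SVR specifics.  Standardization
parameters are learned on the training set only and stored in the fitted
handle.

Out-of-fold prediction partitions subjects into k seeded random folds of
near-equal size (differing by at most one); each fold is predicted by a
model fitted on the remaining folds, so every training subject receives
exactly one prediction from a model that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ConfigurationError, DegenerateDataError, ShapeError
from .io import PREDICTION_COLUMNS, feature_columns, validate_cohort

__all__ = ["FittedRegressor", "fit_regressor", "predict", "cross_val_predict"]

BACKENDS = ("svr", "ols")

SVR_PARAMS = {"kernel": "linear", "C": 1.0, "epsilon": 0.1}


def _make_estimator(backend: str) -> Pipeline:
    if backend == "svr":
        reg = SVR(**SVR_PARAMS)
    elif backend == "ols":
        reg = LinearRegression()
    else:
        raise ConfigurationError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
    return Pipeline([("scale", StandardScaler()), ("reg", reg)])


@dataclass
class FittedRegressor:
    """Handle to a fitted brain-age regressor.

    Holds the sklearn pipeline (standardizer + regressor), the feature
    names it was trained on, and the training standardization parameters.
    """

    backend: str
    pipeline: Pipeline
    feature_names: list[str] = field(repr=False)

    @property
    def feature_count(self) -> int:
        return len(self.feature_names)

    @property
    def center(self) -> np.ndarray:
        """Per-feature training means used for standardization."""
        return self.pipeline.named_steps["scale"].mean_

    @property
    def scale(self) -> np.ndarray:
        """Per-feature training SDs used for standardization."""
        return self.pipeline.named_steps["scale"].scale_

    def metadata(self) -> dict[str, Any]:
        """JSON-serializable description of backend, hyperparameters and
        standardization, for reproducibility alongside saved outputs."""
        hyper = dict(SVR_PARAMS) if self.backend == "svr" else {}
        return {
            "backend": self.backend,
            "hyperparameters": hyper,
            "feature_names": list(self.feature_names),
            "standardization": {
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
            },
        }


def _design(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    validate_cohort(cohort)
    feats = feature_columns(cohort)
    if not feats:
        raise DegenerateDataError("cohort has no feature columns (feat_*)")
    X = cohort[feats].to_numpy(dtype=float)
    y = cohort["age"].to_numpy(dtype=float)
    return X, y, feats


def fit_regressor(cohort: pd.DataFrame, backend: str = "svr") -> FittedRegressor:
    """Fit a brain-age regressor on a cohort table.

    Requires at least two subjects, a non-constant age column, and no
    missing feature values.
    """
    X, y, feats = _design(cohort)
    if len(y) < 2:
        raise DegenerateDataError("need at least 2 subjects to fit a regressor")
    if np.ptp(y) == 0:
        raise DegenerateDataError("age column is constant; regression target is degenerate")
    pipe = _make_estimator(backend)
    pipe.fit(X, y)
    return FittedRegressor(backend=backend, pipeline=pipe, feature_names=feats)


def predict(
    model: FittedRegressor,
    cohort: pd.DataFrame,
    provenance: str = "independent_test",
) -> pd.DataFrame:
    """Predict brain age for a cohort; returns a prediction-schema frame.

    An empty cohort yields an empty prediction set with the right columns.
    """
    validate_cohort(cohort)
    feats = feature_columns(cohort)
    if feats != model.feature_names:
        raise ShapeError(
            f"cohort features {len(feats)} do not match model features "
            f"{model.feature_count}"
        )
    if len(cohort) == 0:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    X = cohort[feats].to_numpy(dtype=float)
    predicted = model.pipeline.predict(X)
    ages = cohort["age"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "age": ages,
            "group": cohort["group"].to_numpy(),
            "predicted_raw": predicted,
            "delta": predicted - ages,
            "provenance": provenance,
        }
    )


def fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition of ``n`` subjects into ``k`` folds whose
    sizes differ by at most one.  Returns the fold index per subject."""
    if not 2 <= k <= n:
        raise ConfigurationError(f"k must satisfy 2 <= k <= n; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, k)):
        folds[idx] = f
    return folds


def cross_val_predict(
    cohort: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    backend: str = "svr",
) -> pd.DataFrame:
    """Out-of-fold predictions for every subject via k-fold CV (default
    k = 10).  Each subject appears exactly once in the output, predicted by
    a model fitted (including standardization) on the other k-1 folds.
    """
    X, y, feats = _design(cohort)
    n = len(cohort)
    folds = fold_assignments(n, int(k), seed)
    predicted = np.empty(n, dtype=float)
    for f in range(int(k)):
        test_mask = folds == f
        train = cohort.loc[~test_mask]
        fold_model = fit_regressor(train, backend=backend)
        predicted[test_mask] = fold_model.pipeline.predict(X[test_mask])
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "age": y,
            "group": cohort["group"].to_numpy(),
            "predicted_raw": predicted,
            "delta": predicted - y,
            "provenance": "cv_out_of_fold",
        }
    )
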