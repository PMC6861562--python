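"""Tabular schemas and CSV/JSON/YAML serialization.

Two table schemas are used throughout the package:

* **cohort** — one row per subject: ``subject_id, age, group, feat_0001, ...``
* **predictions** — one row per subject: ``subject_id, age, group,
  predicted_raw, delta, provenance`` and, after adjustment, additionally
  ``predicted_adjusted, delta_adjusted, scheme``.

Ages and predictions are in years; features are unitless regional values.
All files are UTF-8 CSV with '.' as the decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import ConfigurationError

COHORT_BASE_COLUMNS = ["subject_id", "age", "group"]
PREDICTION_COLUMNS = [
    "subject_id",
    "age",
    "group",
    "predicted_raw",
    "delta",
    "provenance",
]
ADJUSTED_COLUMNS = PREDICTION_COLUMNS + [
    "predicted_adjusted",
    "delta_adjusted",
    "scheme",
]

PROVENANCES = ("cv_out_of_fold", "independent_test", "in_sample")


def feature_columns(cohort: pd.DataFrame) -> list[str]:
    """Return the feature column names of a cohort table, in order."""
    return [c for c in cohort.columns if c.startswith("feat_")]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort schema; returns the frame unchanged on success."""
    missing = [c for c in COHORT_BASE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        raise ConfigurationError("cohort subject_id values must be unique")
    feats = feature_columns(cohort)
    if feats and cohort[feats].isna().any().any():
        raise ConfigurationError("cohort feature values must not be missing")
    return cohort


def validate_predictions(pred: pd.DataFrame, *, adjusted: bool = False) -> pd.DataFrame:
    cols = ADJUSTED_COLUMNS if adjusted else PREDICTION_COLUMNS
    missing = [c for c in cols if c not in pred.columns]
    if missing:
        raise ConfigurationError(f"prediction table missing columns: {missing}")
    bad = set(pred["provenance"].unique()) - set(PROVENANCES)
    if bad:
        raise ConfigurationError(f"unknown provenance values: {sorted(bad)}")
    return pred


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, dtype={"subject_id": str}))


def write_predictions_csv(pred: pd.DataFrame, path: str | Path) -> None:
    pred.to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_predictions(df, adjusted="predicted_adjusted" in df.columns)


def read_yaml(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, stable float repr."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
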