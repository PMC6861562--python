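"""End-to-end experiment orchestration.

Runs the full evaluation design at synthetic scale: generate a cohort,
split the cognitively normal (CN) group 90/10 into training and test,
obtain out-of-fold predictions by 10-fold CV on the training set, fit both
offset models (delta-on-age and predicted-on-age) on those CV predictions,
refit the final regressor on the whole training set, predict the CN test
set and the clinical (MCI, AD) groups, apply each adjustment arm
(none / proposed / cole), and evaluate everything: per-arm accuracy,
delta-age correlations, pairwise variance tests between arms, paired
bootstrap MAE comparisons, ANOVA + Tukey + Cohen's d across groups per
arm, and the age-covariate group test on raw deltas.

Determinism: one master seed derives every stage seed by fixed documented
offsets (see ``STAGE_SEED_OFFSETS``), so a stage can be re-run in
isolation and two runs with the same master seed produce byte-identical
bundles.  Leakage guard: both offset models are fitted — and, when an
output directory is given, serialized — before any test-set prediction is
computed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import adjust, evaluation, model, synthetic
from .errors import AgeDeltaError, ConfigurationError
from .io import write_json, write_predictions_csv

__all__ = [
    "ExperimentConfig",
    "STAGE_SEED_OFFSETS",
    "stage_seed",
    "run_experiment",
    "save_bundle",
    "reproduce_figures",
]

logger = logging.getLogger("agedelta.pipeline")

#: Documented master-seed -> stage-seed derivation: stage seed =
#: (master_seed + offset) mod 2**31.
STAGE_SEED_OFFSETS: dict[str, int] = {
    "generator": 1,
    "split": 2,
    "folds": 3,
    "bootstrap": 4,
}

VALID_SCHEMES = ("none", "proposed", "cole")


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment configuration.

    ``generator`` defines the synthetic cohort (its seed field is
    overridden by the derived generator stage seed); ``train_fraction`` of
    the CN group is used for training (default 0.9); ``schemes`` is the
    non-empty subset of {none, proposed, cole} to evaluate.
    """

    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    train_fraction: float = 0.9
    k_folds: int = 10
    backend: str = "svr"
    schemes: tuple[str, ...] = ("none", "proposed", "cole")
    n_boot: int = 1000
    seed: int = 0
    cole_slope_floor: float = adjust.DEFAULT_SLOPE_FLOOR
    control_group: str = "CN"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if not self.schemes:
            raise ConfigurationError("schemes must be a non-empty subset of "
                                     f"{VALID_SCHEMES}")
        bad = set(self.schemes) - set(VALID_SCHEMES)
        if bad:
            raise ConfigurationError(f"unknown schemes: {sorted(bad)}")
        if self.control_group not in self.generator.n_per_group:
            raise ConfigurationError(
                f"control_group {self.control_group!r} absent from generator groups"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        known = set(cls.__dataclass_fields__) - {"generator"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown experiment config keys: {sorted(unknown)}")
        return cls(generator=synthetic.GeneratorConfig.from_dict(gen), **d)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self.__dataclass_fields__}
        out["generator"] = self.generator.to_dict()
        out["schemes"] = list(self.schemes)
        return out


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha1(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:12]


def _log_stage(stage: str, seed: int | None, df: pd.DataFrame, t0: float) -> None:
    logger.info(
        "stage=%s seed=%s rows=%d hash=%s elapsed=%.2fs",
        stage, seed, len(df), _hash_frame(df), time.perf_counter() - t0,
    )


def split_cohort(
    cohort: pd.DataFrame,
    control_group: str,
    train_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint-and-exhaustive split of the control group into
    training and test subsets; clinical groups are untouched."""
    cn = cohort[cohort["group"] == control_group]
    if len(cn) < 2:
        raise ConfigurationError(f"control group {control_group!r} too small to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cn))
    n_train = int(round(train_fraction * len(cn)))
    n_train = min(max(n_train, 1), len(cn) - 1)
    train = cn.iloc[np.sort(order[:n_train])].reset_index(drop=True)
    test = cn.iloc[np.sort(order[n_train:])].reset_index(drop=True)
    return train, test


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Execute the full experiment; returns (and optionally writes) a
    report bundle ``{"report": <nested dict>, "tables": {name: DataFrame}}``.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    seeds = {s: stage_seed(config.seed, s) for s in STAGE_SEED_OFFSETS}
    tables: dict[str, pd.DataFrame] = {}
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "schemes": list(config.schemes),
    }

    t0 = time.perf_counter()
    cohort = synthetic.generate_cohort(config.generator.with_seed(seeds["generator"]))
    _log_stage("generate", seeds["generator"], cohort, t0)

    t0 = time.perf_counter()
    train, cn_test = split_cohort(
        cohort, config.control_group, config.train_fraction, seeds["split"]
    )
    _log_stage("split", seeds["split"], train, t0)

    t0 = time.perf_counter()
    cv_preds = model.cross_val_predict(
        train, k=config.k_folds, seed=seeds["folds"], backend=config.backend
    )
    tables["train_cv_predictions"] = cv_preds
    _log_stage("cross_val", seeds["folds"], cv_preds, t0)

    # offset models are fitted and serialized before any test data is predicted
    offsets: dict[str, adjust.OffsetModel] = {}
    for scheme in ("proposed", "cole"):
        if scheme in config.schemes:
            offsets[scheme] = adjust.fit_offset_model(cv_preds, scheme)
            if out_path is not None:
                offsets[scheme].to_json(out_path / f"offset_{scheme}.json")
    report["offset_models"] = {
        s: {
            "scheme": m.scheme,
            "slope": m.slope,
            "intercept": m.intercept,
            "n_train": m.n_train,
            "fit_provenance": m.fit_provenance,
            "r": m.r,
        }
        for s, m in offsets.items()
    }

    t0 = time.perf_counter()
    final_model = model.fit_regressor(train, backend=config.backend)
    report["model_metadata"] = final_model.metadata()
    _log_stage("final_fit", None, train, t0)

    clinical = sorted(
        g for g in config.generator.n_per_group if g != config.control_group
    )
    test_sets: dict[str, pd.DataFrame] = {config.control_group: cn_test}
    for g in clinical:
        test_sets[g] = cohort[cohort["group"] == g].reset_index(drop=True)
    test_preds = {
        name: model.predict(final_model, df, provenance="independent_test")
        for name, df in test_sets.items()
    }

    # adjustment arms
    arms: dict[str, dict[str, pd.DataFrame]] = {}
    for scheme in config.schemes:
        m = offsets.get(scheme)
        arm = {"train": adjust.apply_scheme(cv_preds, m, scheme, config.cole_slope_floor)}
        for name, preds in test_preds.items():
            arm[name] = adjust.apply_scheme(preds, m, scheme, config.cole_slope_floor)
        arms[scheme] = arm
        for name, df in arm.items():
            tables[f"{scheme}_{name}"] = df

    report["evaluation"] = _evaluate(config, arms, clinical)
    bundle = {"report": report, "tables": tables}
    if out_path is not None:
        save_bundle(bundle, out_path)
    return bundle


def _evaluate(
    config: ExperimentConfig,
    arms: dict[str, dict[str, pd.DataFrame]],
    clinical: Sequence[str],
) -> dict[str, Any]:
    boot_seed = stage_seed(config.seed, "bootstrap")
    cn = config.control_group
    ev: dict[str, Any] = {"accuracy": {}, "group_comparison": {}}

    # per-arm accuracy on training (CV) and CN test predictions
    for scheme, arm in arms.items():
        ev["accuracy"][scheme] = {}
        for ds in ("train", cn):
            rep = evaluation.accuracy_metrics(
                arm[ds]["age"],
                arm[ds]["predicted_adjusted"],
                n_boot=config.n_boot,
                seed=boot_seed,
            )
            ev["accuracy"][scheme][ds] = rep.to_dict()

    # pairwise inter-arm comparisons: Levene on deltas, paired bootstrap on MAE
    ev["levene_between_arms"] = {}
    ev["bootstrap_mae_between_arms"] = {}
    datasets = ["train", cn, *clinical]
    for a, b in combinations(config.schemes, 2):
        for ds in datasets:
            f, p = evaluation.levene_variance_test(
                arms[a][ds]["delta_adjusted"], arms[b][ds]["delta_adjusted"]
            )
            ev["levene_between_arms"][f"{a}_vs_{b}:{ds}"] = {"f": f, "p": p}
        p, ci_a, ci_b = evaluation.bootstrap_mae_comparison(
            np.abs(arms[a][cn]["delta_adjusted"]),
            np.abs(arms[b][cn]["delta_adjusted"]),
            n_boot=config.n_boot,
            seed=boot_seed,
        )
        ev["bootstrap_mae_between_arms"][f"{a}_vs_{b}:{cn}"] = {
            "p": p, "mae_ci_a": list(ci_a), "mae_ci_b": list(ci_b),
        }

    # per-arm group contrast across CN test + clinical groups
    group_order = [cn, *clinical]
    for scheme, arm in arms.items():
        frames = [arm[g].assign(test_group=g) for g in group_order]
        combined = pd.concat(frames, ignore_index=True)
        deltas = combined["delta_adjusted"].to_numpy()
        labels = combined["test_group"].to_numpy()
        entry: dict[str, Any] = {"group_mean_delta": {}}
        for g in group_order:
            mean, ci = evaluation.mean_delta_ci(
                arm[g]["delta_adjusted"], n_boot=config.n_boot, seed=boot_seed
            )
            entry["group_mean_delta"][g] = {"mean": mean, "ci": list(ci)}
        at = evaluation.group_anova_tukey(deltas, labels)
        entry.update(at.to_dict())
        entry["cohens_d_vs_control"] = {
            g: evaluation.cohens_d(
                arm[g]["delta_adjusted"], arm[cn]["delta_adjusted"]
            )
            for g in clinical
        }
        ev["group_comparison"][scheme] = entry

    # age-covariate group test on raw deltas (group-level adjustment)
    raw = pd.concat(
        [arms[config.schemes[0]][g].assign(test_group=g) for g in group_order],
        ignore_index=True,
    )
    le = adjust.le_group_test(raw["delta"], raw["age"], raw["test_group"])
    ev["le_covariate_test"] = le.to_dict()
    return ev


def save_bundle(bundle: dict[str, Any], out_dir: str | Path) -> None:
    """Write the report JSON and every table as CSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(bundle["report"], out / "report.json")
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    for name, df in bundle["tables"].items():
        write_predictions_csv(df, tables_dir / f"{name}.csv")


def _fit_with_band(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """OLS fit of y on x with the 95% prediction band at each x."""
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    frame = res.get_prediction(X).summary_frame(alpha=0.05)
    return pd.DataFrame(
        {
            "fit": frame["mean"].to_numpy(),
            "band_low": frame["obs_ci_lower"].to_numpy(),
            "band_high": frame["obs_ci_upper"].to_numpy(),
        }
    )


def reproduce_figures(bundle: dict[str, Any]) -> dict[str, pd.DataFrame]:
    """Per-arm scatter-data tables for the standard diagnostic figures.

    For every arm and dataset in the bundle, emits a table of (age,
    predicted, delta) with the fitted regression line and 95% prediction
    band for both predicted-vs-age and delta-vs-age.
    """
    tables = bundle.get("tables") or {}
    schemes = (bundle.get("report") or {}).get("schemes") or []
    if not schemes:
        raise AgeDeltaError("bundle has no schemes; nothing to plot")
    out: dict[str, pd.DataFrame] = {}
    for name, df in tables.items():
        if "predicted_adjusted" not in df.columns or len(df) < 3:
            continue
        age = df["age"].to_numpy(dtype=float)
        pred = df["predicted_adjusted"].to_numpy(dtype=float)
        delta = df["delta_adjusted"].to_numpy(dtype=float)
        pred_band = _fit_with_band(age, pred).add_prefix("pred_")
        delta_band = _fit_with_band(age, delta).add_prefix("delta_")
        tab = pd.DataFrame({"age": age, "predicted": pred, "delta": delta})
        out[name] = pd.concat([tab, pred_band, delta_band], axis=1).sort_values(
            "age", kind="stable"
        ).reset_index(drop=True)
    if not out:
        raise AgeDeltaError("bundle contains no adjusted prediction tables")
    return out
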