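"""Classifier training: grid-searched RBF-SVM and random forest with
repeated stratified 10-fold cross-validation, selection on MCC, and a
two-model consensus predictor.

Protocol
--------
The data are split into k = 10 stratified folds (each fold holds ~10% of
each class). For one repeat, every sample is predicted exactly once by a
model trained on the other nine folds; the repeat's metrics come from the
*pooled* confusion counts over all k test folds. Ten independent repeats
(fold seeds varied as seed + repeat index) give a mean and dispersion per
grid point. The grid point with the highest mean MCC wins; ties go to the
first point in a deterministic scan order (ascending C then gamma for the
SVM; ascending ntree, mtry, nsplit for the forest). The winner is refitted
on all data and the full cross-validation record is retained for audit.

Hyperparameter grids (defaults)
-------------------------------
* SVM (RBF kernel): C over 2^-15 .. 2^10 and gamma over 2^-10 .. 2^10, both
  on a log2 grid with a configurable step (default 1).
* Random forest: ntree (number of trees) 10..500 step 10; mtry (features
  tried per split) 1..7; nsplit (minimum samples to split an internal
  node) 2..10.

Feature columns are standardised (zero mean, unit variance) inside each
training fold for the SVM only — the RBF kernel is scale-sensitive and the
PCP mass column is ~10^3 larger than the composition fractions — while the
forest consumes raw features. Standardisation lives inside the sklearn
Pipeline, so cross-validation never leaks test-fold statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__
from .features import FeatureConfig, encode_dataset
from .metrics import MetricSet, chou_metrics, confusion_counts
from .sequence_io import Peptide

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SvmGrid:
    """RBF-SVM hyperparameter grid on log2 axes."""

    log2_c: tuple[int, ...] = tuple(range(-15, 11))
    log2_gamma: tuple[int, ...] = tuple(range(-10, 11))

    def __post_init__(self) -> None:
        for axis in (self.log2_c, self.log2_gamma):
            if not axis or list(axis) != sorted(set(axis)):
                raise ValueError("grid axes must be non-empty and increasing")

    @classmethod
    def with_step(cls, step: int) -> "SvmGrid":
        """The default ranges thinned to every ``step``-th log2 value."""
        return cls(
            log2_c=tuple(range(-15, 11, step)),
            log2_gamma=tuple(range(-10, 11, step)),
        )

    def points(self) -> list[dict]:
        return [
            {"C": 2.0**c, "gamma": 2.0**g}
            for c, g in product(self.log2_c, self.log2_gamma)
        ]


@dataclass(frozen=True)
class RfGrid:
    """Random-forest hyperparameter grid (ntree, mtry, nsplit)."""

    ntree: tuple[int, ...] = tuple(range(10, 501, 10))
    mtry: tuple[int, ...] = tuple(range(1, 8))
    nsplit: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        for axis in (self.ntree, self.mtry, self.nsplit):
            if not axis or any(v < 1 for v in axis):
                raise ValueError("grid axes must be positive integers")

    def points(self) -> list[dict]:
        return [
            {"ntree": t, "mtry": m, "nsplit": s}
            for t, m, s in product(self.ntree, self.mtry, self.nsplit)
        ]


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings; the seed is mandatory so every
    fold assignment is reproducible."""

    k: int = 10
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    """Per-repeat pooled metrics plus summary statistics."""

    per_repeat: list[MetricSet]

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([m.mcc for m in self.per_repeat]))

    @property
    def std_mcc(self) -> float:
        return float(np.std([m.mcc for m in self.per_repeat]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.per_repeat]))


@dataclass
class TrainedModel:
    """A fitted classifier with the configuration that produced it."""

    algorithm: str  # "svm" or "rf"
    hyperparameters: dict
    feature_config: FeatureConfig
    estimator: object
    cv_record: Optional[CVResult]
    seed: int
    feature_names: list[str]
    package_version: str = __version__


def make_folds(labels: Sequence[int], cv_config: CVConfig) -> list[np.ndarray]:
    """Stratified partition of indices into k disjoint test folds.

    Deterministic given the seed; per-fold class counts differ from perfect
    stratification by at most one sample per class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if cv_config.k > counts.min():
        raise ValueError(
            f"k={cv_config.k} exceeds the minority class size {counts.min()}"
        )
    splitter = StratifiedKFold(
        n_splits=cv_config.k, shuffle=True, random_state=cv_config.seed
    )
    return [test for _, test in splitter.split(np.zeros(len(y)), y)]


def build_estimator(algorithm: str, hyperparameters: dict):
    """Construct the (unfitted) sklearn estimator for one grid point."""
    if algorithm == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        kernel="rbf",
                        C=hyperparameters["C"],
                        gamma=hyperparameters["gamma"],
                    ),
                ),
            ]
        )
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=hyperparameters["ntree"],
            max_features=hyperparameters["mtry"],
            min_samples_split=hyperparameters["nsplit"],
            random_state=hyperparameters.get("random_state", 0),
            n_jobs=1,
        )
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def cross_validate(
    algorithm: str,
    hyperparameters: dict,
    X: np.ndarray,
    y: Sequence[int],
    cv_config: CVConfig,
) -> CVResult:
    """Repeated stratified k-fold CV pooling confusion counts per repeat.

    Each repeat uses fold seed ``cv_config.seed + repeat`` so repeats are
    independent partitions; within a repeat every sample is predicted
    exactly once by a model that never saw it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    per_repeat: list[MetricSet] = []
    for repeat in range(cv_config.repeats):
        folds = make_folds(
            y, dataclasses.replace(cv_config, seed=cv_config.seed + repeat)
        )
        predicted = np.empty_like(y)
        for test_idx in folds:
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            est = build_estimator(algorithm, hyperparameters)
            est.fit(X[train_mask], y[train_mask])
            predicted[test_idx] = est.predict(X[test_idx])
        per_repeat.append(chou_metrics(confusion_counts(y, predicted)))
    return CVResult(per_repeat)


def grid_search(
    algorithm: str,
    grid: "SvmGrid | RfGrid",
    X: np.ndarray,
    y: Sequence[int],
    cv_config: CVConfig,
    feature_config: FeatureConfig = FeatureConfig(),
    feature_names: Optional[list[str]] = None,
) -> TrainedModel:
    """Evaluate every grid point by cross-validation, select the highest
    mean MCC (first point in scan order on ties), refit on all data."""
    points = grid.points()
    if not points:
        raise ValueError("empty hyperparameter grid")
    best: Optional[tuple[float, dict, CVResult]] = None
    n_degenerate = 0
    for params in points:  # scan order = the declared tie-break order
        result = cross_validate(algorithm, params, X, y, cv_config)
        if any(m.mcc is None or m.mcc_degenerate for m in result.per_repeat):
            n_degenerate += 1
        score = result.mean_mcc
        if best is None or score > best[0]:
            best = (score, params, result)
    if best is None or n_degenerate == len(points):
        raise RuntimeError(
            "grid search failed: every grid point yielded a degenerate "
            "(single-class) prediction; check the input labels"
        )
    _, params, cv_record = best
    estimator = build_estimator(algorithm, params)
    estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
    if feature_names is None:
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else []
        )
    return TrainedModel(
        algorithm=algorithm,
        hyperparameters=params,
        feature_config=feature_config,
        estimator=estimator,
        cv_record=cv_record,
        seed=cv_config.seed,
        feature_names=feature_names,
    )


def _scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    if model.algorithm == "rf":
        return model.estimator.predict_proba(X)[:, 1]
    return model.estimator.decision_function(X)


def predict(model: TrainedModel, peptides: Iterable[Peptide]) -> pd.DataFrame:
    """Score peptides with a trained model.

    Returns a DataFrame with columns ``id``, ``score``, ``label``. The
    score is the class-1 probability for the forest (label = score >= 0.5)
    and the signed decision value for the SVM (label = score >= 0); both
    are monotone in confidence that the peptide is an ACP.
    """
    peptides = list(peptides)
    matrix, _ = encode_dataset(peptides, model.feature_config)
    if peptides and list(matrix.columns) != model.feature_names:
        raise ValueError("feature columns do not match the trained model")
    if not peptides:
        return pd.DataFrame(columns=["id", "score", "label"])
    scores = _scores(model, matrix.to_numpy())
    threshold = 0.5 if model.algorithm == "rf" else 0.0
    return pd.DataFrame(
        {
            "id": [p.id for p in peptides],
            "score": scores,
            "label": (scores >= threshold).astype(int),
        }
    )


def consensus_predict(
    rf_model: TrainedModel,
    svm_model: TrainedModel,
    peptides: Iterable[Peptide],
) -> pd.DataFrame:
    """Combine the two models: a class is called only when they agree.

    Output columns: id, rf_score, rf_label, svm_score, svm_label,
    consensus in {"ACP", "non-ACP", "ambiguous"}.
    """
    if rf_model.feature_config != svm_model.feature_config:
        raise ValueError("models were trained with different feature configs")
    peptides = list(peptides)
    rf_out = predict(rf_model, peptides)
    svm_out = predict(svm_model, peptides)
    agree = rf_out["label"].to_numpy() == svm_out["label"].to_numpy()
    call = np.where(
        agree,
        np.where(rf_out["label"] == 1, "ACP", "non-ACP"),
        "ambiguous",
    )
    return pd.DataFrame(
        {
            "id": rf_out["id"],
            "rf_score": rf_out["score"],
            "rf_label": rf_out["label"],
            "svm_score": svm_out["score"],
            "svm_label": svm_out["label"],
            "consensus": call,
        }
    )


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a single versioned archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": model.package_version,
        "algorithm": model.algorithm,
        "hyperparameters": model.hyperparameters,
        "feature_config": dataclasses.asdict(model.feature_config),
        "feature_names": model.feature_names,
        "seed": model.seed,
        "cv_record": model.cv_record,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; refuses unknown formats."""
    try:
        payload = joblib.load(path)
    except Exception as err:  # corrupted archive
        raise ValueError(f"cannot read model file {path}: {err}") from err
    if (
        not isinstance(payload, dict)
        or payload.get("format_version") != MODEL_FORMAT_VERSION
    ):
        raise ValueError(
            f"incompatible model file {path}: expected format "
            f"{MODEL_FORMAT_VERSION}, got {payload.get('format_version')!r}"
            if isinstance(payload, dict)
            else f"incompatible model file {path}: not an acpml archive"
        )
    return TrainedModel(
        algorithm=payload["algorithm"],
        hyperparameters=payload["hyperparameters"],
        feature_config=FeatureConfig(
            blocks=tuple(payload["feature_config"]["blocks"]),
            atom_table_id=payload["feature_config"]["atom_table_id"],
            pcp_mass_units=payload["feature_config"]["pcp_mass_units"],
        ),
        estimator=payload["estimator"],
        cv_record=payload["cv_record"],
        seed=payload["seed"],
        feature_names=payload["feature_names"],
        package_version=payload["package_version"],
    )
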