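"""Damage-level classifiers: random forest, 1D-CNN and BP neural network.

Models are fitted on standardized features (the scaler is learned on
training data only and applied unchanged to test data), hyperparameters
are tuned by stratified 5-fold cross-validation over a small grid, and
evaluation follows the remote-sensing metric conventions of
:mod:`pestspec.metrics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from pestspec.features import FeatureTable
from pestspec.metrics import ConfusionMatrix, classification_metrics
from pestspec.nn import Conv1DNetClassifier

MODEL_KINDS = ("RF", "CNN1D", "BPNN")
LEVEL_LABELS = {1: "healthy", 2: "mild", 3: "moderate", 4: "severe"}


class SplitSpec(BaseModel):
    """Train/test partition: default 3:1, stratified by damage level."""

    ratio: tuple[int, int] = (3, 1)
    stratified: bool = True
    seed: int = 0

    @property
    def test_fraction(self) -> float:
        tr, te = self.ratio
        return te / (tr + te)


def split_train_test(table: FeatureTable, spec: SplitSpec | None = None):
    """Random (optionally stratified) split into train and test tables."""
    spec = spec or SplitSpec()
    y = table.labels
    if spec.stratified:
        counts = y.value_counts()
        infeasible = counts[counts < 1.0 / spec.test_fraction]
        if len(infeasible):
            raise ValueError(
                f"stratified split infeasible for class(es) {infeasible.index.tolist()}"
            )
    train_ids, test_ids = train_test_split(
        table.values.index,
        test_size=spec.test_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed % (2**31),
    )
    return table.select_rows(train_ids), table.select_rows(test_ids)


def _default_grid(kind: str, n_features: int, n_classes: int) -> list[dict]:
    if kind == "RF":
        return [{"max_depth": None}, {"max_depth": 12}]
    if kind == "BPNN":
        width = max(8, int(np.ceil(2.0 / 3.0 * (n_features + n_classes))))
        return [{"hidden_layer_sizes": (width,), "learning_rate_init": 0.01}]
    if kind == "CNN1D":
        return [{"lr": 0.01}]
    raise ValueError(f"unknown model kind {kind!r}")


def _make_estimator(kind: str, params: dict, seed: int):
    seed = seed % (2**31)
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1, **params
        )
    if kind == "BPNN":
        return MLPClassifier(
            activation="logistic",
            solver="adam",
            max_iter=400,
            random_state=seed,
            **params,
        )
    if kind == "CNN1D":
        return Conv1DNetClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class TrainedModel:
    """A fitted scaler+estimator pipeline with its tuning record."""

    kind: str
    pipeline: Pipeline
    feature_names: list[str]
    cv_summary: list[float]
    best_params: dict
    seed: int

    def predict(self, table: FeatureTable) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.feature_names]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        X = table.values[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict(X)


def train_model(
    kind: str,
    train: FeatureTable,
    cv_folds: int = 5,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> TrainedModel:
    """Fit one classifier kind with small-grid 5-fold CV tuning.

    Returns the refitted model and the per-fold CV accuracies of the
    winning configuration.  Deterministic given ``seed``.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"model kind must be one of {MODEL_KINDS}")
    X = train.values.to_numpy(dtype=float)
    y = train.labels.to_numpy()
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    grid = grid if grid is not None else _default_grid(kind, X.shape[1], len(classes))
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X, y))
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in grid:
            pipe = Pipeline(
                [
                    ("scaler", StandardScaler()),
                    ("clf", _make_estimator(kind, params, seed)),
                ]
            )
            accs = []
            for tr, te in folds:
                p = clone(pipe).fit(X[tr], y[tr])
                accs.append(float(p.score(X[te], y[te])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0]:
                best = (mean_acc, params, accs)
        _, best_params, cv_accs = best
        final = Pipeline(
            [
                ("scaler", StandardScaler()),
                ("clf", _make_estimator(kind, best_params, seed)),
            ]
        ).fit(X, y)
    return TrainedModel(
        kind=kind,
        pipeline=final,
        feature_names=train.feature_names,
        cv_summary=cv_accs,
        best_params=best_params,
        seed=seed,
    )


@dataclass
class ModelResult:
    """Held-out evaluation of one model: predictions, confusion, metrics."""

    model_kind: str
    predictions: pd.Series
    confusion: ConfusionMatrix
    oa: float
    kappa: float
    recall: float
    f1: float
    per_class: dict
    cv_summary: list[float] = field(default_factory=list)
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        rows = {
            "OA": self.oa,
            "kappa": self.kappa,
            "recall": self.recall,
            "F1": self.f1,
        }
        return pd.DataFrame({self.model_kind: rows})

    def to_dict(self) -> dict:
        levels = [int(l) for l in self.confusion.levels]
        return {
            "model_kind": self.model_kind,
            "oa": self.oa,
            "kappa": self.kappa,
            "recall": self.recall,
            "f1": self.f1,
            "levels": levels,
            "confusion": self.confusion.counts.astype(int).tolist(),
            "per_class": {
                k: [None if np.isnan(x) else float(x) for x in v]
                for k, v in self.per_class.items()
            },
            "cv_summary": list(self.cv_summary),
            "seed": self.seed,
        }


def evaluate(model: TrainedModel, test: FeatureTable) -> ModelResult:
    """Confusion matrix and OA/kappa/macro-recall/macro-F1 on a test table."""
    if test.n_samples == 0:
        raise ValueError("test table is empty")
    y_true = test.labels.to_numpy()
    y_pred = model.predict(test)
    known = model.pipeline.named_steps["clf"].classes_
    levels = sorted(set(y_true) | set(y_pred) | set(int(c) for c in known))
    absent = [l for l in levels if (y_true == l).sum() == 0]
    if absent:
        warnings.warn(
            f"class(es) {absent} absent from the test truth; their per-class "
            "metrics are undefined and excluded from macro averages"
        )
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, levels)
    m = classification_metrics(cm)
    return ModelResult(
        model_kind=model.kind,
        predictions=pd.Series(y_pred, index=test.values.index, name="predicted_level"),
        confusion=cm,
        oa=m["oa"],
        kappa=m["kappa"],
        recall=m["recall"],
        f1=m["f1"],
        per_class=m["per_class"],
        cv_summary=model.cv_summary,
        seed=model.seed,
    )


def predict_all(model: TrainedModel, table: FeatureTable):
    """Predict a level for every tree plus a level-composition summary.

    Returns ``(predictions, composition)`` where composition is a
    DataFrame of per-level counts and percentages over the whole stand.
    """
    y_pred = model.predict(table)
    pred = pd.Series(y_pred, index=table.values.index, name="predicted_level")
    counts = pred.value_counts().reindex([1, 2, 3, 4], fill_value=0)
    comp = pd.DataFrame(
        {
            "level": [LEVEL_LABELS[l] for l in counts.index],
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(pred),
        },
        index=counts.index,
    )
    return pred, comp
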