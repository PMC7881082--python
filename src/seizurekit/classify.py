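"""Training and applying the seven benchmark classifiers.

The comparison suite covers SVM (RBF), a bagged-tree ensemble, k-nearest
neighbors, linear discriminant analysis, logistic regression, a single
decision tree, and Gaussian naive Bayes — all via scikit-learn, each behind
a shared ``train``/``predict`` surface.

Feature columns span roughly ten orders of magnitude (SKW ~0.1 vs POW
~1e12), so every model is fitted inside a pipeline that z-scores features
with training-set statistics; those statistics are frozen at fit time and
re-applied verbatim at prediction. "Seizure" (``State == "s"``) is the
positive class everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, SchemaMismatchError
from .features import FEATURE_COLUMNS, STATE_COLUMN

__all__ = ["CLASSIFIER_NAMES", "TrainedModel", "train", "predict",
           "save_model", "load_model"]

# defaults chosen as the common toolkit defaults; all overridable per call
_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "svm": {"kernel": "rbf", "C": 1.0},
    "ensemble": {"n_estimators": 100},  # bagged decision trees
    "knn": {"n_neighbors": 5},  # odd, avoids voting ties
    "lda": {},
    "logistic_regression": {"max_iter": 1000},
    "decision_tree": {"criterion": "gini", "max_depth": None},
    "naive_bayes": {},
}

CLASSIFIER_NAMES = tuple(_DEFAULT_HYPERPARAMETERS)


def _make_estimator(name: str, seed: int, hp: dict):
    if name == "svm":
        return SVC(random_state=seed, **hp)
    if name == "ensemble":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **hp,
        )
    if name == "knn":
        return KNeighborsClassifier(**hp)
    if name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if name == "logistic_regression":
        return LogisticRegression(random_state=seed, **hp)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if name == "naive_bayes":
        return GaussianNB(**hp)
    raise ConfigurationError(
        f"unknown classifier {name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}"
    )


@dataclass
class TrainedModel:
    """A fitted classifier with its z-scoring pipeline and provenance."""

    name: str
    pipeline: Pipeline
    feature_columns: list[str]
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def scaler(self) -> StandardScaler:
        """The per-column center/scale applied at fit time."""
        return self.pipeline.named_steps["scale"]


def train(
    name: str,
    table: pd.DataFrame,
    seed: int = 0,
    **hyperparameters,
) -> TrainedModel:
    """Fit one of the seven classifiers on an averaged feature table.

    The table must carry the eleven feature columns and a binary ``State``
    column with at least two rows per class. Stochastic learners are seeded;
    the same seed and data give an identical model.
    """
    hp = dict(_DEFAULT_HYPERPARAMETERS.get(name, {}))
    hp.update(hyperparameters)
    estimator = _make_estimator(name, seed, hp)  # validates the name
    missing = [c for c in FEATURE_COLUMNS + [STATE_COLUMN] if c not in table.columns]
    if missing:
        raise SchemaMismatchError(f"training table is missing columns {missing}")
    y = table[STATE_COLUMN].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            f"training table contains a single class {classes.tolist()}; two required"
        )
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class to train")
    pipeline = Pipeline([("scale", StandardScaler()), ("clf", estimator)])
    pipeline.fit(table[FEATURE_COLUMNS].to_numpy(), y)
    return TrainedModel(
        name=name,
        pipeline=pipeline,
        feature_columns=list(FEATURE_COLUMNS),
        hyperparameters=hp,
        seed=seed,
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict one ``"s"``/``"n"`` label per row of ``table``.

    Scaling parameters from fit time are applied, never re-estimated.
    """
    missing = [c for c in model.feature_columns if c not in table.columns]
    if missing:
        raise SchemaMismatchError(f"prediction table is missing columns {missing}")
    if len(table) == 0:
        return np.array([], dtype=object)
    return model.pipeline.predict(table[model.feature_columns].to_numpy())


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (name, hyperparameters, scaling, fitted state)."""
    joblib.dump(
        {
            "format": "seizurekit-model",
            "name": model.name,
            "hyperparameters": model.hyperparameters,
            "feature_columns": model.feature_columns,
            "seed": model.seed,
            "pipeline": model.pipeline,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "seizurekit-model":
        raise ConfigurationError(f"{path}: not a seizurekit model file")
    return TrainedModel(
        name=payload["name"],
        pipeline=payload["pipeline"],
        feature_columns=payload["feature_columns"],
        hyperparameters=payload["hyperparameters"],
        seed=payload["seed"],
    )
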