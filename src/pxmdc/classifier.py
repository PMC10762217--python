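"""Missing-mechanism classifiers: gradient-boosted trees plus two baselines.

The primary backend is XGBoost; random forest and Gaussian naive Bayes are kept
as reference baselines.  The task is binary (MNAR vs MCAR — missingness that
depends only on observed values is folded into MCAR, as is conventional when the
dependence cannot be established).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder
from xgboost import XGBClassifier

from .core_io import MCAR, MNAR
from .feature_extraction import FEATURE_COLUMNS, FeatureTable

BACKENDS = ("xgb", "rf", "nb")

#: class order used for integer encoding throughout
CLASS_ORDER = (MCAR, MNAR)

_CATEGORICAL = ["metabolite_code", "tier_code"]
_NUMERIC = [c for c in FEATURE_COLUMNS if c not in _CATEGORICAL]


def _make_estimator(backend: str, seed: int, hyperparams: dict | None) -> Any:
    hp = dict(hyperparams or {})
    if backend == "xgb":
        defaults = dict(
            n_estimators=300,
            max_depth=6,
            learning_rate=0.1,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
        )
        defaults.update(hp)
        return XGBClassifier(**defaults)
    if backend == "rf":
        defaults = dict(n_estimators=500, random_state=seed, n_jobs=1)
        defaults.update(hp)
        return RandomForestClassifier(**defaults)
    if backend == "nb":
        # Gaussian NB on the numeric block; categorical codes one-hot encoded.
        encoder = ColumnTransformer(
            [
                ("num", "passthrough", list(range(len(_NUMERIC)))),
                (
                    "cat",
                    OneHotEncoder(handle_unknown="ignore", sparse_output=False),
                    list(range(len(_NUMERIC), len(FEATURE_COLUMNS))),
                ),
            ]
        )
        return Pipeline([("encode", encoder), ("nb", GaussianNB(**hp))])
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


@dataclass
class TrainedClassifier:
    backend: str
    model: Any
    metabolite_codes: dict[str, int]
    classes: tuple[str, str]
    seed: int
    split: float
    hyperparams: dict


def _design(features: FeatureTable) -> np.ndarray:
    X = features.design_matrix()
    missing_cols = [c for c in FEATURE_COLUMNS if c not in X.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns {missing_cols}")
    return X[_NUMERIC + _CATEGORICAL].to_numpy(dtype=float)


def train(
    features: FeatureTable,
    backend: str = "xgb",
    split: float = 0.8,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> tuple[TrainedClassifier, float]:
    """Fit on a stratified ``split`` fraction; return model and held-out accuracy."""
    if len(features) == 0:
        raise ValueError("cannot train on an empty feature table")
    y_str = features.labels
    if y_str.isna().any():
        raise ValueError("training features must all carry mechanism labels")
    present = set(y_str.unique())
    if len(present) < 2:
        raise ValueError(f"need both classes to train, got only {sorted(present)}")
    X = _design(features)
    y = y_str.map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy(dtype=int)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )
    est = _make_estimator(backend, seed, hyperparams)
    est.fit(X_tr, y_tr)
    accuracy = float(np.mean(est.predict(X_val) == y_val))
    clf = TrainedClassifier(
        backend=backend,
        model=est,
        metabolite_codes=dict(features.metabolite_codes),
        classes=CLASS_ORDER,
        seed=seed,
        split=split,
        hyperparams=dict(hyperparams or {}),
    )
    return clf, accuracy


def predict(model: TrainedClassifier, features: FeatureTable) -> pd.Series:
    """Predicted mechanism per feature row, aligned with the table's index."""
    if len(features) == 0:
        return pd.Series([], dtype=object, name="predicted_mechanism")
    X = _design(features)
    codes = model.model.predict(X)
    labels = np.asarray(model.classes, dtype=object)[np.asarray(codes, dtype=int)]
    return pd.Series(labels, index=features.frame.index, name="predicted_mechanism")
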