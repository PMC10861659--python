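"""Random-forest hair-detectability model with a range-based applicability domain.

Workflow: descriptor table -> useless-feature filter -> 500-tree random
forest (fixed seed) -> stratified tenfold cross-validation -> screening.
The detectability score of a query is the fraction of trees voting for the
positive (hair-detectable) class; predictions are only issued inside the
applicability domain, the per-feature min-max box of the training set
(closed intervals). Scores strictly above 0.9 are flagged high-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .descriptors import DescriptorTable

__all__ = [
    "UselessFeatureFilter",
    "HairDetectabilityForest",
    "QSARModel",
    "ScreeningResult",
    "DEFAULT_FOREST_SPEC",
    "remove_useless",
    "train_model",
    "cross_validate",
    "in_domain",
    "screen",
]

POSITIVE, NEGATIVE = "positive", "negative"
DETECT_THRESHOLD = 0.5       # majority vote
HIGH_CONF_THRESHOLD = 0.9    # strictly above

#: 500 trees, sqrt(p) features per split, fixed seed - stable on a 17 x p table.
DEFAULT_FOREST_SPEC = {"n_trees": 500, "max_features_rule": "sqrt",
                       "seed": 20240115, "bootstrap": True}


class UselessFeatureFilter(TransformerMixin, BaseEstimator):
    """Drop uninformative features.

    Numeric features with (relative-tolerance) zero variance are dropped;
    categorical features whose distinct-value count exceeds ``threshold``
    percent of the row count are identifier-like and dropped. Retained
    column order is preserved, and the filter is idempotent.
    """

    def __init__(self, threshold: float = 99.0, rel_tol: float = 1e-12):
        self.threshold = threshold
        self.rel_tol = rel_tol

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100]")
        X = pd.DataFrame(X)
        keep = []
        for col in X.columns:
            s = X[col]
            if pd.api.types.is_numeric_dtype(s):
                v = s.to_numpy(dtype=float)
                span = float(np.ptp(v)) if v.size else 0.0
                scale = max(1.0, float(np.max(np.abs(v)))) if v.size else 1.0
                if span > self.rel_tol * scale:
                    keep.append(col)
            else:
                if len(X) and s.nunique() <= self.threshold / 100.0 * len(X):
                    keep.append(col)
        if not keep:
            raise ValueError("all features removed by the filter")
        self.retained_features_ = list(keep)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_features_")
        return pd.DataFrame(X)[self.retained_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_features_")
        return np.asarray(self.retained_features_, dtype=object)


def remove_useless(table: DescriptorTable, variance_pct_threshold: float = 99.0) -> DescriptorTable:
    """Filtered copy of a descriptor table (thin wrapper over the filter)."""
    filt = UselessFeatureFilter(threshold=variance_pct_threshold)
    values = filt.fit(table.values).transform(table.values)
    return DescriptorTable(
        values=values,
        feature_kinds={c: table.feature_kinds[c] for c in values.columns},
        provenance=table.provenance,
        excluded=table.excluded,
    )


class HairDetectabilityForest(ClassifierMixin, BaseEstimator):
    """Random-forest classifier with vote-fraction scores and a range AD.

    Fitted attributes: ``classes_``, ``feature_names_in_``, ``ad_ranges_``
    (per-feature closed (min, max) over the training rows) and the
    underlying ``forest_``. ``vote_score`` returns the fraction of trees
    predicting the positive class - the screening score.
    """

    def __init__(self, n_estimators: int = 500, max_features: str = "sqrt",
                 random_state: int = DEFAULT_FOREST_SPEC["seed"],
                 bootstrap: bool = True):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state
        self.bootstrap = bootstrap

    def fit(self, X, y):
        X, names = self._coerce(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present to train")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.feature_names_in_ = names
        self.n_features_in_ = X.shape[1]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
            bootstrap=self.bootstrap,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.ad_ranges_ = {
            name: (float(X[:, j].min()), float(X[:, j].max()))
            for j, name in enumerate(names)
        }
        return self

    def _coerce(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return X, [f"x{j}" for j in range(X.shape[1])]

    def _align(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature(s): {', '.join(missing)}")
            return X[self.feature_names_in_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def vote_score(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row."""
        X = self._align(X)
        # individual trees predict indices into forest_.classes_
        pos_idx = list(self.forest_.classes_).index(self._positive_label())
        votes = np.stack(
            [tree.predict(X).astype(int) == pos_idx
             for tree in self.forest_.estimators_]
        )
        return votes.mean(axis=0)

    def _positive_label(self):
        if POSITIVE in self.classes_:
            return POSITIVE
        return self.classes_[-1]

    def predict(self, X):
        score = self.vote_score(X)
        pos = self._positive_label()
        neg = [c for c in self.classes_ if c != pos][0]
        return np.where(score >= DETECT_THRESHOLD, pos, neg)

    def predict_proba(self, X):
        score = self.vote_score(X)
        pos_idx = list(self.classes_).index(self._positive_label())
        proba = np.zeros((len(score), len(self.classes_)))
        proba[:, pos_idx] = score
        proba[:, 1 - pos_idx] = 1.0 - score
        return proba

    def in_domain(self, X) -> np.ndarray:
        """True where every feature lies inside its training [min, max]."""
        X = self._align(X)
        ok = np.ones(X.shape[0], dtype=bool)
        for j, name in enumerate(self.feature_names_in_):
            lo, hi = self.ad_ranges_[name]
            ok &= (X[:, j] >= lo) & (X[:, j] <= hi)
        return ok


@dataclass
class QSARModel:
    """Trained screening model: forest + retained features + AD box."""

    retained_features: list[str]
    ad_ranges: dict[str, tuple[float, float]]
    forest_spec: dict
    training_labels: dict[str, str]
    training_accuracy: float
    estimator: HairDetectabilityForest = field(repr=False, default=None)


def train_model(
    table: DescriptorTable,
    labels: dict[str, str],
    forest_spec: dict | None = None,
) -> QSARModel:
    """Train on a filtered descriptor table with hair-detectability labels.

    ``training_accuracy`` re-predicts the training rows; the AD is the
    per-feature min/max box over the training rows (closed intervals).
    """
    spec = dict(DEFAULT_FOREST_SPEC, **(forest_spec or {}))
    missing = [s for s in table.substances if s not in labels]
    if missing:
        raise ValueError(f"missing labels for: {', '.join(missing)}")
    y = np.array([labels[s] for s in table.substances])
    est = HairDetectabilityForest(
        n_estimators=spec["n_trees"],
        max_features=spec["max_features_rule"],
        random_state=spec["seed"],
        bootstrap=spec["bootstrap"],
    ).fit(table.values, y)
    acc = float((est.predict(table.values) == y).mean())
    return QSARModel(
        retained_features=table.feature_names,
        ad_ranges=dict(est.ad_ranges_),
        forest_spec=spec,
        training_labels={s: labels[s] for s in table.substances},
        training_accuracy=acc,
        estimator=est,
    )


def cross_validate(
    table: DescriptorTable,
    labels: dict[str, str],
    k: int = 10,
    seed: int = 0,
    forest_spec: dict | None = None,
):
    """Stratified k-fold CV; returns (fold_assignments, accuracy, per-class recall).

    Folds are stratified so each holds a class mix as close as integer-
    feasible to the global ratio; metrics are pooled over held-out
    predictions, and the fold assignment is deterministic per seed.
    """
    n = len(table.substances)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    spec = dict(DEFAULT_FOREST_SPEC, **(forest_spec or {}))
    y = np.array([labels[s] for s in table.substances])
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    X = table.values
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(n, -1, dtype=int)
    pred = np.empty(n, dtype=object)
    base = HairDetectabilityForest(
        n_estimators=spec["n_trees"],
        max_features=spec["max_features_rule"],
        random_state=spec["seed"],
        bootstrap=spec["bootstrap"],
    )
    for fold, (train, test) in enumerate(skf.split(X, y)):
        folds[test] = fold
        est = clone(base).fit(X.iloc[train], y[train])
        pred[test] = est.predict(X.iloc[test])
    accuracy = float((pred == y).mean())
    recall = {
        c: float((pred[y == c] == c).mean()) for c in np.unique(y)
    }
    return folds, accuracy, recall


def in_domain(model: QSARModel, feature_vector: dict[str, float]) -> bool:
    """Range-based AD membership for one substance's features.

    A missing feature is an error, not silently out-of-domain.
    """
    missing = [f for f in model.retained_features if f not in feature_vector]
    if missing:
        raise ValueError(f"missing feature(s): {', '.join(missing)}")
    for f in model.retained_features:
        lo, hi = model.ad_ranges[f]
        if not lo <= feature_vector[f] <= hi:
            return False
    return True


@dataclass(frozen=True)
class ScreeningResult:
    substance: str
    in_ad: bool
    score: Optional[float]
    predicted: str                # detectable | undetectable | out_of_domain
    high_confidence: bool


def screen(
    model: QSARModel,
    table: DescriptorTable,
    wada_classes: dict[str, str] | None = None,
):
    """Score a substance list; out-of-AD rows get no score or prediction.

    Returns (results, summary) where summary has the partition counts
    (n_input = out_of_ad + detectable + undetectable) and, when classes
    are supplied, per-class detectable/high-confidence counts.
    """
    missing = [f for f in model.retained_features if f not in table.feature_names]
    if missing:
        raise ValueError(f"table lacks model feature(s): {', '.join(missing)}")
    X = table.values[model.retained_features]
    est = model.estimator
    inside = est.in_domain(X)
    scores = est.vote_score(X)
    results = []
    for i, sub in enumerate(table.substances):
        if not inside[i]:
            results.append(ScreeningResult(sub, False, None, "out_of_domain", False))
            continue
        sc = float(scores[i])
        predicted = "detectable" if sc >= DETECT_THRESHOLD else "undetectable"
        high = sc > HIGH_CONF_THRESHOLD and predicted == "detectable"
        results.append(ScreeningResult(sub, True, sc, predicted, high))
    summary = {
        "n_input": len(results),
        "out_of_domain": sum(r.predicted == "out_of_domain" for r in results),
        "detectable": sum(r.predicted == "detectable" for r in results),
        "undetectable": sum(r.predicted == "undetectable" for r in results),
        "high_confidence": sum(r.high_confidence for r in results),
    }
    if wada_classes:
        per_class: dict[str, dict[str, int]] = {}
        for r in results:
            k = wada_classes.get(r.substance, "unknown")
            d = per_class.setdefault(
                k, {"detectable": 0, "undetectable": 0, "out_of_domain": 0,
                    "high_confidence": 0}
            )
            d[r.predicted] += 1
            d["high_confidence"] += int(r.high_confidence)
        summary["per_class"] = per_class
    return results, summary
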