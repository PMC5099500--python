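"""The three supervised learners over tf-idf vectors: NB, LR, linear SVM.

A uniform train/predict contract wraps scikit-learn estimators:

* ``nb`` — multinomial naive Bayes with Laplace smoothing (alpha=1),
  treating non-negative tf-idf weights as fractional counts;
* ``lr`` — L2-regularized logistic regression (liblinear, C=1.0,
  tol=1e-6), one-vs-rest for multiclass;
* ``svm`` — linear soft-margin SVM with hinge loss (C=1.0), one-vs-rest.

Prediction is the argmax of per-class decision scores; exact ties break to
the first class in the classifier's (sorted) class order, so results are
deterministic. A trained classifier is bound to the feature space it was
trained on and refuses vectors from any other space.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.preprocessing import LabelBinarizer
from sklearn.svm import LinearSVC

from .featurize import FeatureSpace, FeatureVector, vectors_to_csr

__all__ = ["ALGORITHMS", "TrainedClassifier", "train", "predict", "predict_many",
           "save_model", "load_model"]

ALGORITHMS = ("nb", "lr", "svm")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "nb": {"alpha": 1.0},
    "lr": {"C": 1.0, "tol": 1e-6, "max_iter": 1000},
    "svm": {"C": 1.0, "loss": "hinge", "tol": 1e-4, "max_iter": 20000},
}


def space_hash(space: FeatureSpace) -> str:
    """Stable hash identifying a feature space (features, df, N)."""
    payload = json.dumps(
        {"features": list(space.features), "df": space.df, "N": space.N},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TrainedClassifier:
    algorithm: str
    classes: tuple[str, ...]
    model: object
    feature_space: FeatureSpace
    hyperparameters: dict
    space_hash: str = field(default="")

    def __post_init__(self) -> None:
        if not self.space_hash:
            self.space_hash = space_hash(self.feature_space)


def _build_estimator(algorithm: str, hp: dict, seed: int):
    if algorithm == "nb":
        return MultinomialNB(alpha=hp["alpha"])
    if algorithm == "lr":
        return OneVsRestClassifier(
            LogisticRegression(
                C=hp["C"], tol=hp["tol"], max_iter=hp["max_iter"],
                solver="liblinear", random_state=seed,
            )
        )
    if algorithm == "svm":
        return OneVsRestClassifier(
            LinearSVC(
                C=hp["C"], loss=hp["loss"], tol=hp["tol"], max_iter=hp["max_iter"],
                random_state=seed,
            )
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train(
    algorithm: str,
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    space: FeatureSpace,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Train one classifier on tf-idf vectors from a single feature space."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    if len(set(labels)) < 2:
        raise ValueError("training requires >=2 distinct labels")
    hp = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    if hyperparameters:
        hp.update(hyperparameters)
    hp["seed"] = seed
    X = vectors_to_csr(vectors, space)
    y = np.asarray(labels)
    est = _build_estimator(algorithm, hp, seed)
    est.fit(X, y)
    return TrainedClassifier(
        algorithm=algorithm,
        classes=tuple(str(c) for c in est.classes_),
        model=est,
        feature_space=space,
        hyperparameters=hp,
    )


def _scores_matrix(clf: TrainedClassifier, X) -> np.ndarray:
    if clf.algorithm == "nb":
        return clf.model.predict_log_proba(X)
    scores = clf.model.decision_function(X)
    if scores.ndim == 1:  # binary: expand to per-class columns
        scores = np.column_stack([-scores, scores])
    return scores


def _check_space(clf: TrainedClassifier, vectors: Sequence[FeatureVector]) -> None:
    for vec in vectors:
        for f in vec.weights:
            if clf.feature_space.index_of(f) is None:
                raise ValueError(
                    f"vector {vec.tweet_ref!r} not from this classifier's "
                    f"feature space (unknown feature {f!r})"
                )


def predict_many(
    clf: TrainedClassifier, vectors: Sequence[FeatureVector]
) -> list[str]:
    """Predicted labels for a batch; argmax with first-class tie-break."""
    _check_space(clf, vectors)
    X = vectors_to_csr(vectors, clf.feature_space)
    scores = _scores_matrix(clf, X)
    idx = np.argmax(scores, axis=1)  # first maximum wins on ties
    return [clf.classes[i] for i in idx]


def predict(
    clf: TrainedClassifier, vector: FeatureVector
) -> tuple[str, dict[str, float]]:
    """Predicted label plus the per-class decision scores for one vector."""
    _check_space(clf, [vector])
    X = vectors_to_csr([vector], clf.feature_space)
    scores = _scores_matrix(clf, X)[0]
    label = clf.classes[int(np.argmax(scores))]
    return label, dict(zip(clf.classes, scores.tolist()))


# ---------------------------------------------------------------------------
# serialization — versioned JSON bundle of hyperparameters, classes and
# learned parameters, tied to the feature space by hash

_FORMAT_VERSION = 1


def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    bundle: dict = {
        "format_version": _FORMAT_VERSION,
        "algorithm": clf.algorithm,
        "classes": list(clf.classes),
        "hyperparameters": clf.hyperparameters,
        "space_hash": clf.space_hash,
        "feature_space": {
            "features": list(clf.feature_space.features),
            "df": clf.feature_space.df,
            "chi2": clf.feature_space.chi2,
            "N": clf.feature_space.N,
            "k": clf.feature_space.k,
        },
    }
    if clf.algorithm == "nb":
        bundle["params"] = {
            "class_log_prior": clf.model.class_log_prior_.tolist(),
            "feature_log_prob": clf.model.feature_log_prob_.tolist(),
        }
    else:
        bundle["params"] = {
            "estimators": [
                {"coef": est.coef_.tolist(), "intercept": est.intercept_.tolist()}
                for est in clf.model.estimators_
            ]
        }
    Path(path).write_text(json.dumps(bundle), encoding="utf-8")


def load_model(path: str | Path) -> TrainedClassifier:
    bundle = json.loads(Path(path).read_text(encoding="utf-8"))
    if bundle.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version in {path}")
    fs = bundle["feature_space"]
    space = FeatureSpace(
        features=tuple(fs["features"]), df=fs["df"], chi2=fs["chi2"],
        N=fs["N"], k=fs["k"],
    )
    algorithm = bundle["algorithm"]
    classes = np.asarray(bundle["classes"])
    hp = bundle["hyperparameters"]
    seed = hp.get("seed", 0)
    est = _build_estimator(algorithm, hp, seed)
    if algorithm == "nb":
        est.classes_ = classes
        est.class_log_prior_ = np.asarray(bundle["params"]["class_log_prior"])
        est.feature_log_prob_ = np.asarray(bundle["params"]["feature_log_prob"])
        est.feature_count_ = np.zeros_like(est.feature_log_prob_)
        est.class_count_ = np.zeros(len(classes))
    else:
        lb = LabelBinarizer(sparse_output=True)
        lb.fit(classes)
        est.label_binarizer_ = lb
        est.classes_ = lb.classes_
        from sklearn.base import clone

        inner = est.estimator
        sub_estimators = []
        for p in bundle["params"]["estimators"]:
            sub = clone(inner)
            sub.coef_ = np.asarray(p["coef"])
            sub.intercept_ = np.asarray(p["intercept"])
            sub.classes_ = np.asarray([0, 1])
            sub_estimators.append(sub)
        est.estimators_ = sub_estimators
    clf = TrainedClassifier(
        algorithm=algorithm,
        classes=tuple(bundle["classes"]),
        model=est,
        feature_space=space,
        hyperparameters=hp,
        space_hash=bundle["space_hash"],
    )
    if clf.space_hash != space_hash(space):
        raise ValueError("feature space hash mismatch in model bundle")
    return clf
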