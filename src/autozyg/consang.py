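"""Parental-relatedness (PR) inference from the ROH length spectrum.

Each genome is summarized by 15 statistics — the total genetic length of
its ten longest ROHs (cM) and the counts of ROHs in fourteen 10-cM bins
spanning [10, 150) cM — and classified into a PR union class by an
ensemble of ten independently initialized single-hidden-layer neural
networks whose class probabilities are summed.  Training data are simulated
offspring of known union classes run through the same ROH-calling pipeline.

ROHs shorter than 10 cM fall outside every bin but still compete for the
ten-longest summary.

Fine labels are also grouped into three reporting tiers (first cousin or
closer / second cousin or first cousin once removed / unrelated) because
adjacent fine classes overlap heavily in their ROH spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigError, StructuralError
from .pedigree import UNION_CLASS_LABELS
from .roh import ROHCallParams, call_roh, froh_per_sample
from .synthdata import FounderPanel, simulate_union_offspring

__all__ = [
    "FEATURE_NAMES",
    "roh_summary_vector",
    "summarize_samples",
    "ParentalRelatednessClassifier",
    "train_pr_classifier",
    "classify_pr",
    "group_label",
    "generations_of_first_cousins",
    "select_highly_consanguineous",
]

_BIN_EDGES_CM = np.arange(10.0, 151.0, 10.0)  # [10,20), ..., [140,150)

FEATURE_NAMES = ["total_top10_cm"] + [
    f"n_roh_{int(a)}_{int(b)}cm" for a, b in zip(_BIN_EDGES_CM[:-1], _BIN_EDGES_CM[1:])
]

#: fine label -> reporting tier
_GROUPS = {
    "sibling": "first_cousin_or_closer",
    "avuncular": "first_cousin_or_closer",
    "first_cousin_1g": "first_cousin_or_closer",
    "first_cousin_2g": "first_cousin_or_closer",
    "first_cousin_3g": "first_cousin_or_closer",
    "first_cousin_once_removed": "second_cousin_or_1c1r",
    "second_cousin": "second_cousin_or_1c1r",
    "unrelated": "unrelated",
}

_GENERATIONS = {"first_cousin_1g": 1, "first_cousin_2g": 2, "first_cousin_3g": 3}


def group_label(label: str) -> str:
    try:
        return _GROUPS[label]
    except KeyError:
        raise ConfigError(f"no grouping defined for PR label {label!r}") from None


def generations_of_first_cousins(label: str) -> int | None:
    return _GENERATIONS.get(label)


def roh_summary_vector(segments) -> np.ndarray:
    """15-feature ROH length-spectrum summary for one sample.

    ``segments``: DataFrame with a ``length_cm`` column (or empty).
    """
    if isinstance(segments, pd.DataFrame):
        if len(segments) and "length_cm" not in segments:
            raise StructuralError("segments need a length_cm column")
        lengths = segments["length_cm"].to_numpy(dtype=float) if len(segments) else np.empty(0)
    else:
        lengths = np.asarray(segments, dtype=float)
    if np.any(lengths < 0):
        raise ConfigError("negative ROH length")
    top10 = np.sort(lengths)[::-1][:10].sum() if lengths.size else 0.0
    counts, _ = np.histogram(lengths, bins=_BIN_EDGES_CM)
    return np.concatenate(([top10], counts.astype(float)))


def summarize_samples(segments: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Feature matrix (one row per sample) from a multi-sample segment table."""
    groups = dict(tuple(segments.groupby("sample_id"))) if len(segments) else {}
    empty = segments.iloc[0:0]
    rows = [roh_summary_vector(groups.get(s, empty)) for s in sample_ids]
    return pd.DataFrame(rows, index=sample_ids, columns=FEATURE_NAMES)


class ParentalRelatednessClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of single-hidden-layer probabilistic classifiers.

    Ten members (logistic hidden activations, softmax output, L2 weight
    decay) are trained from different random initializations on
    standardized features; the ensemble score for a class is the sum of
    member probabilities and the predicted label its argmax.  Ties break
    toward the earliest class in ``class_order``.

    Parameters follow the sklearn convention; fitted state carries a
    trailing underscore.
    """

    def __init__(
        self,
        n_members: int = 10,
        hidden_size: int = 10,
        alpha: float = 0.01,
        max_iter: int = 500,
        class_order: tuple[str, ...] = UNION_CLASS_LABELS,
        random_state: int | None = 0,
    ) -> None:
        self.n_members = n_members
        self.hidden_size = hidden_size
        self.alpha = alpha
        self.max_iter = max_iter
        self.class_order = class_order
        self.random_state = random_state

    def fit(self, X, y) -> "ParentalRelatednessClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise StructuralError("X must be 2-D (n_samples, n_features)")
        present = pd.unique(y)
        if len(present) < 2:
            raise ConfigError("need at least two classes to train")
        unknown = set(present) - set(self.class_order)
        if unknown:
            raise ConfigError(f"labels outside class_order: {sorted(unknown)}")
        var = X.var(axis=0)
        # count bins for ROHs longer than any chromosome are structurally
        # constant (zero) and carry no signal; the top-10 length summary
        # going degenerate means the training set itself is broken
        if var[0] == 0 or np.all(var == 0):
            j = int(np.flatnonzero(var == 0)[0])
            name = FEATURE_NAMES[j] if j < len(FEATURE_NAMES) else f"feature {j}"
            raise ConfigError(f"zero-variance training feature: {name}")
        self.classes_ = np.array([c for c in self.class_order if c in set(present)])
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_members)
        self.members_ = []
        for s in seeds:
            m = MLPClassifier(
                hidden_layer_sizes=(self.hidden_size,),
                activation="logistic",
                alpha=self.alpha,
                max_iter=self.max_iter,
                solver="lbfgs",
                random_state=int(s % (2**31)),
            )
            m.fit(Xs, y)
            self.members_.append(m)
        self.n_features_in_ = X.shape[1]
        return self

    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ConfigError("non-finite feature values")
        if X.shape[1] != self.n_features_in_:
            raise StructuralError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = self.scaler_.transform(X)
        total = np.zeros((X.shape[0], len(self.classes_)))
        for m in self.members_:
            proba = m.predict_proba(Xs)
            cols = {c: k for k, c in enumerate(m.classes_)}
            total += proba[:, [cols[c] for c in self.classes_]]
        return total

    def predict_proba(self, X) -> np.ndarray:
        """Normalized summed ensemble scores (rows sum to 1)."""
        s = self._scores(X)
        return s / s.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        s = self._scores(X)
        return self.classes_[np.argmax(s, axis=1)]  # first max wins ties

    # -- text serialization -------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "members_")
        payload = {
            "format_version": 1,
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "scaler": {
                "mean": self.scaler_.mean_.tolist(),
                "scale": self.scaler_.scale_.tolist(),
            },
            "members": [
                {
                    "classes": m.classes_.tolist(),
                    "coefs": [w.tolist() for w in m.coefs_],
                    "intercepts": [b.tolist() for b in m.intercepts_],
                }
                for m in self.members_
            ],
        }
        payload["params"]["class_order"] = list(self.class_order)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ParentalRelatednessClassifier":
        payload = json.loads(text)
        params = payload["params"]
        params["class_order"] = tuple(params["class_order"])
        obj = cls(**params)
        obj.classes_ = np.array(payload["classes"])
        obj.scaler_ = StandardScaler()
        obj.scaler_.mean_ = np.array(payload["scaler"]["mean"])
        obj.scaler_.scale_ = np.array(payload["scaler"]["scale"])
        obj.scaler_.var_ = obj.scaler_.scale_ ** 2
        obj.scaler_.n_features_in_ = len(obj.scaler_.mean_)
        obj.n_features_in_ = len(obj.scaler_.mean_)
        obj.members_ = []
        for mrec in payload["members"]:
            m = MLPClassifier(hidden_layer_sizes=(params["hidden_size"],),
                              activation="logistic")
            m.classes_ = np.array(mrec["classes"])
            m.coefs_ = [np.array(w) for w in mrec["coefs"]]
            m.intercepts_ = [np.array(b) for b in mrec["intercepts"]]
            m.n_layers_ = len(m.coefs_) + 1
            # binary members have a single logistic output unit
            m.n_outputs_ = 1 if len(m.classes_) == 2 else len(m.classes_)
            m.out_activation_ = "logistic" if m.n_outputs_ == 1 else "softmax"
            m._label_binarizer = None
            obj.members_.append(m)
        return obj


def _simulate_training_features(
    panel: FounderPanel,
    classes: list[str],
    n_per_class: int,
    roh_params: ROHCallParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X_parts, y_parts, froh_parts = [], [], []
    denom = panel.gmap.total_bp
    for label in classes:
        genos, truth = simulate_union_offspring(
            panel, label, n_per_class, seed=int(rng.integers(2**31))
        )
        ids = truth["sample_id"].tolist()
        segs = call_roh(genos, panel.sites, panel.gmap, roh_params, sample_ids=ids)
        X_parts.append(summarize_samples(segs, ids).to_numpy())
        y_parts.append(np.full(n_per_class, label, dtype=object))
        froh_parts.append(froh_per_sample(segs, ids, denom).to_numpy())
    return np.vstack(X_parts), np.concatenate(y_parts), np.concatenate(froh_parts)


@dataclass
class TrainedPRModel:
    """A fitted ensemble plus held-out evaluation metadata."""

    classifier: ParentalRelatednessClassifier
    confusion: pd.DataFrame
    holdout_accuracy: float
    n_per_class: int
    seed: int | None


def train_pr_classifier(
    panel: FounderPanel,
    classes: list[str],
    n_per_class: int = 1000,
    roh_params: ROHCallParams = ROHCallParams(),
    holdout_fraction: float = 0.2,
    seed: int | None = 0,
) -> TrainedPRModel:
    """Simulate offspring per class, call ROHs, featurize, and fit the
    ensemble; reports a held-out confusion matrix."""
    if n_per_class < 50:
        raise ConfigError("n_per_class must be >= 50")
    if len(set(classes)) < 2:
        raise ConfigError("need at least two distinct union classes")
    rng = np.random.default_rng(seed)
    X, y, _ = _simulate_training_features(panel, classes, n_per_class, roh_params, rng)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    order = [c for c in UNION_CLASS_LABELS if c in classes] + [
        c for c in classes if c not in UNION_CLASS_LABELS
    ]
    clf = ParentalRelatednessClassifier(
        class_order=tuple(order), random_state=int(rng.integers(2**31))
    ).fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    cm = confusion_matrix(y_te, pred, labels=clf.classes_)
    confusion = pd.DataFrame(cm, index=clf.classes_, columns=clf.classes_)
    return TrainedPRModel(
        classifier=clf,
        confusion=confusion,
        holdout_accuracy=float((pred == y_te).mean()),
        n_per_class=n_per_class,
        seed=seed,
    )


def classify_pr(
    classifier: ParentalRelatednessClassifier, features
) -> pd.DataFrame:
    """Classify feature rows; returns label, grouped label, generations of
    first-cousin ancestry, and normalized per-class scores."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    proba = classifier.predict_proba(X)
    labels = classifier.classes_[np.argmax(proba, axis=1)]
    out = pd.DataFrame(
        {
            "label": labels,
            "grouped_label": [group_label(l) for l in labels],
            "generations_of_1c": [generations_of_first_cousins(l) for l in labels],
        }
    )
    for k, c in enumerate(classifier.classes_):
        out[f"score_{c}"] = proba[:, k]
    return out


#: labels entering the highly consanguineous analysis subset
_HIGHLY_CONSANGUINEOUS = {
    "avuncular",
    "first_cousin_1g",
    "first_cousin_2g",
    "first_cousin_3g",
}


def select_highly_consanguineous(
    labels, froh, froh_max: float = 0.18
) -> np.ndarray:
    """Mask of individuals inferred to be offspring of first cousin or
    avuncular unions with F_ROH below the cutoff (the midpoint between the
    avuncular and sibling expectations)."""
    labels = np.asarray(labels)
    froh = np.asarray(froh, dtype=float)
    if labels.shape != froh.shape:
        raise StructuralError("labels and froh must be aligned")
    in_class = np.isin(labels, list(_HIGHLY_CONSANGUINEOUS))
    return in_class & (froh < froh_max)
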