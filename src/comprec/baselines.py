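"""Classical comparators: k-NN, SVM, decision tree, random forest.

All four run on a fixed position-wise one-hot featurization of the same
padded hairpin layout the networks see (PAD positions are all-zero), and
are scored through the identical thresholded-accuracy bookkeeping, so a
comparison with the networks differs only in the classifier.  Settings
are scikit-learn defaults except the stated overrides: 35 neighbors for
k-NN, depth cap 12 for the tree, 400 trees for the forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import DEFAULT_THETA, AccuracyResult
from .synthetic_data import (
    Dataset,
    HairpinExample,
    MAX_STRAND_LENGTH,
    encode,
    encode_dataset,
)

METHODS = ("KNN", "SVM", "TREE", "FOREST")


@dataclass(frozen=True)
class BaselineSpec:
    method: str
    knn_neighbors: int = 35
    tree_max_depth: int = 12
    forest_trees: int = 400

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _one_hot(tokens: np.ndarray) -> np.ndarray:
    # token ids 1..4 -> unit vectors; PAD (0) -> all-zero
    eye = np.zeros((5, 4))
    eye[1:] = np.eye(4)
    return eye[tokens].reshape(tokens.shape[0], -1)


def featurize(
    e: HairpinExample, max_strand_length: int = MAX_STRAND_LENGTH
) -> np.ndarray:
    """One-hot vector of length 4 * (2 * max_strand_length + loop_length)."""
    return _one_hot(encode(e, max_strand_length)[None, :])[0]


def featurize_dataset(
    ds: Dataset, max_strand_length: int = MAX_STRAND_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    tokens, labels = encode_dataset(ds, max_strand_length)
    return _one_hot(tokens), labels


def build_estimator(spec: BaselineSpec, seed: int = 0):
    if spec.method == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.knn_neighbors)
    if spec.method == "SVM":
        return SVC(random_state=seed)
    if spec.method == "TREE":
        return DecisionTreeClassifier(
            max_depth=spec.tree_max_depth, random_state=seed
        )
    return RandomForestClassifier(
        n_estimators=spec.forest_trees, random_state=seed
    )


def fit_baseline(spec: BaselineSpec, ds: Dataset, seed: int = 0):
    """Fit on (one-hot features, observed label) pairs of a training set."""
    if ds.role != "train":
        raise ValueError("baselines fit on train-role datasets only")
    if ds.N == 0:
        raise ValueError("empty dataset")
    X, y = featurize_dataset(ds)
    est = build_estimator(spec, seed)
    est.fit(X, y)
    return est


def baseline_accuracy(
    fitted, ds: Dataset, theta: float = DEFAULT_THETA
) -> AccuracyResult:
    """Hard predictions scored with the same accuracy rule as the networks."""
    X, t = featurize_dataset(ds)
    if X.shape[1] != fitted.n_features_in_:
        raise ValueError(
            f"feature length {X.shape[1]} != fitted {fitted.n_features_in_}"
        )
    pred_pos = fitted.predict(X) == 1
    correct = np.where(t == 1, pred_pos, ~pred_pos)
    return AccuracyResult(
        accuracy=float(correct.mean()),
        theta=theta,
        n_examples=ds.N,
        role=ds.role,
    )


def run_baseline_simulation(
    method: str,
    gp,
    rep_seed: int,
) -> tuple[AccuracyResult, AccuracyResult]:
    """Baseline counterpart of the network simulation: identical data path."""
    from .evaluation import build_simulation_data, _child_seeds

    train_ds, test_ds = build_simulation_data(gp, rep_seed)
    fit_seed = _child_seeds(rep_seed, 5)[3]
    fitted = fit_baseline(BaselineSpec(method), train_ds, seed=fit_seed)
    return (
        baseline_accuracy(fitted, train_ds),
        baseline_accuracy(fitted, test_ds),
    )
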