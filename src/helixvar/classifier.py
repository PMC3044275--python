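"""Sequence features and the max-margin helix-regularity classifier.

Each helix plus its 4-residue flanking context is encoded into a fixed
440-dimensional vector built from six composition blocks (whole helix,
N-terminus, C-terminus, middle, prior flank, after flank; 20 features each)
and four positional one-hot blocks (N1..N4, C4..C1, and the four positions
of each flank; 80 features each): 6·20 + 4·80 = 440.  Vectors are scaled to
unit Euclidean length so the linear kernel is a cosine-like dot product in
[0, 1].  A soft-margin linear SVM separates regular helices (+1) from
distorted ones (−1); feature weights are recovered from the support-vector
expansion w_j = Σ_i α_i y_i (x_i)_j and must reproduce the decision values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assembly import FLANK_WIDTH, HelixSegment
from .propensities import AMINO_ACIDS, C_POSITIONS, N_POSITIONS

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "TrainingSet",
    "MarginClassifier",
    "EvalMetrics",
    "partition_sequence",
    "encode",
    "build_training_set",
    "kernel",
    "train",
    "feature_weights",
    "evaluate",
    "holdout_evaluate",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_PRIOR_POSITIONS = tuple(f"P{i}" for i in range(1, FLANK_WIDTH + 1))
_AFTER_POSITIONS = tuple(f"A{i}" for i in range(1, FLANK_WIDTH + 1))


def _block(prefix: str, positions: Sequence[str] | None = None) -> list[str]:
    if positions is None:
        return [f"{prefix}_{a}" for a in AMINO_ACIDS]
    return [f"{prefix}_{p}_{a}" for p in positions for a in AMINO_ACIDS]


#: Frozen 440-feature naming: block order and within-block amino-acid order
#: never change.
FEATURE_NAMES: tuple[str, ...] = tuple(
    _block("helix_comp")
    + _block("nterm_comp")
    + _block("nterm", N_POSITIONS)
    + _block("cterm_comp")
    + _block("cterm", C_POSITIONS)
    + _block("mid_comp")
    + _block("prior_comp")
    + _block("prior", _PRIOR_POSITIONS)
    + _block("after_comp")
    + _block("after", _AFTER_POSITIONS)
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 440


def partition_sequence(segment: HelixSegment, max_length: int = 15):
    """Split a helix into N-terminus, middle, C-terminus and flank strings.

    N-terminus = positions 1..4, C-terminus = last four.  The middle is
    positions 4..6 for a length-8 helix and positions 4..(length−4)
    otherwise; position 4 belongs to both the N-terminus and the middle by
    construction.  Flank strings keep their validity masks.
    """
    n = segment.length
    if n < 8:
        raise ValueError("helix shorter than 8 residues cannot be partitioned")
    if n > max_length:
        raise ValueError(f"helix length {n} exceeds the configured maximum {max_length}")
    seq = segment.sequence
    nterm = seq[0:4]
    cterm = seq[-4:]
    middle = seq[3:6] if n == 8 else seq[3 : n - 4]
    return {
        "nterm": nterm,
        "middle": middle,
        "cterm": cterm,
        "prior": (segment.flank_before, segment.flank_before_mask),
        "after": (segment.flank_after, segment.flank_after_mask),
    }


def _composition(seq: str, mask=None) -> np.ndarray:
    out = np.zeros(20)
    valid = 0
    for i, a in enumerate(seq):
        if mask is not None and not mask[i]:
            continue
        j = _AA_INDEX.get(a)
        if j is None:
            if a != "-":
                warnings.warn(f"non-standard residue {a!r} ignored in encoding",
                              stacklevel=3)
            continue
        out[j] += 1
        valid += 1
    if valid:
        out /= valid
    return out


def _one_hot(seq: str, mask=None) -> np.ndarray:
    out = np.zeros(20 * len(seq))
    for i, a in enumerate(seq):
        if mask is not None and not mask[i]:
            continue
        j = _AA_INDEX.get(a)
        if j is None:
            if a != "-":
                warnings.warn(f"non-standard residue {a!r} ignored in encoding",
                              stacklevel=3)
            continue
        out[20 * i + j] = 1.0
    return out


def encode(segment: HelixSegment, max_length: int = 15) -> np.ndarray:
    """Encode one helix segment into the unit-normalized 440-vector."""
    parts = partition_sequence(segment, max_length=max_length)
    prior_seq, prior_mask = parts["prior"]
    after_seq, after_mask = parts["after"]
    x = np.concatenate(
        [
            _composition(segment.sequence),
            _composition(parts["nterm"]),
            _one_hot(parts["nterm"]),
            _composition(parts["cterm"]),
            _one_hot(parts["cterm"]),  # sequence order == C4..C1, C4 first
            _composition(parts["middle"]),
            _composition(prior_seq, prior_mask),
            _one_hot(prior_seq, prior_mask),
            _composition(after_seq, after_mask),
            _one_hot(after_seq, after_mask),
        ]
    )
    assert x.shape == (N_FEATURES,)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("degenerate segment encodes to the zero vector")
    return x / norm


@dataclass
class TrainingSet:
    """Unit-row feature matrix with ±1 labels and per-example provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, int)
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")

    def __len__(self) -> int:
        return len(self.y)


def build_training_set(
    positives: Sequence[HelixSegment],
    negatives: Sequence[HelixSegment],
    max_length: int = 15,
) -> TrainingSet:
    X = np.array([encode(s, max_length) for s in list(positives) + list(negatives)])
    y = np.array([1] * len(positives) + [-1] * len(negatives))
    prov = [s.source_id for s in list(positives) + list(negatives)]
    return TrainingSet(X=X, y=y, provenance=prov)


def kernel(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Dot-product (linear) kernel between two 440-feature vectors."""
    x = np.asarray(x, float)
    x_prime = np.asarray(x_prime, float)
    if x.shape != (N_FEATURES,) or x_prime.shape != (N_FEATURES,):
        raise ValueError("kernel expects two length-440 vectors")
    return float(x @ x_prime)


@dataclass
class MarginClassifier:
    """Trained soft-margin linear classifier.

    ``dual_coef`` holds α_i·y_i per support vector, so the decision value is
    Σ_i dual_coef_i ⟨sv_i, x⟩ + bias, identically w·x + bias with
    w = dual_coef @ support_vectors.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    weights: np.ndarray
    C: float = 1.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def decision_from_support(self, X: np.ndarray) -> np.ndarray:
        """Decision values via the explicit support-vector expansion."""
        return self.dual_coef @ (self.support_vectors @ np.atleast_2d(X).T) + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties at exactly 0 go to the positive class
        return np.where(self.decision_function(X) >= 0, 1, -1)


def train(D: TrainingSet, C: float = 1.0, seed: int = 0) -> MarginClassifier:
    """Fit the soft-margin linear SVM on a ±1-labeled training set."""
    from sklearn.svm import SVC

    if len(set(D.y)) < 2:
        raise ValueError("training requires both classes")
    svc = SVC(kernel="linear", C=C, random_state=seed)
    svc.fit(D.X, D.y)
    w = (svc.dual_coef_[0] @ svc.support_vectors_).ravel()
    return MarginClassifier(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        weights=w,
        C=C,
    )


def feature_weights(model: MarginClassifier):
    """Named feature weights w_j = Σ_i α_i y_i (x_i)_j, sortable by value."""
    import pandas as pd

    w = model.dual_coef @ model.support_vectors
    return pd.Series(w, index=list(FEATURE_NAMES), name="weight")


@dataclass
class EvalMetrics:
    """Precision/recall/F1 with per-fold values and pooled confusion counts."""

    precision: float
    recall: float
    f1: float
    per_fold: list
    confusion: dict

    @staticmethod
    def from_confusion(tp: int, fp: int, fn: int, tn: int,
                       per_fold: list | None = None) -> "EvalMetrics":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return EvalMetrics(precision=precision, recall=recall, f1=f1,
                           per_fold=per_fold or [],
                           confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn})


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    return tp, fp, fn, tn


def evaluate(D: TrainingSet, folds: int = 10, seed: int = 0,
             C: float = 1.0) -> EvalMetrics:
    """Stratified k-fold cross-validated precision, recall and F1.

    Pooled metrics are computed from the summed confusion counts over
    folds; per-fold metrics are also retained.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(D) < folds:
        raise ValueError("fewer examples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    totals = np.zeros(4, dtype=int)
    per_fold = []
    for tr, te in skf.split(D.X, D.y):
        if len(set(D.y[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        model = train(TrainingSet(D.X[tr], D.y[tr]), C=C, seed=seed)
        cm = _confusion(D.y[te], model.predict(D.X[te]))
        totals += np.array(cm)
        per_fold.append(EvalMetrics.from_confusion(*cm))
    return EvalMetrics.from_confusion(*(int(t) for t in totals), per_fold=per_fold)


def holdout_evaluate(D: TrainingSet, train_fraction: float = 0.70,
                     seed: int = 0, C: float = 1.0) -> EvalMetrics:
    """Single stratified train/test split evaluation (default 70/30)."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(D))
    tr, te = train_test_split(idx, train_size=train_fraction, random_state=seed,
                              stratify=D.y)
    model = train(TrainingSet(D.X[tr], D.y[tr]), C=C, seed=seed)
    return EvalMetrics.from_confusion(*_confusion(D.y[te], model.predict(D.X[te])))
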