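"""Linear-SVM augmentation experiment on binarized braingraphs.

Graphs are encoded as 0-1 upper-triangle edge-indicator vectors and fed
to a soft-margin linear SVM,

    min_{w, z, b}  (1/2) w·w + C Σ_i z_i
    s.t.           z_i >= 0,  y_i (w·x_i - b) >= 1 - z_i,

with prediction sign(w·x + b).  When every training point is replaced by
``fold`` augmented copies, the penalty must be rescaled to ``C / fold``
to keep the objective (and hence the optimum) comparable with the
non-augmented problem: duplicating each point ``fold`` times at
``C / fold`` leaves the loss term unchanged.

:func:`augmentation_experiment` compares, over a log10-C grid, a plain
arm (one consensus-average graph per training subject) against an
augmented arm (all ``C(R, k)`` subset-trim-average graphs per training
subject at penalty ``C / C(R, k)``); both arms are evaluated on the same
held-out consensus graphs, and the split is by subject so no augmented
graph of a test subject ever enters training.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC, LinearSVC

from .blurring import basic_average, newtonian_blur
from .graph_model import (
    AugmentationConfig,
    Parcellation,
    ValidationError,
    WeightedBraingraph,
)
from .synthetic_data import LabeledCohort

__all__ = [
    "SVMProblem",
    "ExperimentResult",
    "graph_to_features",
    "feature_matrix",
    "scale_penalty",
    "train_linear_svm",
    "split_subjects",
    "augmentation_experiment",
    "DEFAULT_LOG10C_GRID",
]

#: Default log10(C) grid: [-4, 2] in steps of 0.5.
DEFAULT_LOG10C_GRID = tuple(np.arange(-4.0, 2.01, 0.5))


def n_features(parcellation: Parcellation) -> int:
    n = parcellation.n_nodes
    return n * (n - 1) // 2


def _edge_index(parcellation: Parcellation) -> dict[tuple[int, int], int]:
    ids = [i for i, _ in parcellation.nodes]
    index = {}
    pos = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            index[(ids[a], ids[b])] = pos
            pos += 1
    return index


def graph_to_features(
    graph: WeightedBraingraph, parcellation: Parcellation
) -> np.ndarray:
    """0-1 upper-triangle edge-indicator vector of length n(n-1)/2.

    Positions follow lexicographic ``(u, v)`` order over the
    parcellation's node ids, so for 83 nodes the vector has 3403 entries
    and edge ``(1, 2)`` occupies position 0.
    """
    if graph.parcellation.nodes != parcellation.nodes:
        raise ValidationError(
            f"graph {graph.subject_id!r} is not over the given parcellation"
        )
    index = _edge_index(parcellation)
    x = np.zeros(len(index), dtype=np.float64)
    for e in graph.edges:
        x[index[e]] = 1.0
    return x


def feature_matrix(
    graphs: Sequence[WeightedBraingraph], parcellation: Parcellation
) -> np.ndarray:
    """Stack binary feature vectors of many graphs into an (m, d) matrix."""
    index = _edge_index(parcellation)
    X = np.zeros((len(graphs), len(index)), dtype=np.float64)
    for i, g in enumerate(graphs):
        if g.parcellation.nodes != parcellation.nodes:
            raise ValidationError(
                f"graph {g.subject_id!r} is not over the given parcellation"
            )
        for e in g.edges:
            X[i, index[e]] = 1.0
    return X


def scale_penalty(C: float, fold: int) -> float:
    """Rescale the SVM penalty for a ``fold``-times larger training set.

    Returns ``C / fold``; with each point duplicated ``fold`` times this
    preserves the value (and minimizer) of the soft-margin objective.
    """
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    if fold < 1:
        raise ValidationError(f"fold must be a positive integer, got {fold}")
    return C / fold


@dataclass
class SVMProblem:
    """A binary soft-margin SVM training problem."""

    features: np.ndarray  # (m, d)
    labels: np.ndarray  # (m,) of +1/-1
    penalty: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValidationError("features must be (m, d) with m matching labels")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValidationError("labels must be +1/-1")
        if self.penalty <= 0:
            raise ValidationError(f"penalty C must be positive, got {self.penalty}")


def train_linear_svm(
    problem: SVMProblem, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Solve the soft-margin linear SVM and return ``(w, b)``.

    Delegates the convex quadratic program to libsvm's exact dual solver
    (no intercept regularization), so the returned pair minimizes the
    stated objective to within solver tolerance.  Prediction is
    ``sign(w·x + b)``.
    """
    if len(np.unique(problem.labels)) < 2:
        raise ValidationError("training set must contain both classes")
    clf = SVC(kernel="linear", C=problem.penalty, tol=tol)
    clf.fit(problem.features, problem.labels)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def split_subjects(
    labels: Sequence[int], train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified subject-level train/test split.

    Within each class, ``round(train_fraction * n_class)`` subjects go to
    training; e.g. 1053 subjects split 737 / 316 at fraction 0.7 with a
    roughly balanced label.  Returns (train_indices, test_indices).
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValidationError(
                f"degenerate split for class {cls}: {n_train} of {len(idx)} in training"
            )
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclass
class ExperimentResult:
    """Accuracy curves over the log10(C) grid for both arms."""

    grid: list[float]
    rows: list[tuple[float, float, float, float]] = field(default_factory=list)
    # each row: (train_plain, test_plain, train_augmented, test_augmented)

    def __post_init__(self) -> None:
        for row in self.rows:
            if any(not 0 <= a <= 1 for a in row):
                raise ValidationError("accuracies must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["log10C", "train_plain", "test_plain", "train_augmented", "test_augmented"]
            )
            for logc, row in zip(self.grid, self.rows):
                writer.writerow([logc, *row])
        return path


def _accuracy(clf, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(clf.predict(X) == y))


def _fit_fast_linear(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    # Hinge-loss dual coordinate descent scales to the fold-times-larger
    # augmented training sets; iterations are capped, and a cap hit is a
    # solver budget, not an error.
    clf = LinearSVC(C=C, loss="hinge", max_iter=2000, tol=1e-4, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def augmentation_experiment(
    cohort: LabeledCohort,
    blur_config: AugmentationConfig | None = None,
    grid: Sequence[float] = DEFAULT_LOG10C_GRID,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> ExperimentResult:
    """Compare plain vs augmented linear-SVM training over a C grid.

    Subjects (never individual graphs) are split into train/test.  The
    plain arm trains on one consensus-average graph per training subject
    at penalty ``C``; the augmented arm trains on all ``C(R, k)``
    subset-trim-average graphs per training subject at penalty
    ``C / C(R, k)``.  Both arms are evaluated on the identical test set
    of consensus graphs; augmented graphs of test subjects are never
    built or used.  Train accuracy of each arm is measured on its own
    training set.
    """
    if blur_config is None:
        blur_config = AugmentationConfig()
    parcellation = cohort.ensembles[0].parcellation
    labels = np.asarray(cohort.labels)
    if min(np.sum(labels == 1), np.sum(labels == -1)) < 2:
        raise ValidationError("need at least 2 subjects per class")
    train_idx, test_idx = split_subjects(labels, train_fraction, seed)
    assert set(train_idx.tolist()).isdisjoint(test_idx.tolist())

    consensus = [basic_average(ens) for ens in cohort.ensembles]
    X_plain_train = feature_matrix([consensus[i] for i in train_idx], parcellation)
    y_plain_train = labels[train_idx]
    X_test = feature_matrix([consensus[i] for i in test_idx], parcellation)
    y_test = labels[test_idx]

    aug_graphs: list[WeightedBraingraph] = []
    y_aug: list[int] = []
    for i in train_idx:
        augmented = newtonian_blur(cohort.ensembles[i], blur_config)
        aug_graphs.extend(augmented.graphs)
        y_aug.extend([int(labels[i])] * len(augmented))
    X_aug_train = feature_matrix(aug_graphs, parcellation)
    y_aug_train = np.asarray(y_aug)
    fold = blur_config.n_subsets

    rows = []
    for log10c in grid:
        C = 10.0 ** float(log10c)
        clf_plain = _fit_fast_linear(X_plain_train, y_plain_train, C)
        clf_aug = _fit_fast_linear(X_aug_train, y_aug_train, scale_penalty(C, fold))
        rows.append(
            (
                _accuracy(clf_plain, X_plain_train, y_plain_train),
                _accuracy(clf_plain, X_test, y_test),
                _accuracy(clf_aug, X_aug_train, y_aug_train),
                _accuracy(clf_aug, X_test, y_test),
            )
        )
    return ExperimentResult(grid=[float(c) for c in grid], rows=rows)
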