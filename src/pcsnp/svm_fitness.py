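"""SVM training, grid-searched cross-validation, and accuracy evaluation.

This module is both the GA fitness function and the final classifier.  The
kernel machinery itself is scikit-learn's ``SVC`` (one-vs-one multiclass);
what is fixed here is the contract around it: the log-spaced hyperparameter
grids, stratified seeded folds, deterministic tie-breaking, and accuracy
semantics (overall fraction correct).  Genotype codes enter the SVM as raw
{0, 1, 2} values by default; no scaling is applied.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Default C grid: 13 powers of ten spanning 1e-6 .. 1e6.
DEFAULT_C_GRID = tuple(10.0 ** e for e in range(-6, 7))
#: Default RBF gamma grid: 21 powers of ten spanning 1e-10 .. 1e10.
DEFAULT_GAMMA_GRID = tuple(10.0 ** e for e in range(-10, 11))


@dataclass(frozen=True)
class KernelSpec:
    """A fully specified SVM kernel: kind plus tuned hyperparameters."""

    kind: str
    C: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"kind must be 'linear' or 'rbf', got {self.kind!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires a positive gamma")


@dataclass
class CVResult:
    best_params: KernelSpec
    cv_accuracy: float
    fold_accuracies: list


def _make_svc(spec: KernelSpec) -> SVC:
    if spec.kind == "linear":
        return SVC(kernel="linear", C=spec.C)
    return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)


def _fold_splits(y: np.ndarray, folds: int, seed: int, on_small_class: str):
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if counts.size < 2:
        raise ValueError("need at least 2 distinct classes")
    if min_count < folds:
        if on_small_class == "error":
            raise ValueError(
                f"smallest class has {min_count} member(s) < {folds} folds"
            )
        folds = max(2, min_count)
        warnings.warn(
            f"reducing folds to {folds}: smallest class has {min_count} member(s)",
            stacklevel=3,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def tune_and_score(
    X,
    y,
    kind: str = "linear",
    folds: int = 5,
    seed: int = 0,
    C_grid=None,
    gamma_grid=None,
    on_small_class: str = "shrink",
) -> CVResult:
    """Exhaustive grid search with stratified k-fold cross-validation.

    The grid is every combination of log10-spaced C values (13 by default)
    and, for the RBF kernel, gamma values (21 by default).  The best mean CV
    accuracy wins; exact ties break toward smaller C, then smaller gamma.
    Duplicate grid entries are collapsed, and the fold assignment is fully
    determined by *seed*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature column")
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    Cs = sorted(set(C_grid if C_grid is not None else DEFAULT_C_GRID))
    if kind == "rbf":
        gammas = sorted(set(gamma_grid if gamma_grid is not None else DEFAULT_GAMMA_GRID))
    else:
        gammas = [None]
    splits = _fold_splits(y, folds, seed, on_small_class)

    best: CVResult | None = None
    for C in Cs:
        for gamma in gammas:
            spec = KernelSpec(kind, C, gamma)
            accs = []
            for train_idx, test_idx in splits:
                clf = _make_svc(spec)
                clf.fit(X[train_idx], y[train_idx])
                accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best.cv_accuracy:
                best = CVResult(spec, mean_acc, accs)
    assert best is not None
    return best


def subset_fitness(
    mask,
    X,
    y,
    kind: str = "linear",
    folds: int = 5,
    seed: int = 0,
    C_grid=None,
    gamma_grid=None,
) -> float:
    """Cross-validated SVM accuracy of the columns selected by *mask*.

    This is the GA fitness: restrict the feature matrix to the masked
    columns, tune over the grid, and return the best mean CV accuracy.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: fitness is undefined on zero features")
    X = np.asarray(X, dtype=float)
    result = tune_and_score(
        X[:, mask], y, kind=kind, folds=folds, seed=seed,
        C_grid=C_grid, gamma_grid=gamma_grid,
    )
    return result.cv_accuracy


def final_evaluate(
    selected,
    train,
    test,
    kind: str = "linear",
    folds: int = 5,
    seed: int = 0,
    C_grid=None,
    gamma_grid=None,
) -> float:
    """Tune on the training set, refit, and score on the held-out test set.

    *selected* is a collection of SNP ids; *train* and *test* are
    :class:`~pcsnp.genotype_io.GenotypeMatrix` objects sharing the same SNP
    ids.  Hyperparameters come from k-fold CV on the training samples; the
    tuned model is refit on the full training set and its overall fraction
    of correct test predictions is returned.
    """
    ids = list(selected)
    if not ids:
        raise ValueError("selected feature set is empty")
    if train.snp_ids != test.snp_ids:
        raise ValueError("train and test must share identical SNP ids")
    indices = sorted(train.snp_index(s) for s in ids)  # order-independent
    X_train = train.values[:, indices].astype(float)
    X_test = test.values[:, indices].astype(float)
    y_train = np.asarray(train.labels)
    y_test = np.asarray(test.labels)
    cv = tune_and_score(
        X_train, y_train, kind=kind, folds=folds, seed=seed,
        C_grid=C_grid, gamma_grid=gamma_grid,
    )
    clf = _make_svc(cv.best_params)
    clf.fit(X_train, y_train)
    return float(np.mean(clf.predict(X_test) == y_test))
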