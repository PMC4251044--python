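"""One-vs-rest RBF-kernel SVM classification of discovered subtypes.

The training protocol mirrors the discovery study design: a stratified
90/10 split holds out an independent test set, the training side is
partitioned into 5 stratified folds for cross-validation, and one binary
maximum-margin classifier per class (RBF kernel, shared C and gamma) is
fitted on class-vs-rest labels.  Prediction takes the argmax of the
per-class decision scores.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from seqsubtype.descriptors import FeatureMatrix
from seqsubtype.errors import SeqSubtypeError

#: Hyperparameter grid used when none is given (the powers of two commonly
#: swept for RBF SVMs).
DEFAULT_C_GRID = tuple(2.0**e for e in range(-2, 9))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-8, 3))


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/independent split plus a 5-fold partition of train."""

    train_ids: tuple[str, ...]
    independent_ids: tuple[str, ...]
    fold_of: dict[str, int]  # train id -> fold in 1..n_folds
    n_folds: int
    seed: int

    def fold_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(i for i in self.train_ids if self.fold_of[i] == fold)


def make_split(
    ids: list[str],
    labels: list,
    train_fraction: float = 0.9,
    folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random split and fold assignment, deterministic per seed.

    Within each class, members are shuffled and ``round((1 - train_fraction)
    * n)`` of them go to the independent set (a singleton class stays in
    training).  Training members are then dealt round-robin into folds with
    a global counter, so fold sizes are near-equal overall and each fold's
    class proportions are within one member of the dataset's.
    """
    if len(ids) != len(labels):
        raise ValueError("ids and labels must align")
    by_class: dict = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    for lab, members in by_class.items():
        if len(members) < 1:
            raise ValueError(f"class {lab!r} has no members")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    independent: list[str] = []
    for lab in sorted(by_class, key=str):
        members = list(by_class[lab])
        rng.shuffle(members)
        n_ind = int(round(len(members) * (1.0 - train_fraction)))
        n_ind = min(n_ind, len(members) - 1)  # keep every class represented in training
        independent.extend(members[:n_ind])
        train.extend(members[n_ind:])
    fold_of = {rid: (pos % folds) + 1 for pos, rid in enumerate(train)}
    return SplitPlan(
        train_ids=tuple(train),
        independent_ids=tuple(independent),
        fold_of=fold_of,
        n_folds=folds,
        seed=seed,
    )


@dataclass
class OvRModel:
    """A fitted one-vs-rest RBF-SVM ensemble."""

    class_labels: tuple
    C: float
    gamma: float
    feature_dimension: int
    descriptor_name: str = ""
    _models: dict = field(default_factory=dict, repr=False)

    def decision_scores(self, features) -> np.ndarray:
        """Per-record, per-class real decision values (n x k)."""
        X = _as_array(features, self.feature_dimension)
        return np.column_stack([self._models[c].decision_function(X) for c in self.class_labels])

    def predict(self, features) -> np.ndarray:
        """Predicted label per record: argmax of the decision scores."""
        scores = self.decision_scores(features)
        idx = np.argmax(scores, axis=1)
        return np.array([self.class_labels[i] for i in idx])

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "OvRModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise SeqSubtypeError(f"{path} is not a saved OvRModel")
        return model


def _as_array(features, expected_dim: int | None = None) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        X = features.values
    else:
        X = np.asarray(features, dtype=float)
    if expected_dim is not None and X.shape[1] != expected_dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {expected_dim}")
    return X


def train_ovr(
    features,
    labels,
    C: float = 8.0,
    gamma: float = 2.0,
    balanced: bool = False,
    descriptor_name: str = "",
) -> OvRModel:
    """Fit one binary RBF-SVM per class against the rest."""
    X = _as_array(features)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y.tolist()), key=str))
    if len(classes) < 2:
        raise ValueError("train_ovr requires at least 2 classes")
    models = {}
    for c in classes:
        clf = SVC(
            kernel="rbf", C=C, gamma=gamma,
            class_weight="balanced" if balanced else None,
        )
        clf.fit(X, (y == c).astype(int))
        models[c] = clf
    name = descriptor_name or (features.descriptor_name if isinstance(features, FeatureMatrix) else "")
    return OvRModel(
        class_labels=classes, C=C, gamma=gamma,
        feature_dimension=X.shape[1], descriptor_name=name, _models=models,
    )


def decision_scores(model: OvRModel, features) -> np.ndarray:
    """Module-level alias for :meth:`OvRModel.decision_scores`."""
    return model.decision_scores(features)


def cross_val_predict(
    features: FeatureMatrix,
    labels: dict | pd.Series,
    plan: SplitPlan,
    C: float,
    gamma: float,
    balanced: bool = False,
):
    """Pooled out-of-fold predictions and scores over the plan's folds.

    Returns ``(ids, true, predicted, scores)`` where ``scores`` is an
    (n_train x k) array of decision values aligned with the sorted class
    labels of the full training side.
    """
    lab = dict(labels)
    id_pos = {rid: i for i, rid in enumerate(features.row_ids)}
    classes = tuple(sorted({lab[i] for i in plan.train_ids}, key=str))
    ids_out, y_true, y_pred = [], [], []
    scores_rows = []
    for fold in range(1, plan.n_folds + 1):
        val_ids = plan.fold_ids(fold)
        fit_ids = tuple(i for i in plan.train_ids if plan.fold_of[i] != fold)
        X_fit = features.values[[id_pos[i] for i in fit_ids]]
        y_fit = [lab[i] for i in fit_ids]
        model = train_ovr(X_fit, y_fit, C=C, gamma=gamma, balanced=balanced)
        X_val = features.values[[id_pos[i] for i in val_ids]]
        sc = model.decision_scores(X_val)
        # align fold score columns with the global class order
        full = np.full((len(val_ids), len(classes)), -np.inf)
        for col, c in enumerate(model.class_labels):
            full[:, classes.index(c)] = sc[:, col]
        pred = [classes[i] for i in np.argmax(full, axis=1)]
        ids_out.extend(val_ids)
        y_true.extend(lab[i] for i in val_ids)
        y_pred.extend(pred)
        scores_rows.append(full)
    return ids_out, y_true, y_pred, np.vstack(scores_rows), classes


def grid_search(
    features: FeatureMatrix,
    labels,
    plan: SplitPlan,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    balanced: bool = False,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing mean cross-validated overall accuracy.

    Only the training folds are used; ties resolve to the smallest C, then
    the smallest gamma.
    """
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    lab = dict(labels) if not isinstance(labels, dict) else labels
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            _, y_true, y_pred, _, _ = cross_val_predict(features, lab, plan, C, gamma, balanced)
            acc = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    return best[1], best[2]
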