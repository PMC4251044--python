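"""Feature importance: between-class ANOVA ranking and pairwise t-tests.

``anova_rank`` scores every descriptor feature with a one-way ANOVA F
statistic across the subtype labels; only the relative ranking is
interpreted.  ``pairwise_ttests`` runs a Welch (unequal-variance)
two-sample t-test per feature for every unordered class pair -- cluster
sizes coming out of subtype discovery are typically very unequal, which
makes the pooled-variance test anticonservative -- and lists, per pair,
the three features with the largest two-class F score.  Raw p-values are
reported; an optional Bonferroni correction is available for users who
want family-wise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif

from seqsubtype.descriptors import FeatureMatrix


@dataclass(frozen=True)
class FeatureRanking:
    feature_names: tuple[str, ...]
    f_scores: np.ndarray
    p_values: np.ndarray
    order: np.ndarray  # indices sorted by descending F

    def top(self, n: int) -> list[tuple[str, float]]:
        return [(self.feature_names[i], float(self.f_scores[i])) for i in self.order[:n]]


@dataclass(frozen=True)
class PairwiseTestTable:
    feature_names: tuple[str, ...]
    class_labels: tuple
    #: p_values[f] is a k x k symmetric matrix (diagonal 1) for feature f
    p_values: np.ndarray  # (n_features, k, k)
    #: top three features (by two-class F) per unordered class pair
    top3: dict
    degenerate: tuple  # (feature, class_a, class_b) triples with zero variance


def _check_classes(labels) -> tuple[np.ndarray, list]:
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()), key=str)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
    return y, classes


def anova_rank(features: FeatureMatrix, labels) -> FeatureRanking:
    """Rank features by one-way ANOVA F across classes (descending)."""
    y, _ = _check_classes(labels)
    X = features.values
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    p = np.where(np.isnan(p), 1.0, p)
    order = np.argsort(-F, kind="stable")
    return FeatureRanking(
        feature_names=features.feature_names, f_scores=F, p_values=p, order=order
    )


def pairwise_ttests(
    features: FeatureMatrix, labels, alpha: float = 0.05, bonferroni: bool = False
) -> PairwiseTestTable:
    """Welch t-test per feature per unordered class pair, plus top-3 lists.

    Features with zero variance in both groups of a pair get p = 1 and are
    flagged as degenerate.  With ``bonferroni=True`` p-values are
    multiplied by the number of (feature, pair) tests and clipped at 1.
    """
    y, classes = _check_classes(labels)
    X = features.values
    k = len(classes)
    nf = X.shape[1]
    pvals = np.ones((nf, k, k))
    degenerate = []
    top3: dict = {}
    n_tests = nf * k * (k - 1) // 2
    for ai in range(k):
        for bi in range(ai + 1, k):
            a_rows = X[y == classes[ai]]
            b_rows = X[y == classes[bi]]
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(a_rows, b_rows, equal_var=False, axis=0)
            p = np.asarray(p, dtype=float)
            for f in np.flatnonzero(np.isnan(p)):
                degenerate.append((features.feature_names[f], classes[ai], classes[bi]))
            p = np.where(np.isnan(p), 1.0, p)
            if bonferroni:
                p = np.minimum(p * n_tests, 1.0)
            pvals[:, ai, bi] = pvals[:, bi, ai] = p
            pair_labels = np.concatenate([np.zeros(len(a_rows)), np.ones(len(b_rows))])
            with np.errstate(invalid="ignore", divide="ignore"):
                F, _ = f_classif(np.vstack([a_rows, b_rows]), pair_labels)
            F = np.nan_to_num(F, nan=0.0)
            best = np.argsort(-F, kind="stable")[:3]
            top3[(classes[ai], classes[bi])] = [features.feature_names[i] for i in best]
    return PairwiseTestTable(
        feature_names=features.feature_names,
        class_labels=tuple(classes),
        p_values=pvals,
        top3=top3,
        degenerate=tuple(degenerate),
    )


def significant_count(table: PairwiseTestTable, feature: str, alpha: float = 0.05) -> int:
    """Number of class pairs where ``feature`` differs at level ``alpha``."""
    f = table.feature_names.index(feature)
    k = len(table.class_labels)
    iu = np.triu_indices(k, 1)
    return int((table.p_values[f][iu] < alpha).sum())
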