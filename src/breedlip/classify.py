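"""Supervised classification of binned lipidomics profiles.

Two complementary models, following the flow-infusion metabolomics
protocol this package reimplements:

* **PC-LDA** — PCA to denoise/compress, then linear discriminant analysis
  on the retained scores. The eigenvalues (Tw) of the between/within
  scatter eigenproblem quantify class separation on each discriminant
  function.
* **Bootstrapped random forest** — repeated stratified 2/3 train / 1/3
  test splits; each split fits a forest and scores the held-out third by
  the classification *margin* (vote fraction for the true class minus the
  best vote fraction for any other class), the area under the ROC curve
  and plain accuracy. A binary model is *adequate* when margin > 0.2 and
  AUC or ACC > 0.8.

The per-bootstrap engine also computes out-of-split permutation importance
(mean decrease in test accuracy) on request; ranking reuses the exact same
splits and forests as classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .matrix import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapScheme",
    "ClassModelReport",
    "PCLDAResult",
    "pc_lda",
    "rf_bootstrap_classify",
    "MARGIN_THRESHOLD",
    "SCORE_THRESHOLD",
]

#: Adequacy thresholds for binary models: margin > 0.2 and (AUC or ACC) > 0.8.
MARGIN_THRESHOLD = 0.2
SCORE_THRESHOLD = 0.8


def _as_values(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values()
    return np.asarray(matrix, dtype=float)


# ---------------------------------------------------------------------------
# PC-LDA
# ---------------------------------------------------------------------------

@dataclass
class PCLDAResult:
    """PC-LDA fit: discriminant scores and separation eigenvalues."""

    df_scores: np.ndarray  # (n_samples, n_dfs)
    tw: np.ndarray  # eigenvalues, non-increasing
    pcs_retained: int
    explained_variance: float
    classes: list


def pc_lda(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence,
    var_kept: float = 0.95,
) -> PCLDAResult:
    """PCA followed by LDA on the retained principal-component scores.

    PCA is on mean-centred data; the smallest number of PCs reaching
    ``var_kept`` cumulative variance is retained (additionally capped at
    n_samples - n_classes so the within-class scatter stays invertible).
    LDA solves the generalized eigenproblem Sb v = tw Sw v; the k-th
    eigenvalue Tw_k measures between/within separation on discriminant
    function k. At most n_classes - 1 DFs are returned. A singular Sw is
    ridge-regularized with a logged epsilon.
    """
    X = _as_values(matrix)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("pc_lda needs at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    if not (0 < var_kept <= 1):
        raise ValueError("var_kept must be in (0, 1]")

    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    keep = var > var.max() * 1e-12  # drop numerically null directions
    var, U, s = var[keep], U[:, keep], s[keep]
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_kept - 1e-12) + 1)
    k = max(1, min(k, len(s), X.shape[0] - len(classes)))
    scores = U[:, :k] * s[:k]
    explained = float(frac[k - 1])

    # scatter matrices on PC scores
    overall = scores.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for c in range(len(classes)):
        Sc = scores[y_idx == c]
        mu = Sc.mean(axis=0)
        d = Sc - mu
        Sw += d.T @ d
        Sb += len(Sc) * np.outer(mu - overall, mu - overall)

    try:
        tw, vec = scipy.linalg.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        eps = 1e-8 * (np.trace(Sw) / k if np.trace(Sw) > 0 else 1.0)
        logger.warning("pc_lda: singular within-class scatter; ridge eps=%g", eps)
        tw, vec = scipy.linalg.eigh(Sb, Sw + eps * np.eye(k))

    order = np.argsort(tw)[::-1]
    n_df = min(len(classes) - 1, k)
    tw = np.clip(tw[order][:n_df], 0.0, None)
    vec = vec[:, order][:, :n_df]
    return PCLDAResult(
        df_scores=scores @ vec,
        tw=tw,
        pcs_retained=k,
        explained_variance=explained,
        classes=list(classes),
    )


# ---------------------------------------------------------------------------
# Bootstrapped random forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapScheme:
    """Resampling and forest settings for classification/feature selection."""

    n_bootstraps: int = 100
    train_fraction: float = 2.0 / 3.0
    ntree: int = 1000
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_bootstraps < 1 or self.ntree < 1:
            raise ValueError("n_bootstraps and ntree must be positive")


@dataclass
class ClassModelReport:
    """Bootstrap-averaged scores for one binary comparison."""

    comparison: tuple
    margin: float
    auc: float
    acc: float
    n_bootstraps: int
    per_bootstrap: list[tuple[float, float, float]] = field(repr=False,
                                                            default_factory=list)

    @property
    def adequate(self) -> bool:
        return (self.margin > MARGIN_THRESHOLD
                and (self.auc > SCORE_THRESHOLD or self.acc > SCORE_THRESHOLD))

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "margin": self.margin,
            "auc": self.auc,
            "acc": self.acc,
            "n_bootstraps": self.n_bootstraps,
            "adequate": self.adequate,
            "per_bootstrap": [list(t) for t in self.per_bootstrap],
        }


def _split(
    y_idx: np.ndarray, frac: float, stratified: bool, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; at least one sample per class per side."""
    train: list[int] = []
    test: list[int] = []
    groups = ([np.flatnonzero(y_idx == c) for c in np.unique(y_idx)]
              if stratified else [np.arange(len(y_idx))])
    for idx in groups:
        perm = rng.permutation(idx)
        n_tr = int(np.clip(round(frac * len(idx)), 1, len(idx) - 1))
        train.extend(perm[:n_tr])
        test.extend(perm[n_tr:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def _tree_predict(tree, X32: np.ndarray) -> np.ndarray:
    """Hard class prediction via the fitted Cython tree, skipping the
    per-call validation of the public predict (these calls dominate the
    bootstrap loop's cost on small inputs)."""
    values = tree.tree_.predict(X32)  # leaf class counts per sample
    if values.ndim == 3:  # (n, n_outputs, n_classes) in some versions
        values = values[:, 0, :]
    return np.argmax(values, axis=1)


def _forest_votes(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-tree hard class votes, shape (ntree, n_samples), values in {0, 1}."""
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    return np.stack([_tree_predict(t, X32) for t in forest.estimators_])


def _permutation_importance(
    forest: RandomForestClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-tree out-of-split mean decrease in accuracy, one value per feature.

    The classical random-forest importance: break the feature's pairing
    with the held-out samples, remeasure each tree's own accuracy, and
    average the per-tree decrease over all trees of the forest. Scoring
    trees individually (rather than the pooled forest vote) keeps redundant
    features — adduct/isotopologue clusters where permuting one member
    barely moves the ensemble — at small positive scores instead of
    collapsing them to exactly zero.

    On the very small held-out sets of pairwise models (a third of 15-24
    samples) a single random permutation is extremely noisy, so there the
    *exact expectation* over all permutations is computed instead: a
    permuted column assigns each held-out value to each row with equal
    probability, so evaluating the tree on the full row x value grid and
    averaging gives the expected permuted accuracy with no sampling noise.
    The grid grows with the square of the held-out count, so larger test
    sets (where one permutation is already well averaged) use the classic
    single-permutation estimate. Trees that never use a feature contribute
    exactly 0 either way.
    """
    ntree = len(forest.estimators_)
    n_test, n_feat = X_test.shape
    X32 = np.ascontiguousarray(X_test, dtype=np.float32)
    votes = _forest_votes(forest, X_test)  # (ntree, n_test) hard votes
    tree_acc = (votes == y_test[None, :]).mean(axis=1)
    exact = n_test <= 14

    perms: dict[int, np.ndarray] = {}
    decrease = np.zeros(n_feat)
    for t, tree in enumerate(forest.estimators_):
        feats = np.unique(tree.tree_.feature)
        feats = feats[feats >= 0]
        if len(feats) == 0:
            continue
        if exact:
            # for each feature, n_test copies of X_test; copy k carries
            # value X_test[k, j] in column j for every row
            stacked = np.repeat(X32[None, :, :], len(feats) * n_test, axis=0)
            for row, j in enumerate(feats):
                block = stacked[row * n_test:(row + 1) * n_test]
                block[:, :, j] = X32[:, j][:, None]
            preds = _tree_predict(tree, stacked.reshape(-1, n_feat))
            preds = preds.reshape(len(feats), n_test, n_test)
            # mean over value draws, then over held-out rows
            perm_acc = (preds == y_test[None, None, :]).mean(axis=(1, 2))
        else:
            # one shared permutation per feature keeps trees consistent
            stacked = np.repeat(X32[None, :, :], len(feats), axis=0)
            for row, j in enumerate(feats):
                if j not in perms:
                    perms[j] = rng.permutation(n_test)
                stacked[row, :, j] = X32[perms[j], j]
            preds = _tree_predict(tree, stacked.reshape(-1, n_feat))
            preds = preds.reshape(len(feats), n_test)
            perm_acc = (preds == y_test[None, :]).mean(axis=1)
        decrease[feats] += tree_acc[t] - perm_acc

    return decrease / ntree


def _bootstrap_runs(
    X: np.ndarray,
    y_idx: np.ndarray,
    scheme: BootstrapScheme,
    importance: bool = False,
) -> tuple[list[tuple[float, float, float]], np.ndarray | None]:
    """Run the bootstrap loop shared by classification and feature ranking.

    Returns per-bootstrap (margin, auc, acc) triples and, when requested,
    permutation importances averaged over the same splits/forests.
    """
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.n_bootstraps)
    triples: list[tuple[float, float, float]] = []
    imp_sum = np.zeros(X.shape[1]) if importance else None
    for child in children:
        rng = np.random.default_rng(child)
        train, test = _split(y_idx, scheme.train_fraction, scheme.stratified, rng)
        forest = RandomForestClassifier(
            n_estimators=scheme.ntree,
            max_features="sqrt",
            n_jobs=1,
            random_state=int(rng.integers(2 ** 31)),
        ).fit(X[train], y_idx[train])
        proba = forest.predict_proba(X[test])
        p_true = proba[np.arange(len(test)), y_idx[test]]
        margin = float(np.mean(2.0 * p_true - 1.0))
        auc = float(roc_auc_score(y_idx[test], proba[:, 1]))
        acc = float(np.mean(np.argmax(proba, axis=1) == y_idx[test]))
        triples.append((margin, auc, acc))
        if importance:
            imp_sum += _permutation_importance(forest, X[test], y_idx[test], rng)
    imp = imp_sum / scheme.n_bootstraps if importance else None
    return triples, imp


def _check_binary(labels: Sequence, classes: Sequence | None):
    y = np.asarray(labels)
    uniq = list(np.unique(y))
    if classes is not None:
        classes = list(classes)
        if sorted(map(str, classes)) != sorted(map(str, uniq)):
            raise ValueError(f"classes {classes} do not match labels {uniq}")
    else:
        classes = uniq
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got {len(classes)} classes")
    y_idx = (y == classes[1]).astype(np.int64)
    for c, cls in enumerate(classes):
        n = int(np.sum(y_idx == c))
        if n < 3:
            raise ValueError(f"class {cls!r} has only {n} samples (need >= 3)")
    return y_idx, tuple(classes)


def rf_bootstrap_classify(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence,
    scheme: BootstrapScheme | None = None,
    classes: Sequence | None = None,
) -> ClassModelReport:
    """Bootstrapped random-forest scores for one binary comparison.

    Each bootstrap draws a stratified 2/3 train / 1/3 test split, fits a
    forest of ``scheme.ntree`` trees, and scores the held-out samples;
    report scores are arithmetic means over bootstraps. ``classes`` fixes
    label order (class 1 = second entry) so vote probabilities and AUC are
    oriented consistently; by default classes sort alphabetically.
    """
    scheme = scheme or BootstrapScheme()
    X = _as_values(matrix)
    y_idx, classes = _check_binary(labels, classes)
    triples, _ = _bootstrap_runs(X, y_idx, scheme)
    arr = np.asarray(triples)
    return ClassModelReport(
        comparison=classes,
        margin=float(arr[:, 0].mean()),
        auc=float(arr[:, 1].mean()),
        acc=float(arr[:, 2].mean()),
        n_bootstraps=scheme.n_bootstraps,
        per_bootstrap=[tuple(t) for t in triples],
    )
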