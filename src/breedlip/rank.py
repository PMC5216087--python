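"""Per-feature explanatory-signal ranking and correlation clustering.

Three complementary statistics are computed for every feature of a binary
comparison:

* **RFIS** — random-forest importance score: the mean decrease in held-out
  classification accuracy when the feature is permuted, averaged over the
  same bootstrap splits and forests used for classification. Redundant
  features (adducts/isotopologues of one compound) share credit, so RFIS
  values are small in absolute terms (~1e-3) even for strong signals.
* **univariate AUC** — rank-based (Mann-Whitney) AUC, folded to >= 0.5.
* **Welch t-test** — per-feature p-values with Benjamini-Hochberg FDR
  q-values.

Features are ranked by RFIS (ties: p ascending, then name). Pearson
correlation clustering groups candidate features whose |r| exceeds a
threshold (default 0.8) into single-linkage components — the signature of
different ionisation products of a single metabolite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .classify import (BootstrapScheme, ClassModelReport, _as_values,
                       _bootstrap_runs, _check_binary)
from .matrix import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["RankedFeature", "CorrelationCluster", "rank_features",
           "rank_with_report", "correlation_clusters", "assign_clusters"]


def _near_constant(X: np.ndarray) -> np.ndarray:
    """Columns whose variation is at floating-point noise level."""
    return X.std(axis=0) <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))


@dataclass
class RankedFeature:
    """Composite ranking record for one feature in one binary comparison."""

    name: str
    mz: float
    rt: float
    rfis: float
    uni_auc: float
    p_value: float
    q_value: float
    direction: str  # "elevated" | "decreased" in class 1 relative to class 2
    degenerate: bool = False  # zero-variance feature, stats not meaningful
    cluster_id: str | None = None


def rank_features(
    matrix: FeatureMatrix,
    labels: Sequence,
    scheme: BootstrapScheme | None = None,
    classes: Sequence | None = None,
) -> list[RankedFeature]:
    """Rank every feature of a binary comparison by RFIS / AUC / t-test.

    ``classes`` fixes orientation: ``direction`` is called for the *second*
    entry (class 1) relative to the first. Zero-variance features are
    flagged degenerate with p = 1 and RFIS = 0. The returned list is sorted
    by RFIS descending, ties broken by p ascending then feature name.
    """
    return rank_with_report(matrix, labels, scheme, classes)[0]


def rank_with_report(
    matrix: FeatureMatrix,
    labels: Sequence,
    scheme: BootstrapScheme | None = None,
    classes: Sequence | None = None,
) -> tuple[list[RankedFeature], "ClassModelReport"]:
    """Rank features and score the comparison from one set of forests.

    Classification scores and permutation importances come from the same
    bootstrap splits and forests — the fits are shared, halving the cost of
    running :func:`rank_features` next to ``rf_bootstrap_classify``.
    """
    scheme = scheme or BootstrapScheme()
    X = _as_values(matrix)
    y_idx, classes = _check_binary(labels, classes)
    triples, rfis = _bootstrap_runs(X, y_idx, scheme, importance=True)
    arr = np.asarray(triples)
    report = ClassModelReport(
        comparison=classes,
        margin=float(arr[:, 0].mean()),
        auc=float(arr[:, 1].mean()),
        acc=float(arr[:, 2].mean()),
        n_bootstraps=scheme.n_bootstraps,
        per_bootstrap=[tuple(t) for t in triples],
    )

    a = X[y_idx == 1]  # class 1 (focal)
    b = X[y_idx == 0]
    degenerate = _near_constant(X)
    if degenerate.any():
        logger.warning("rank_features: %d zero-variance features flagged",
                       int(degenerate.sum()))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isfinite(t_res.pvalue), t_res.pvalue, 1.0)
    p[degenerate] = 1.0
    q = multipletests(p, method="fdr_bh")[1]

    # Mann-Whitney AUC via rank sums, vectorised over features
    n1, n0 = len(a), len(b)
    ranks = scipy.stats.rankdata(X, axis=0)
    r1 = ranks[y_idx == 1].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc_folded = np.maximum(auc, 1.0 - auc)

    rfis = np.where(degenerate, 0.0, rfis)
    direction = np.where(a.mean(axis=0) >= b.mean(axis=0),
                         "elevated", "decreased")

    ranked = [
        RankedFeature(
            name=name,
            mz=float(matrix.features["mz"].iloc[j]),
            rt=float(matrix.features["rt"].iloc[j]),
            rfis=float(rfis[j]),
            uni_auc=float(auc_folded[j]),
            p_value=float(p[j]),
            q_value=float(q[j]),
            direction=str(direction[j]),
            degenerate=bool(degenerate[j]),
        )
        for j, name in enumerate(matrix.feature_names)
    ]
    ranked.sort(key=lambda f: (-f.rfis, f.p_value, f.name))
    return ranked, report


@dataclass
class CorrelationCluster:
    """A single-linkage component of the |r| > threshold correlation graph."""

    cluster_id: str
    members: list[str]
    seed_feature: str  # first member in the supplied candidate order


def correlation_clusters(
    matrix: FeatureMatrix,
    candidates: Sequence[str] | None = None,
    threshold: float = 0.8,
) -> list[CorrelationCluster]:
    """Group candidate features into |r| > threshold correlation clusters.

    Pearson r is computed over all samples; components are single-linkage
    (any chain of supra-threshold edges joins a cluster) and singletons are
    kept. Candidate order is preserved and taken as the ranking order, so
    each cluster's ``seed_feature`` is its best-ranked member. Constant
    features have undefined r and are excluded with a warning.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    names = list(candidates) if candidates is not None else matrix.feature_names
    sub = matrix.subset_features(names)
    X = sub.values()

    constant = _near_constant(X)
    if constant.any():
        dropped = [n for n, c in zip(names, constant) if c]
        logger.warning("correlation_clusters: excluding %d constant features "
                       "(undefined r): %s", len(dropped), dropped[:5])
        names = [n for n, c in zip(names, constant) if not c]
        X = X[:, ~constant]
    if not names:
        return []

    r = np.corrcoef(X, rowvar=False)
    adj = (np.abs(np.atleast_2d(r)) > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    clusters = []
    seen: dict[int, int] = {}  # component label -> cluster index, in rank order
    for j, name in enumerate(names):
        c = int(comp[j])
        if c not in seen:
            seen[c] = len(clusters)
            clusters.append(CorrelationCluster(
                cluster_id=f"C{len(clusters) + 1}", members=[], seed_feature=name))
        clusters[seen[c]].members.append(name)
    return clusters


def assign_clusters(
    ranked: list[RankedFeature], clusters: list[CorrelationCluster],
) -> list[RankedFeature]:
    """Attach cluster ids to ranked features in place; returns the list."""
    by_name = {m: c.cluster_id for c in clusters for m in c.members}
    for f in ranked:
        f.cluster_id = by_name.get(f.name)
    return ranked
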