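"""Iterative removal of diet-confounded signals from a feature matrix.

In an owner-fed cohort, diet is partially collinear with breed: the signals
that best separate a confounded breed meta-class are largely diet-derived.
The filter removes them by walking a strictly decreasing schedule of RFIS
cutoffs computed on that meta-class comparison. At each cutoff all features
whose RFIS exceeds it are removed, together with any feature correlated at
|r| > 0.8 with a removed one (adducts/isotopologues of the same compound,
one-hop expansion). The meta-class random-forest model is refit on the
reduced matrix; the walk stops at the first cutoff where the model has
*collapsed* — its bootstrapped margin no longer exceeds the 0.2 adequacy
floor — i.e. the point where no confounded signal worth removing remains.
Tw of the post-removal PC-LDA is logged at every step for the audit trail
but is not the stopping statistic (it has no published threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .classify import (BootstrapScheme, MARGIN_THRESHOLD, pc_lda,
                       rf_bootstrap_classify)
from .matrix import FeatureMatrix
from .rank import RankedFeature

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "FilterStep", "filter_confounder",
           "DEFAULT_SCHEDULE", "HEURISTIC_CUTOFF"]

#: Default cutoff schedule: log-uniform descent over the plausible RFIS range.
DEFAULT_SCHEDULE: tuple[float, ...] = (
    0.01, 0.0056, 0.0032, 0.0018, 0.001, 0.00056, 0.00032, 0.00018, 0.0001,
)

#: The heuristic final cutoff reported for this protocol in prior work.
HEURISTIC_CUTOFF: float = 0.0003


@dataclass
class FilterStep:
    """One cutoff evaluation along the filtering trajectory."""

    rfis_cutoff: float
    n_removed_direct: int
    n_removed_correlated: int
    metaclass_margin: float
    metaclass_tw: float


@dataclass
class FilterReport:
    """Audit record of a confounder-filter run."""

    cutoff_trajectory: list[FilterStep] = field(default_factory=list)
    final_cutoff: float = float("nan")
    removed_features: list[str] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0
    collapsed: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoff_trajectory"] = [asdict(s) for s in self.cutoff_trajectory]
        return d


def _correlated_expansion(
    matrix: FeatureMatrix, direct: list[str], threshold: float,
) -> list[str]:
    """Features outside ``direct`` with |r| > threshold to any direct member."""
    if not direct:
        return []
    X = matrix.values()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    near0 = sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    sd[near0] = np.inf  # constant features can never exceed the threshold
    Z = X / sd
    names = matrix.feature_names
    direct_idx = [names.index(n) for n in direct] if len(direct) < 40 else None
    if direct_idx is None:  # positional lookup via dict for larger sets
        pos = {n: j for j, n in enumerate(names)}
        direct_idx = [pos[n] for n in direct]
    r = Z.T @ Z[:, direct_idx] / X.shape[0]  # (n_features, n_direct)
    hit = np.abs(r).max(axis=1) > threshold
    direct_set = set(direct)
    return [n for j, n in enumerate(names) if hit[j] and n not in direct_set]


def filter_confounder(
    matrix: FeatureMatrix,
    metaclass_labels: Sequence,
    ranked: list[RankedFeature],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    corr_threshold: float = 0.8,
    scheme: BootstrapScheme | None = None,
) -> tuple[FeatureMatrix, FilterReport]:
    """Filter confounded signals until the meta-class model collapses.

    ``metaclass_labels`` is aligned with the matrix samples; entries that
    are None/NaN mark samples excluded from the meta-class comparison (they
    stay in the returned matrix). ``ranked`` must come from
    :func:`breedlip.rank.rank_features` on the same comparison. Returns the
    matrix filtered at the first collapsing cutoff (or the last cutoff,
    with ``collapsed=False`` and a warning, if the schedule is exhausted)
    plus the full trajectory.
    """
    scheme = scheme or BootstrapScheme()
    schedule = list(schedule)
    if any(c <= 0 for c in schedule):
        raise ValueError("cutoffs must be positive")
    if any(schedule[i] <= schedule[i + 1] for i in range(len(schedule) - 1)):
        raise ValueError("schedule must be strictly decreasing")

    labels = np.asarray(metaclass_labels, dtype=object)
    mask = np.array([l is not None and l == l for l in labels])  # NaN-safe
    sample_ids = [s for s, m in zip(matrix.sample_ids, mask) if m]
    y = labels[mask]

    report = FilterReport(n_before=matrix.n_features)
    rfis = {f.name: f.rfis for f in ranked}

    filtered = matrix
    removed: list[str] = []
    for cutoff in schedule:
        direct = [f.name for f in ranked if f.rfis > cutoff]
        correlated = _correlated_expansion(matrix, direct, corr_threshold)
        removal = direct + correlated
        filtered = matrix.drop_features(removal)
        sub = filtered.subset_samples(sample_ids)
        model = rf_bootstrap_classify(sub, y, scheme)
        tw1 = float(pc_lda(sub, y).tw[0]) if sub.n_features >= 2 else 0.0
        report.cutoff_trajectory.append(FilterStep(
            rfis_cutoff=cutoff,
            n_removed_direct=len(direct),
            n_removed_correlated=len(correlated),
            metaclass_margin=model.margin,
            metaclass_tw=tw1,
        ))
        removed = removal
        report.final_cutoff = cutoff
        if model.margin <= MARGIN_THRESHOLD:
            report.collapsed = True
            break

    if schedule and not report.collapsed:
        logger.warning(
            "filter_confounder: schedule exhausted without collapse "
            "(final margin %.3f at cutoff %g)",
            report.cutoff_trajectory[-1].metaclass_margin, report.final_cutoff)
    if not schedule:
        filtered = matrix

    report.removed_features = sorted(removed, key=lambda n: -rfis.get(n, 0.0))
    report.n_after = filtered.n_features
    return filtered, report
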