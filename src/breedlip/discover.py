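"""All-pairs breed modelling and breed-unique signal discovery.

``pairwise_grid`` scores every unordered breed pair with the bootstrapped
random forest and records which comparisons clear the adequacy thresholds
(margin > 0.2 and AUC or ACC > 0.8). ``unique_signals`` then looks for
*breed-unique* features: a breed is pursued only if enough of its pairwise
models are adequate (default >= 6 of 8); a candidate feature must be
top-ranked (RFIS and t-test p below thresholds) with a consistent
direction relative to the focal breed in **every** adequate comparison of
that breed; and a candidate shared by two breeds is a common discriminating
series, not a unique signal, so it is discarded for both.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .classify import BootstrapScheme, ClassModelReport, rf_bootstrap_classify
from .matrix import FeatureMatrix
from .rank import rank_features, rank_with_report

logger = logging.getLogger(__name__)

__all__ = ["PairwiseGrid", "UniqueBreedSignal", "pairwise_grid", "unique_signals"]


def _pair_seed(base_seed: int, a: str, b: str) -> int:
    """Deterministic per-pair seed (< 2**31), independent of pair order."""
    key = "|".join(sorted((str(a), str(b)))).encode()
    h = np.random.SeedSequence([base_seed, zlib.crc32(key)])
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class PairwiseGrid:
    """Reports for every unordered breed pair, with adequacy bookkeeping.

    When built with ``collect_rankings=True`` the per-pair feature rankings
    (from the same forests as the scores) are kept in ``rankings``, keyed by
    the sorted pair with class 1 = the lexicographically later breed.
    """

    breeds: list[str]
    reports: dict[tuple[str, str], ClassModelReport] = field(default_factory=dict)
    rankings: dict[tuple[str, str], list] = field(default_factory=dict, repr=False)

    def report(self, a: str, b: str) -> ClassModelReport:
        return self.reports[tuple(sorted((a, b)))]

    @property
    def adequate_count(self) -> dict[str, int]:
        counts = {b: 0 for b in self.breeds}
        for (a, b), rep in self.reports.items():
            if rep.adequate:
                counts[a] += 1
                counts[b] += 1
        return counts

    def adequate_partners(self, breed: str) -> list[str]:
        return [b if a == breed else a
                for (a, b), rep in sorted(self.reports.items())
                if breed in (a, b) and rep.adequate]

    def to_dict(self) -> dict:
        return {
            "breeds": self.breeds,
            "reports": {f"{a}|{b}": rep.to_dict()
                        for (a, b), rep in sorted(self.reports.items())},
            "adequate_count": self.adequate_count,
        }


def pairwise_grid(
    matrix: FeatureMatrix,
    breeds: Sequence,
    scheme: BootstrapScheme | None = None,
    collect_rankings: bool = False,
) -> PairwiseGrid:
    """Score all unordered breed pairs (36 for nine breeds).

    Each pair gets its own deterministic seed derived from ``scheme.seed``
    and the pair's breed names, so single pairs can be reproduced without
    rerunning the grid. With ``collect_rankings=True`` the same forests
    also yield per-pair feature rankings (RFIS from identical bootstrap
    splits), which :func:`unique_signals` can consume without refitting.
    """
    scheme = scheme or BootstrapScheme()
    breeds = np.asarray(breeds)
    labels = sorted(map(str, np.unique(breeds)))
    if len(labels) < 2:
        raise ValueError("pairwise_grid needs at least 2 breeds")
    grid = PairwiseGrid(breeds=labels)
    for a, b in combinations(labels, 2):
        sel = np.isin(breeds, (a, b))
        sub = matrix.subset_samples([s for s, m in zip(matrix.sample_ids, sel) if m])
        pair_scheme = replace(scheme, seed=_pair_seed(scheme.seed, a, b))
        if collect_rankings:
            ranked, report = rank_with_report(
                sub, breeds[sel], pair_scheme, classes=(a, b))
            grid.rankings[(a, b)] = ranked
            grid.reports[(a, b)] = report
        else:
            grid.reports[(a, b)] = rf_bootstrap_classify(
                sub, breeds[sel], pair_scheme, classes=(a, b))
    return grid


@dataclass
class UniqueBreedSignal:
    """A feature top-ranked in every adequate model of exactly one breed."""

    breed: str
    name: str
    mz: float
    rt: float
    direction: str  # elevated | decreased in the breed vs all its comparators
    support: int  # number of the breed's adequate comparisons
    rfis_min: float  # worst RFIS across those comparisons
    p_max: float  # worst t-test p across those comparisons


def unique_signals(
    grid: PairwiseGrid,
    matrix: FeatureMatrix,
    breeds: Sequence,
    min_adequate: int = 6,
    rfis_min: float = 0.002,
    p_max: float = 0.05,
    scheme: BootstrapScheme | None = None,
    strict_all_pairs: bool = False,
) -> list[UniqueBreedSignal]:
    """Discover breed-unique signals from the pairwise grid.

    Breeds with fewer than ``min_adequate`` adequate comparisons are not
    pursued. For each remaining breed the candidate set is the intersection
    over all its adequate comparisons (all comparisons if
    ``strict_all_pairs``) of features with RFIS > ``rfis_min`` and
    p < ``p_max``, required to keep one direction relative to the focal
    breed throughout. Features that are candidates for more than one breed
    are discarded as shared series. Rankings reuse the per-pair seeds of
    the grid, so the forests match the grid's models.
    """
    scheme = scheme or BootstrapScheme()
    breeds_arr = np.asarray(breeds)
    counts = grid.adequate_count
    eligible = [b for b in grid.breeds if counts[b] >= min_adequate]
    logger.info("unique_signals: pursuing %s (adequate counts %s)",
                eligible, counts)

    rank_cache: dict[tuple[str, str], list] = {}

    def ranked_for(focal: str, other: str):
        key = tuple(sorted((focal, other)))
        if key not in rank_cache:
            if key in grid.rankings:  # same forests as the grid's scores
                rank_cache[key] = grid.rankings[key]
            else:
                sel = np.isin(breeds_arr, key)
                sub = matrix.subset_samples(
                    [s for s, m in zip(matrix.sample_ids, sel) if m])
                pair_scheme = replace(scheme, seed=_pair_seed(scheme.seed, *key))
                # orientation: class 1 = key[1]; flip below when focal = key[0]
                rank_cache[key] = rank_features(
                    sub, breeds_arr[sel], pair_scheme, classes=key)
        flip = focal == key[0]
        out = {}
        for f in rank_cache[key]:
            direction = f.direction
            if flip:
                direction = "elevated" if direction == "decreased" else "decreased"
            out[f.name] = (f.rfis, f.p_value, direction)
        return out

    candidates: dict[str, dict[str, tuple[str, int, float, float]]] = {}
    for focal in eligible:
        partners = (grid.adequate_partners(focal) if not strict_all_pairs
                    else [b for b in grid.breeds if b != focal])
        support = len(partners)
        per_pair = []
        for other in partners:
            stats = ranked_for(focal, other)
            per_pair.append({
                n: v for n, v in stats.items()
                if v[0] > rfis_min and v[1] < p_max
            })
        if not per_pair:
            continue
        common = set(per_pair[0])
        for d in per_pair[1:]:
            common &= set(d)
        found = {}
        for n in common:
            dirs = {d[n][2] for d in per_pair}
            if len(dirs) != 1:
                continue  # inconsistent direction across comparisons
            found[n] = (
                dirs.pop(),
                support,
                min(d[n][0] for d in per_pair),
                max(d[n][1] for d in per_pair),
            )
        candidates[focal] = found

    shared = {
        n for i, a in enumerate(candidates)
        for b in list(candidates)[i + 1:]
        for n in set(candidates[a]) & set(candidates[b])
    }
    out: list[UniqueBreedSignal] = []
    for breed in eligible:
        for n, (direction, support, worst_rfis, worst_p) in sorted(
                candidates.get(breed, {}).items()):
            if n in shared:
                continue
            out.append(UniqueBreedSignal(
                breed=breed,
                name=n,
                mz=float(matrix.features.loc[n, "mz"]),
                rt=float(matrix.features.loc[n, "rt"]),
                direction=direction,
                support=support,
                rfis_min=worst_rfis,
                p_max=worst_p,
            ))
    return out
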