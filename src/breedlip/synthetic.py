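"""Synthetic lipidomics cohorts with known ground truth.

Emulates the statistical structure a breed-discrimination analysis has to
cope with in an owner-maintained dog cohort: nine breed classes of 7-12
animals, ~2500 LC-MS features per profile, correlated adduct/isotopologue
clusters, a breed meta-class axis, a diet effect partially collinear with
breed (one "Labrador-analogue" breed eats both diets, the others are
near-pure), and a handful of single-breed-unique signals. Every planted
effect is recorded in a :class:`SyntheticTruth` ledger so downstream stages
can be scored for recovery.

Intensity model (log2 scale), per sample s and feature f with base
metabolite b(f):

    log2 x_sf = baseline_f + effect_{b(f)}(s) + bio_{s,b(f)} + eps_sf

``baseline_f`` is uniform over ~3 orders of magnitude (typical LC-MS
dynamic range); ``effect`` is the planted breed/diet shift in log2
fold-change units; ``bio`` is per-(sample, metabolite) biological noise
shared by a metabolite's adduct/isotope satellites — sharing it is what
makes within-cluster Pearson |r| exceed 0.8, exactly as co-ionisation
products of one compound co-vary in real data; ``eps`` is independent
technical noise. Matrices are returned on the raw intensity scale (2**log2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .masses import C13_DELTA
from .matrix import FeatureMatrix, feature_name, _dedupe

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate"]

#: Canonical nine-breed cohort (abbreviation -> cohort size).
DEFAULT_BREEDS: tuple[tuple[str, int], ...] = (
    ("Be", 12), ("Ch", 7), ("CS", 12), ("Da", 8), ("GR", 12),
    ("Gh", 12), ("GS", 12), ("LR", 12), ("Ma", 9),
)

# satellite m/z offsets: 13C isotopologue, NH4-vs-H adduct, Na-vs-H adduct
_SATELLITE_DELTAS = (C13_DELTA, 17.026549, 21.981944)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the cohort conditions emulated.

    ``samples_per_breed`` bounds (7-12) apply when breed sizes are drawn
    rather than given explicitly. ``noise_sd`` is biological (shared within
    an adduct cluster), ``tech_sd`` technical (independent); both are log2
    units.
    """

    n_breeds: int = 9
    breed_sizes: tuple[tuple[str, int], ...] | None = DEFAULT_BREEDS
    samples_min: int = 7
    samples_max: int = 12
    n_features: int = 2500
    n_base_metabolites: int = 1900
    diet_classes: tuple[str, str] = ("chicken", "red_meat")
    group1: tuple[str, ...] = ("Ch", "Da", "Gh")
    metaclass2: tuple[str, ...] = ("Ch", "Da", "Ma", "GR")
    mixed_diet_breed: str = "LR"  # the Labrador analogue
    diet_purity: float = 0.9  # P(majority diet) for non-mixed breeds
    n_diet_features: int = 40
    n_metaclass1_features: int = 20
    n_metaclass2_features: int = 6
    n_shared_features: int = 35
    #: shared series span >= 3 scattered breeds: a 2-breed set is barely
    #: distinguishable from a unique marker whenever that one pair models
    #: poorly, which is not the structure the uniqueness rule assumes
    shared_breeds_range: tuple[int, int] = (3, 4)
    #: shared-series effects are moderate relative to breed-unique markers,
    #: which show near-complete per-breed separation in real profiles
    shared_effect_scale: float = 0.65
    unique_plan: tuple[tuple[str, int, str], ...] = (
        ("Ch", 5, "decreased"), ("GR", 7, "elevated"), ("Gh", 1, "decreased"),
    )
    effect_log2fc: float = 1.0
    noise_sd: float = 0.45
    tech_sd: float = 0.2
    mz_range: tuple[float, float] = (200.0, 1000.0)
    rt_range: tuple[float, float] = (60.0, 600.0)
    baseline_log2_range: tuple[float, float] = (10.0, 20.0)
    seed: int = 0

    def resolve_breeds(self, rng: np.random.Generator) -> list[tuple[str, int]]:
        if self.breed_sizes is not None and len(self.breed_sizes) == self.n_breeds:
            return [(b, int(n)) for b, n in self.breed_sizes]
        names = [f"B{i + 1}" for i in range(self.n_breeds)]
        sizes = rng.integers(self.samples_min, self.samples_max + 1,
                             size=self.n_breeds)
        return list(zip(names, (int(s) for s in sizes)))

    def validate(self) -> None:
        if self.n_features < self.n_base_metabolites:
            raise ValueError("n_features must be >= n_base_metabolites")
        if not (0.5 <= self.diet_purity <= 1.0):
            raise ValueError("diet_purity must be in [0.5, 1]")
        if not (0 < self.samples_min <= self.samples_max):
            raise ValueError("invalid samples_per_breed range")
        lo, hi = self.shared_breeds_range
        if not (2 <= lo <= hi):
            raise ValueError("shared features must span >= 2 breeds "
                             "(a 1-breed shared feature would be unique)")
        if hi >= self.n_breeds:
            raise ValueError("shared features must leave some breeds unshifted")
        n_planted = (self.n_diet_features + self.n_metaclass1_features
                     + self.n_metaclass2_features + self.n_shared_features
                     + sum(k for _, k, _ in self.unique_plan))
        if n_planted > self.n_base_metabolites:
            raise ValueError(
                f"{n_planted} planted base metabolites exceed "
                f"n_base_metabolites={self.n_base_metabolites}"
            )
        for _, _, direction in self.unique_plan:
            if direction not in ("elevated", "decreased"):
                raise ValueError(f"unknown direction {direction!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of every planted effect, by feature name.

    Satellites inherit their parent metabolite's planted effects and are
    therefore included in the planted sets. ``cluster_members`` maps each
    base-metabolite feature to its satellites (all correlations planted
    positive); ``unique_features`` maps breed -> {feature: direction}.
    """

    metaclass1_features: set[str] = field(default_factory=set)
    metaclass2_features: set[str] = field(default_factory=set)
    diet_features: set[str] = field(default_factory=set)
    unique_features: dict[str, dict[str, str]] = field(default_factory=dict)
    shared_features: dict[str, list[str]] = field(default_factory=dict)
    cluster_members: dict[str, list[str]] = field(default_factory=dict)

    def all_unique(self) -> set[str]:
        return {f for d in self.unique_features.values() for f in d}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["metaclass1_features"] = sorted(self.metaclass1_features)
        payload["metaclass2_features"] = sorted(self.metaclass2_features)
        payload["diet_features"] = sorted(self.diet_features)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            metaclass1_features=set(raw["metaclass1_features"]),
            metaclass2_features=set(raw["metaclass2_features"]),
            diet_features=set(raw["diet_features"]),
            unique_features=raw["unique_features"],
            shared_features=raw["shared_features"],
            cluster_members=raw["cluster_members"],
        )


def _assign_diets(
    breeds: Sequence[str], breed_of: np.ndarray, config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-sample diet labels with breed-diet collinearity.

    Breeds in ``group1`` eat mostly chicken, the rest mostly red meat, the
    mixed-diet breed is a 50/50 split (both classes guaranteed present).
    """
    chicken, red_meat = config.diet_classes
    diets = np.empty(len(breed_of), dtype=object)
    for b in breeds:
        idx = np.flatnonzero(breed_of == b)
        if b == config.mixed_diet_breed:
            p_chicken = 0.5
        elif b in config.group1:
            p_chicken = config.diet_purity
        else:
            p_chicken = 1.0 - config.diet_purity
        draws = rng.random(len(idx)) < p_chicken
        if b == config.mixed_diet_breed and len(idx) >= 2:
            if draws.all():
                draws[-1] = False
            elif not draws.any():
                draws[-1] = True
        diets[idx] = np.where(draws, chicken, red_meat)
    return diets


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (FeatureMatrix, sample metadata, SyntheticTruth).

    Deterministic under ``config.seed``: the same config yields
    byte-identical outputs.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- samples -----------------------------------------------------------
    breed_sizes = config.resolve_breeds(rng)
    breeds = [b for b, _ in breed_sizes]
    breed_of = np.concatenate([[b] * n for b, n in breed_sizes])
    n_samples = len(breed_of)
    sample_ids = [f"{b}{i + 1:02d}"
                  for b, n in breed_sizes for i in range(n)]
    diets = _assign_diets(breeds, breed_of, config, rng)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "breed": breed_of,
        "diet": diets,
        "age_months": rng.integers(8, 121, n_samples),
        "sex": rng.choice(["F", "M"], n_samples),
        "weight_kg": np.round(rng.uniform(1.8, 44.2, n_samples), 1),
    })

    # -- feature map: bases and their satellites ---------------------------
    n_base = config.n_base_metabolites
    n_sat = config.n_features - n_base
    base_mz = rng.uniform(*config.mz_range, n_base)
    base_rt = rng.uniform(*config.rt_range, n_base)
    sat_parent = rng.integers(0, n_base, n_sat)
    sat_kind = rng.choice(len(_SATELLITE_DELTAS), n_sat, p=(0.6, 0.25, 0.15))

    parent = np.concatenate([np.arange(n_base), sat_parent])
    mz = np.concatenate([
        base_mz, base_mz[sat_parent] + np.array(_SATELLITE_DELTAS)[sat_kind]])
    rt = np.concatenate([base_rt, base_rt[sat_parent]])
    names = _dedupe(feature_name(m, t) for m, t in zip(mz, rt))

    # -- planted effect sets (disjoint draws over bases) -------------------
    n_unique_total = sum(k for _, k, _ in config.unique_plan)
    n_other = (config.n_diet_features + config.n_metaclass1_features
               + config.n_metaclass2_features + config.n_shared_features)
    chosen = rng.choice(n_base, size=n_other, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = chosen[cursor:cursor + k]
        cursor += k
        return out

    diet_bases = take(config.n_diet_features)
    mc1_bases = take(config.n_metaclass1_features)
    mc2_bases = take(config.n_metaclass2_features)
    shared_bases = take(config.n_shared_features)

    # breed-unique markers sit on satellite-free bases: each marker is a
    # single low-abundance signal, not an adduct series
    has_sat = np.zeros(n_base, dtype=bool)
    has_sat[sat_parent] = True
    free = np.setdiff1d(np.flatnonzero(~has_sat), chosen)
    if len(free) < n_unique_total:
        raise ValueError("infeasible config: not enough satellite-free bases "
                         "for the requested unique markers")
    uniq_pool = rng.choice(free, size=n_unique_total, replace=False)
    upos = 0
    unique_bases = {}
    for b, k, direction in config.unique_plan:
        unique_bases[b] = (uniq_pool[upos:upos + k], direction)
        upos += k

    # shared series: multi-breed discriminators (broad inter-breed profile
    # differences that are *not* unique to any single breed)
    lo, hi = config.shared_breeds_range
    shared_sets: dict[int, tuple[list[str], float]] = {}
    for base in shared_bases:
        k = int(rng.integers(lo, min(hi, len(breeds) - 1) + 1))
        who = sorted(rng.choice(breeds, size=k, replace=False))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        shared_sets[int(base)] = (who, sign)

    # -- per-sample, per-base effect matrix (log2 units) -------------------
    fc = config.effect_log2fc
    effect = np.zeros((n_samples, n_base))
    red_meat_mask = diets == config.diet_classes[1]
    effect[np.ix_(red_meat_mask, diet_bases)] += fc  # red meat elevated
    g1 = np.isin(breed_of, config.group1)
    effect[np.ix_(g1, mc1_bases)] -= fc  # decreased in Ch/Da/Gh analogues
    g2 = np.isin(breed_of, config.metaclass2)
    effect[np.ix_(g2, mc2_bases)] -= fc  # decreased in Ch/Da/Ma/GR analogues
    for b, (bases, direction) in unique_bases.items():
        sign = 1.0 if direction == "elevated" else -1.0
        effect[np.ix_(breed_of == b, bases)] += sign * fc
    for base, (who, sign) in shared_sets.items():
        effect[np.ix_(np.isin(breed_of, who), [base])] += (
            sign * fc * config.shared_effect_scale)

    # -- intensities -------------------------------------------------------
    baseline = rng.uniform(*config.baseline_log2_range, n_base)
    sat_offset = rng.uniform(-3.0, -1.0, n_sat)  # satellites dimmer than parent
    bio = rng.normal(0.0, config.noise_sd, size=(n_samples, n_base))
    tech = rng.normal(0.0, config.tech_sd, size=(n_samples, config.n_features))

    feat_baseline = np.concatenate([baseline, baseline[sat_parent] + sat_offset])
    log2x = feat_baseline[None, :] + effect[:, parent] + bio[:, parent] + tech
    matrix = FeatureMatrix.from_arrays(2.0 ** log2x, sample_ids, mz, rt, names)

    # -- truth ledger ------------------------------------------------------
    members: dict[int, list[str]] = {}
    for f, p in enumerate(parent):
        members.setdefault(int(p), []).append(names[f])

    def named(bases: np.ndarray) -> set[str]:
        return {n for b in bases for n in members[int(b)]}

    truth = SyntheticTruth(
        metaclass1_features=named(mc1_bases),
        metaclass2_features=named(mc2_bases),
        diet_features=named(diet_bases),
        unique_features={
            b: {n: direction for n in named(bases)}
            for b, (bases, direction) in unique_bases.items()
        },
        shared_features={n: who for base, (who, _) in shared_sets.items()
                         for n in members[base]},
        cluster_members={names[int(b)]: members[int(b)][1:]
                         for b in range(n_base) if len(members[int(b)]) > 1},
    )
    return matrix, meta, truth
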