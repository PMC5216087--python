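"""Run configuration: every threshold of the workflow in one place.

A :class:`RunConfig` carries the protocol's default constants (0.01 m/z
bin; 100 bootstraps; ntree 1000; margin floor 0.2; AUC/ACC 0.8; RFIS
presets 0.003 / 0.002 / 0.0003; |r| 0.8; 5 ppm) plus the synthetic-cohort
settings, and round-trips through YAML unchanged. One top-level seed fans
out deterministically to per-stage seeds via named SeedSequence spawning,
so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import BootstrapScheme
from .confound import DEFAULT_SCHEDULE
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "stage_seed", "STAGES"]

#: Pipeline stages, in execution order; index = seed-derivation offset.
STAGES = ("simulate", "bin", "metaclass", "rank", "filter", "grid",
          "unique", "annotate")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence([seed, stage index]), kept below 2**31."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Full workflow configuration with the protocol's default constants."""

    seed: int = 0
    outdir: str = "breedlip_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    bin_width: float = 0.01
    n_bootstraps: int = 100
    train_fraction: float = 2.0 / 3.0
    ntree: int = 1000
    var_kept: float = 0.95

    margin_threshold: float = 0.2
    score_threshold: float = 0.8
    rfis_metaclass: float = 0.003  # explanatory-signal preset, meta-class models
    rfis_pairwise: float = 0.002  # top-ranked preset, pairwise models
    rfis_floor: float = 0.0003  # heuristic collapse-era cutoff
    corr_threshold: float = 0.8
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    ppm_window: float = 5.0
    min_adequate: int = 6
    filter_schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    filter_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("bin_width", "margin_threshold", "score_threshold",
                     "rfis_metaclass", "rfis_pairwise", "rfis_floor",
                     "corr_threshold", "q_threshold", "p_threshold",
                     "ppm_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)

    def scheme(self, stage: str) -> BootstrapScheme:
        return BootstrapScheme(
            n_bootstraps=self.n_bootstraps,
            train_fraction=self.train_fraction,
            ntree=self.ntree,
            seed=stage_seed(self.seed, stage),
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_schedule"] = list(self.filter_schedule)
        syn = d["synthetic"]
        for key in ("breed_sizes", "diet_classes", "group1", "metaclass2",
                    "unique_plan", "mz_range", "rt_range",
                    "baseline_log2_range", "shared_breeds_range"):
            if syn.get(key) is not None:
                syn[key] = [list(x) if isinstance(x, tuple) else x
                            for x in syn[key]]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", {})
        if syn:
            syn = dict(syn)
            for key in ("breed_sizes", "unique_plan"):
                if syn.get(key) is not None:
                    syn[key] = tuple(tuple(x) for x in syn[key])
            for key in ("diet_classes", "group1", "metaclass2", "mz_range",
                        "rt_range", "baseline_log2_range",
                        "shared_breeds_range"):
                if syn.get(key) is not None:
                    syn[key] = tuple(syn[key])
        if raw.get("filter_schedule") is not None:
            raw["filter_schedule"] = tuple(raw["filter_schedule"])
        return cls(synthetic=SyntheticConfig(**syn), **raw)
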