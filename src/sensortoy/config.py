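"""Run configuration: every constant of the study in one flat record.

Defaults reproduce the deployed study conditions: 110 Hz sampling, dot
delays 0.8/0.6/0.4 s, 30 s roadrunner and 60 s maze segments each played
twice, 60 s warm-up, 4 Hz low-pass cut-off, percentile threshold 16 and
alpha = .05.  Configs round-trip through flat YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .compare import ALPHA
from .features import FILTER_CUTOFF_HZ, FILTER_ORDER
from .games import MAZE_SEGMENT_S, ROADRUNNER_DELAYS, ROADRUNNER_SEGMENT_S, WARMUP_S
from .players import PERCENTILE_CUTOFF, SAMPLE_RATE_HZ, CohortConfig


@dataclass
class RunConfig:
    cohort_size: int = 95
    prevalence: float = 0.5
    low_mean: float = CohortConfig.low_mean
    low_sd: float = CohortConfig.low_sd
    typical_mean: float = CohortConfig.typical_mean
    typical_sd: float = CohortConfig.typical_sd
    control_skill_sd: float = CohortConfig.control_skill_sd
    sample_rate_hz: float = SAMPLE_RATE_HZ
    delay_lod0: float = ROADRUNNER_DELAYS[0]
    delay_lod1: float = ROADRUNNER_DELAYS[1]
    delay_lod2: float = ROADRUNNER_DELAYS[2]
    roadrunner_segment_s: float = ROADRUNNER_SEGMENT_S
    maze_segment_s: float = MAZE_SEGMENT_S
    warmup_s: float = WARMUP_S
    filter_cutoff_hz: float = FILTER_CUTOFF_HZ
    filter_order: int = FILTER_ORDER
    percentile_cutoff: int = PERCENTILE_CUTOFF
    alpha: float = ALPHA
    seed: int = 0
    output_dir: str = "results"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            low_mean=self.low_mean, low_sd=self.low_sd,
            typical_mean=self.typical_mean, typical_sd=self.typical_sd,
            control_skill_sd=self.control_skill_sd,
        )

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.cohort_size < 0:
            raise ValueError("cohort_size must be nonnegative")
        if self.sample_rate_hz <= 2 * self.filter_cutoff_hz:
            raise ValueError("sample rate must exceed twice the filter cut-off")

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
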