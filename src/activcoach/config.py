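"""Run configuration: a flat, validated YAML surface over the pipeline.

Every key has a default, so an empty config is a valid desk-scale run on a
synthetic cohort.  Seeds are part of the config and are stamped (with the
config hash) into every artifact the run writes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError
from .records import CohortSpec, GoalProfile


class GoalConfig(BaseModel):
    daily_step_goal: int = 10_000
    weekly_step_goal: int = 70_000
    daily_mpa_goal_min: float = 21.45
    daily_vpa_goal_min: float = 10.7
    weekly_mpa_goal_min: float = Field(150.0, ge=0)
    weekly_vpa_goal_min: float = 75.0
    daily_sedentary_goal_s: int = 8 * 3600
    daily_sleep_goal_h: float = 8.0
    daily_goal_score: int = 3

    def build(self) -> GoalProfile:
        return GoalProfile(weekly_goal_vector=[self.daily_goal_score] * 7,
                           **self.model_dump())


class CohortConfig(BaseModel):
    n_participants: int = 16
    n_days: int = 34
    activity_mix: list[float] = [0.35, 0.25, 0.20, 0.12, 0.08]
    minutes_per_day: int = 1440
    ima_band_noise: float = 0.0

    def build(self, seed: int) -> CohortSpec:
        return CohortSpec(seed=seed, **self.model_dump())


class ForecasterSettings(BaseModel):
    n_steps: int = 7
    filters: tuple[int, int] = (64, 32)
    kernel_size: int = 3
    pool_size: int = 2
    epochs: int = 200
    batch_size: int = 50
    learning_rate: float = 0.001
    validation_fraction: float = 0.05


class ClassifierSettings(BaseModel):
    hidden_layer_sizes: tuple[int, ...] = (32, 32, 16, 16, 16)
    epochs: int = 200
    learning_rate: float = 0.001
    validation_fraction: float = 0.05


class RunConfig(BaseModel):
    input_dir: str | None = None      # directory of per-participant CSVs
    output_dir: str = "activcoach-output"
    seed: int = 0
    interval_coverage_c: float = 1.28
    goals: GoalConfig = GoalConfig()
    cohort: CohortConfig = CohortConfig()
    forecaster: ForecasterSettings = ForecasterSettings()
    classifier: ClassifierSettings = ClassifierSettings()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; missing file fields fall back to defaults.

    Raises :class:`ConfigError` naming the offending key on invalid values.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"])
                         for e in exc.errors())
        raise ConfigError(f"invalid configuration key(s): {keys}") from exc
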