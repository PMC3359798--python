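"""YAML run configuration with strict (unknown-key-rejecting) validation.

A typo in a rate name silently becoming a default would corrupt a study,
so every model forbids extra keys and validation errors name the field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synthetic import CohortSpec, Dist, TimeGrid

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistCfg(_Strict):
    mean: float
    sd: float = 0.0

    def to_dist(self) -> Dist:
        return Dist(self.mean, self.sd)


class TimeGridCfg(_Strict):
    start: float = 0.0
    stop: float = 60.0
    step: float = 1.0


class BloodCfg(_Strict):
    c_in: DistCfg = DistCfg(mean=0.069, sd=0.013)  # mM/min
    k_out: DistCfg = DistCfg(mean=0.031, sd=0.0016)  # 1/min
    hct: float = Field(default=0.45, ge=0.0, le=1.0)


class RegionRatesCfg(_Strict):
    k_in_prime: DistCfg
    k_out_prime: DistCfg
    v_blood: DistCfg = DistCfg(mean=0.13, sd=0.02)


class CohortCfg(_Strict):
    n_per_stage: int = Field(default=20, ge=1)
    control_stage: str = "control"
    # stage -> region -> rates
    stages: dict[str, dict[str, RegionRatesCfg]]

    @field_validator("stages")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("at least one stage is required")
        for stage, regions in v.items():
            if not stage or not regions:
                raise ValueError(f"stage {stage!r} must be non-empty and have regions")
        return v


class FitCfg(_Strict):
    v_ees_fixed: Optional[float] = 0.20
    v_now_fixed: Optional[float] = 0.03
    t_end: Optional[float] = None


class RunConfig(_Strict):
    """Everything one pipeline run needs, minus the --seed override."""

    seed: int = 0
    noise_sd: float = Field(default=0.005, ge=0.0)  # mM
    time_grid: TimeGridCfg = TimeGridCfg()
    blood: BloodCfg = BloodCfg()
    cohort: CohortCfg
    fit: FitCfg = FitCfg()

    def to_cohort_spec(self, seed: int | None = None) -> CohortSpec:
        stages = {
            stage: {
                region: {
                    "k_in_prime": r.k_in_prime.to_dist(),
                    "k_out_prime": r.k_out_prime.to_dist(),
                    "v_blood": r.v_blood.to_dist(),
                }
                for region, r in regions.items()
            }
            for stage, regions in self.cohort.stages.items()
        }
        return CohortSpec(
            stages=stages,
            control_stage=self.cohort.control_stage,
            n_per_stage=self.cohort.n_per_stage,
            noise_sd=self.noise_sd,
            time_grid=TimeGrid(
                self.time_grid.start, self.time_grid.stop, self.time_grid.step
            ),
            blood_c_in=self.blood.c_in.to_dist(),
            blood_k_out=self.blood.k_out.to_dist(),
            hct=self.blood.hct,
            seed=self.seed if seed is None else seed,
        )


def default_config(n_per_stage: int = 20, mild_k_in_factor: float = 1.0) -> RunConfig:
    """Three-region, three-stage control/mild/severe design.

    ``mild_k_in_factor`` scales the mild-stage filtration-rate mean,
    e.g. 2.0 doubles it (expected mild-stage IOF of 2).
    """
    regions = ("lateral_ventricle", "aqueduct", "fourth_ventricle")

    def rates(f_in=1.0):
        return {
            region: RegionRatesCfg(
                k_in_prime=DistCfg(mean=0.06 * f_in, sd=0.012 * f_in),
                k_out_prime=DistCfg(mean=0.05, sd=0.005),
                v_blood=DistCfg(mean=0.13, sd=0.02),
            )
            for region in regions
        }

    return RunConfig(
        cohort=CohortCfg(
            n_per_stage=n_per_stage,
            control_stage="control",
            stages={
                "control": rates(),
                "mild": rates(mild_k_in_factor),
                "severe": rates(),
            },
        )
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
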