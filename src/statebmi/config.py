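"""JSON run configuration: every tunable constant of the pipeline, validated.

A single config file drives the command-line pipelines.  Unknown keys are
rejected so typos fail loudly, and a resolved copy of the configuration is
written next to every output directory for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .binning import Signal, Variant
from .bmi_sim import DEFAULT_STARTS

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_units: int = Field(14, ge=1)
    n_trials_per_stimulus: int = Field(100, ge=1)
    baseline_rate: float = Field(25.0, ge=0)
    state_coupling: float = Field(0.3, ge=0)
    state_timescale: float = Field(0.8, gt=0)
    state_oscillation_band: tuple[float, float] = (1.0, 4.0)
    sine_weight: float = Field(0.1, ge=0, le=1)
    state_skew: float = Field(0.8, ge=0)
    drift_fraction: float = Field(0.205, ge=0)
    pre_stimulus_tuning: float = Field(0.0, ge=0)
    artifact_blank: float = Field(0.030, ge=0)
    pre_span: float = Field(0.75, gt=0)
    post_span: float = Field(0.18, gt=0)


class ScheduleSection(_Strict):
    pre_span: float = Field(0.75, gt=0)
    post_span: float = Field(0.15, gt=0)
    artifact_blank: float = Field(0.030, ge=0)


class DecoderSection(_Strict):
    variant: str = "SD-TD"
    signal: str = "MUA"
    k: int | None = Field(6, ge=1)
    p_thr: float = Field(0.3, ge=0, le=1)
    n_shuffles: int = Field(100, ge=1)

    @field_validator("variant")
    @classmethod
    def _variant_ok(cls, v: str) -> str:
        return Variant(v.upper().replace("_", "-")).value

    @field_validator("signal")
    @classmethod
    def _signal_ok(cls, v: str) -> str:
        return Signal(v.upper()).value


class WorkspaceSection(_Strict):
    side: float = Field(36.0, gt=0)
    f_mag: float = Field(0.008, gt=0)
    r_target: float = Field(1.0, ge=0)
    starts: tuple[tuple[float, float], ...] = DEFAULT_STARTS


class DynamicsSection(_Strict):
    mass: float = Field(0.02, gt=0)
    viscosity: float = Field(0.4, gt=0)
    dt: float = Field(0.25, gt=0)


class ProtocolSection(_Strict):
    reps_per_start: int = Field(100, ge=1)
    max_steps: int = Field(100, ge=1)


class RunConfig(_Strict):
    """Top-level run configuration (see section models for every field)."""

    seed: int = 0
    verbosity: str = "INFO"
    sim: SimSection = SimSection()
    schedule: ScheduleSection = ScheduleSection()
    decoder: DecoderSection = DecoderSection()
    workspace: WorkspaceSection = WorkspaceSection()
    dynamics: DynamicsSection = DynamicsSection()
    protocol: ProtocolSection = ProtocolSection()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    return RunConfig.model_validate(json.loads(Path(path).read_text()))


def dump_config(config: RunConfig, path: str | Path) -> Path:
    """Write the resolved configuration next to the outputs it produced."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(config.model_dump_json(indent=2) + "\n")
    return path
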