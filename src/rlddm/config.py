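"""Run configuration and deterministic seed derivation.

A single YAML file (flat key-value schema) drives the whole pipeline; unknown
keys are rejected so typos surface immediately. One global seed
deterministically derives all stage seeds via a hash of
(global seed, stage name, run id), so any stage can be re-run in isolation
and reproduce its outputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config", "derive_seed"]


class RunConfig(BaseModel):
    """Validated pipeline configuration with documented defaults."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    modality: str = "AV"
    n_trials: int = Field(default=44, ge=4)
    reversal_rate: float = 0.10
    iti_mean: float = 1.87
    iti_range: tuple[float, float] = (0.76, 3.45)
    isi_mean: float = 3.45
    isi_range: tuple[float, float] = (2.28, 4.83)
    # generating parameters for simulation stages
    sim_eta: float = Field(default=0.2, ge=0.0, le=1.0)
    sim_a: float = Field(default=2.5, gt=0.0)
    sim_tau: float = Field(default=1.0, ge=0.0)
    sim_vmod: float = Field(default=3.0, ge=0.0)
    sim_dt: float = Field(default=1e-3, gt=0.0)
    # preprocessing
    rt_fast_cutoff: float = Field(default=0.2, ge=0.0)
    rt_slow_cutoff: float | None = None  # None -> per-trial response window
    # optimizer
    population: int = Field(default=40, ge=8)
    generations: int = Field(default=200, ge=1)
    out_dir: str = "rlddm-output"

    @field_validator("modality")
    @classmethod
    def _check_modality(cls, v):
        if v not in ("AV", "TV"):
            raise ValueError("modality must be 'AV' or 'TV'")
        return v

    @field_validator("reversal_rate")
    @classmethod
    def _check_rate(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("reversal_rate must lie in [0, 1)")
        return v


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives all
    defaults. Errors name the offending key."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a key-value mapping")
    return RunConfig(**data)


def derive_seed(global_seed: int, stage: str, run_id: str = "") -> int:
    """Stable stage seed: SHA-256 of (global seed, stage, run id), < 2**31."""
    digest = hashlib.sha256(f"{global_seed}|{stage}|{run_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
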