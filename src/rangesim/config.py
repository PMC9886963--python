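"""Run configuration: YAML schema, validation, scale profiles, seeding.

A run is described by a single YAML document validated into
:class:`RunConfig` (unknown keys are rejected, fail-fast).  Two scale
profiles resolve the defaults:

* ``desk_scale`` -- 20x20 grid, K=5, sigma=0.5, 400-timestep demographic
  burn-in with founder-diversity injection, 1e7 bp genomes with per-gamete
  mutation/crossover means preserved (10 and 1), 3 replicates;
* ``paper_scale`` -- the full-scale parameterisation (20,000-timestep
  burn-in, 1e9 bp genomes, mu=1e-8, rec=1e-9, 10 replicates), intended for
  cluster use.

All randomness flows from ``master_seed`` through named substreams (one per
scenario/replicate, and within a run separate simulation and sampling
streams); there is no hidden global RNG.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .landscape import ContractionSchedule, PATTERNS, make_schedule
from .simcore import SimParams

__all__ = ["RunConfig", "PROFILES", "load_config", "save_config"]


PROFILES = {
    "desk_scale": {
        "genome_length": 10_000_000,
        "mu": 1e-6,
        "rec": 1e-7,
        "burn_in": 400,
        "n_replicates": 3,
    },
    "paper_scale": {
        "genome_length": 1_000_000_000,
        "mu": 1e-8,
        "rec": 1e-9,
        "burn_in": 20_000,
        "n_replicates": 10,
    },
}


class RunConfig(BaseModel):
    """Validated configuration for a scenario run or a full experiment."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    scenario: str = "shrinkage"
    scenarios: Optional[list] = None  # experiment command: defaults to the 3 patterns
    profile: Literal["desk_scale", "paper_scale"] = "desk_scale"
    master_seed: int = 0
    out_dir: str = "runs/out"

    # landscape / schedule
    nx: int = Field(20, ge=2)
    ny: int = Field(20, ge=2)
    n_events: int = Field(4, ge=0)
    frac_per_event: float = Field(0.22, ge=0.0, le=1.0)
    interval: int = Field(100, ge=1)
    mask_file: Optional[str] = None  # YAML ContractionSchedule override

    # engine parameters (None -> profile/SimParams default)
    sigma: float = Field(0.5, gt=0)
    K: float = Field(5.0, gt=0)
    L: float = Field(4.0, gt=0)
    genome_length: Optional[int] = Field(None, gt=0)
    mu: Optional[float] = Field(None, ge=0)
    rec: Optional[float] = Field(None, ge=0)
    burn_in: Optional[int] = Field(None, ge=1)
    post_run: int = Field(400, ge=1)
    founder_theta: float = Field(1e-3, ge=0)
    genetics_lead: int = Field(250, ge=1)
    kinship_depth: int = Field(10, ge=1)
    relatedness_depth: int = Field(3, ge=1)
    relatedness_cadence: int = Field(10, ge=1)
    relatedness_sample: int = Field(50, ge=2)
    habitat_mode: Literal["scaled", "printed"] = "scaled"
    n_replicates: Optional[int] = Field(None, ge=1)

    @model_validator(mode="after")
    def _check_scenario(self):
        for scen in [self.scenario, *(self.scenarios or [])]:
            if scen not in PATTERNS:
                raise ValueError(f"unknown scenario {scen!r}; choose from {PATTERNS}")
        if self.n_events * self.frac_per_event > 1.0 + 1e-12:
            raise ValueError("n_events * frac_per_event exceeds the whole range")
        return self

    def _resolved(self, key: str):
        val = getattr(self, key)
        return PROFILES[self.profile][key] if val is None else val

    @property
    def replicates(self) -> int:
        return int(self._resolved("n_replicates"))

    @property
    def scenario_list(self) -> list:
        return list(self.scenarios) if self.scenarios else ["shrinkage", "amputation", "fragmentation"]

    def sim_params(self) -> SimParams:
        return SimParams(
            sigma=self.sigma,
            K=self.K,
            L=self.L,
            genome_length=int(self._resolved("genome_length")),
            mu=float(self._resolved("mu")),
            rec=float(self._resolved("rec")),
            burn_in=int(self._resolved("burn_in")),
            post_run=self.post_run,
            founder_theta=self.founder_theta,
            genetics_lead=self.genetics_lead,
            kinship_depth=self.kinship_depth,
            relatedness_depth=self.relatedness_depth,
            relatedness_cadence=self.relatedness_cadence,
            relatedness_sample=self.relatedness_sample,
            habitat_mode=self.habitat_mode,
        )

    def schedule(self, scenario: str | None = None, seed: int | None = None) -> ContractionSchedule:
        if self.mask_file:
            return ContractionSchedule.from_yaml(self.mask_file)
        return make_schedule(
            scenario or self.scenario,
            self.nx,
            self.ny,
            n_events=self.n_events,
            frac_per_event=self.frac_per_event,
            interval=self.interval,
            start=int(self._resolved("burn_in")),
            seed=seed,
        )

    def to_yaml_dict(self) -> dict:
        return self.model_dump(exclude_none=True)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; schema violations name the bad key."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_yaml_dict(), fh, sort_keys=True)
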