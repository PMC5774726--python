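"""Schema-validated run configuration (JSON).

A run config describes everything needed to reproduce a simulation:
the rate-ensemble recipe, the circular/open boundary, the time grid,
the propagation method, the protein metric, optional decay constants,
and a mandatory seed.  Unknown keys are rejected; error messages name
the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .ensemble import CorrelationSpec, RateEnsembleSpec
from .kinetics import DecayModel, RateProfile

__all__ = ["RunConfig", "load_config", "load_profile", "config_hash"]


class CorrelationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["along_sites", "across_templates"] = "along_sites"
    length_scale: int = Field(10, ge=1)
    strength: float = Field(0.5, ge=0.0, lt=1.0)

    def to_spec(self) -> CorrelationSpec:
        return CorrelationSpec(
            mode=self.mode, length_scale=self.length_scale, strength=self.strength
        )


class DecayConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mrna_decay_rate: float = Field(..., ge=0.0)
    protein_decay_rate: float = Field(0.0, ge=0.0)
    ribosome_spacing: float = Field(10.0, ge=1.0)

    def to_model(self) -> DecayModel:
        return DecayModel(
            mrna_decay_rate=self.mrna_decay_rate,
            protein_decay_rate=self.protein_decay_rate,
            ribosome_spacing=self.ribosome_spacing,
        )


class RunConfig(BaseModel):
    """Validated ensemble-simulation configuration."""

    model_config = ConfigDict(extra="forbid")

    family: Literal["gamma", "normal", "exponential", "lognormal", "fixed"]
    params: dict[str, float]
    d: int = Field(..., ge=2)
    n: int = Field(..., ge=1)
    seed: int  # mandatory: every run must be reproducible
    reinit_prob: float = Field(1.0, ge=0.0, le=1.0)
    per_site_means: Optional[list[float]] = None
    slow_sites: Optional[list[tuple[int, float]]] = None
    correlation: Optional[CorrelationConfig] = None
    truncation: Literal["resample", "error"] = "resample"
    times: Optional[list[float]] = None
    method: Literal["auto", "expm", "closed", "divdiff", "spectral"] = "auto"
    metric: Literal[
        "terminal_occupancy", "completion_flux", "cumulative_count", "flux_difference"
    ] = "terminal_occupancy"
    decay: Optional[DecayConfig] = None
    out_prefix: Optional[str] = None

    @model_validator(mode="after")
    def _check_times(self):
        if self.times is not None:
            if not self.times or any(
                b < a for a, b in zip(self.times, self.times[1:])
            ):
                raise ValueError("times must be a non-empty increasing grid")
        return self

    def to_spec(self) -> RateEnsembleSpec:
        return RateEnsembleSpec(
            family=self.family,
            params=self.params,
            d=self.d,
            n_templates=self.n,
            seed=self.seed,
            reinit_prob=self.reinit_prob,
            per_site_means=self.per_site_means,
            slow_sites=[tuple(s) for s in self.slow_sites] if self.slow_sites else None,
            correlation=self.correlation.to_spec() if self.correlation else None,
            truncation=self.truncation,
        )

    def time_grid(self) -> list[float]:
        if self.times is not None:
            return list(self.times)
        from .ensemble import characteristic_time

        T = characteristic_time(self.to_spec())
        return [0.5 * T, T, 2 * T, 3 * T]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    raw = json.loads(Path(path).read_text())
    return RunConfig.model_validate(raw)


def load_profile(path: str | Path, reinit_prob: float = 0.0) -> RateProfile:
    """Load a rate profile from JSON or a one-column epsilon CSV."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return RateProfile.from_json(p)
    return RateProfile.from_csv(p, reinit_prob=reinit_prob)


def config_hash(cfg: RunConfig) -> str:
    import hashlib

    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
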