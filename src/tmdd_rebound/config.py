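"""Schema-validated run configuration and packaged fixtures.

Configs are JSON or YAML mappings with a ``model`` discriminator,
dimensional ``params``, an optional ``feedback`` spec, and optional
solver/detection ``options``.  Unknown keys are rejected so typos fail
loudly; the fully-resolved config is echoed into every report.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .feedback import FeedbackFunction, from_spec
from .model_core import DimensionalParams
from .psoriasis import PsoriasisParams

__all__ = [
    "RunConfig",
    "FeedbackSpec",
    "RunOptions",
    "load_config",
    "load_fixture",
    "omalizumab",
    "psoriasis",
    "psoriasis_original_koff",
]


class FeedbackSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    family: Literal["constant", "mainly_linear", "hyperbolic"] = "constant"
    h0: float | None = None
    beta: float | None = None
    F0: float | None = None

    def build(self) -> FeedbackFunction:
        spec = {"family": self.family}
        if self.h0 is not None:
            spec["h0"] = self.h0
        if self.beta is not None:
            spec["beta"] = self.beta
        if self.F0 is not None:
            spec["F0"] = self.F0
        return from_spec(spec)


class RunOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rtol: float = 1e-10
    atol: float = 1e-12
    delta: float = 1e-6            # rebound detection threshold
    horizon: float | str = "to_steady_state"
    horizon_days: float = 150.0    # psoriasis model only
    dose_mg_per_kg: float = 3.0
    route: Literal["iv", "sc"] = "iv"
    feedback_on: bool = True
    seed: int = 0                  # for sweep-style commands


class TMDDParamSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kon: float
    koff: float
    kout: float
    keL: float
    keP: float
    L0: float
    kin: float | None = None
    R0: float | None = None
    alpha: float = 0.0

    @model_validator(mode="after")
    def _resolve_kin(self):
        if self.kin is None:
            if self.R0 is None:
                raise ValueError("provide kin or R0")
            object.__setattr__(self, "kin", self.kout * self.R0)
        elif self.R0 is not None:
            if abs(self.kin - self.kout * self.R0) > 1e-9 * max(self.kin, 1.0):
                raise ValueError("inconsistent kin vs kout*R0")
        return self

    def build(self) -> DimensionalParams:
        return DimensionalParams(kon=self.kon, koff=self.koff, kin=self.kin,
                                 kout=self.kout, keL=self.keL, keP=self.keP,
                                 L0=self.L0, alpha=self.alpha)


class PsoriasisParamSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ka: float
    k10: float
    k12: float
    k21: float
    k30: float
    koff: float
    Vm: float
    Vm2: float
    Kmc: float
    Vc: float
    Fa: float
    k03max: float
    Y0: float = 100.0

    def build(self) -> PsoriasisParams:
        return PsoriasisParams(**self.model_dump())


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: Literal["basic", "direct", "full", "psoriasis", "generalized"]
    units: dict[str, str] = Field(default_factory=lambda: {
        "time": "day", "concentration": "nM"})
    params: dict
    feedback: FeedbackSpec = Field(default_factory=FeedbackSpec)
    options: RunOptions = Field(default_factory=RunOptions)

    @model_validator(mode="after")
    def _validate_params(self):
        if self.model == "psoriasis":
            PsoriasisParamSpec(**self.params)
        else:
            TMDDParamSpec(**self.params)
        return self

    def build_params(self) -> DimensionalParams | PsoriasisParams:
        if self.model == "psoriasis":
            return PsoriasisParamSpec(**self.params).build()
        return TMDDParamSpec(**self.params).build()

    def build_feedback(self) -> FeedbackFunction:
        return self.feedback.build()

    def resolved(self) -> dict:
        """Fully-resolved config mapping, echoed into reports."""
        return self.model_dump()


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a JSON/YAML config, applying dotted overrides."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    for key, value in (overrides or {}).items():
        node = data
        *parents, leaf = key.split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = value
    return RunConfig(**data)


def load_fixture(name: str) -> RunConfig:
    """Load a packaged fixture config by name (without extension)."""
    text = resources.files("tmdd_rebound.fixtures").joinpath(f"{name}.json").read_text()
    return RunConfig(**json.loads(text))


def omalizumab() -> RunConfig:
    """IgE mAb example: no rebound without feedback, slow-feedback rebound."""
    return load_fixture("omalizumab")


def psoriasis() -> RunConfig:
    """Efalizumab/%CD11a example with koff = 0.0154/day."""
    return load_fixture("psoriasis")


def psoriasis_original_koff() -> RunConfig:
    """Efalizumab example with the originally reported koff = 0.00154/day."""
    return load_fixture("psoriasis_original_koff")
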