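"""Configuration schema, validation, and (de)serialization.

The whole model is driven by one nested, schema-validated document
(:class:`ModelParams`).  Unknown keys are rejected, probabilities are bounded
to [0, 1], and costs must be non-negative.  Values that are placeholders —
quantities whose published source is a supplement rather than the main
analysis — carry a provenance note in the ``provenance`` section and are
listed in a warning when a config is loaded.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .markov import DiscountSpec
from .strategies import (
    DEFAULT_SCHEDULES,
    EpidemiologyParams,
    FollowUpSchedule,
    ImagingCosts,
    SahOutcomeModel,
    ScheduleContext,
    ScreeningTest,
    TreatmentParams,
)

__all__ = ["ModelParams", "ConfigError", "load_params", "dump_params", "config_fingerprint"]

logger = logging.getLogger("uiascreen")


class ConfigError(ValueError):
    """A configuration document violated the schema."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EngineSettings(_Section):
    discount_rate: float = Field(0.03, ge=0.0)
    entry_age: int = Field(40, ge=0)
    max_cycles: int = Field(100, ge=1)
    accrual: Literal["cycle-start", "cycle-end", "half-cycle"] = "cycle-start"
    discount_convention: Literal["first-cycle-undiscounted", "first-cycle-discounted"] = (
        "first-cycle-undiscounted"
    )

    def discount(self) -> DiscountSpec:
        return DiscountSpec(annual_rate=self.discount_rate, convention=self.discount_convention)


class UtilitySettings(_Section):
    healthy: float = Field(0.93, ge=0.0, le=1.0)
    moderate: float = Field(0.76, ge=0.0, le=1.0)
    severe: float = Field(0.235, ge=0.0, le=1.0)
    dead: float = Field(0.0, ge=0.0, le=0.0)


class ScheduleSettings(_Section):
    """Follow-up imaging schedules; ``None`` entries use the defaults."""

    horizon_years: int = Field(60, ge=1)
    untreated_uia: FollowUpSchedule | None = None
    post_clip: FollowUpSchedule | None = None
    post_coil: FollowUpSchedule | None = None


class DistributionSpec(_Section):
    """A sampling distribution for one parameter in the PSA.

    ``beta`` and ``gamma`` are moment-matched to (mean, sd); ``uniform``
    takes (low, high); ``point`` pins the parameter at ``value``.
    """

    parameter: str
    family: Literal["beta", "gamma", "uniform", "point"]
    mean: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    value: float | None = None


class AnalysisSettings(_Section):
    wtp_levels: list[float] = Field(default_factory=lambda: [20000.0, 50000.0, 100000.0])
    price_range: tuple[float, float] = (1.0, 811.30)
    psa_iterations: int = Field(1000, ge=1)
    psa_seed: int = 20240
    prevalence_range: tuple[float, float] = (0.023, 0.09)
    distributions: list[DistributionSpec] = Field(default_factory=list)


class ModelParams(_Section):
    """The complete parameter document consumed by the model."""

    engine: EngineSettings = Field(default_factory=EngineSettings)
    utilities: UtilitySettings = Field(default_factory=UtilitySettings)
    epidemiology: EpidemiologyParams
    test: ScreeningTest
    imaging: ImagingCosts = Field(default_factory=ImagingCosts)
    treatment: TreatmentParams
    sah_outcomes: SahOutcomeModel
    schedules: ScheduleSettings = Field(default_factory=ScheduleSettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)
    provenance: dict[str, str] = Field(default_factory=dict)

    def followup_schedules(self) -> dict[ScheduleContext, FollowUpSchedule]:
        out = dict(DEFAULT_SCHEDULES)
        for ctx in ("untreated_uia", "post_clip", "post_coil"):
            override = getattr(self.schedules, ctx)
            if override is not None:
                out[ctx] = override
        return out

    def placeholder_keys(self) -> list[str]:
        return sorted(k for k, v in self.provenance.items() if "placeholder" in v.lower())

    def with_overrides(self, overrides: dict[str, float]) -> "ModelParams":
        """Deep copy with dotted-path value overrides (used by the PSA)."""
        doc = self.model_dump()
        for path, value in overrides.items():
            parts = path.split(".")
            node = doc
            for p in parts[:-1]:
                if p not in node:
                    raise ConfigError(f"unknown parameter path {path!r}")
                node = node[p]
            if parts[-1] not in node:
                raise ConfigError(f"unknown parameter path {path!r}")
            node[parts[-1]] = value
        try:
            return ModelParams.model_validate(doc)
        except ValidationError as err:
            raise ConfigError(_format_validation_error(err)) from err


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        key = ".".join(str(p) for p in e["loc"])
        lines.append(f"{key}: {e['msg']} (got {e.get('input')!r})")
    return "invalid model configuration:\n  " + "\n  ".join(lines)


def load_params(path: str | Path) -> ModelParams:
    """Load and validate a YAML (or JSON) parameter document.

    Emits a warning listing any keys whose provenance marks them as
    supplement-level placeholders.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    try:
        params = ModelParams.model_validate(doc)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err
    placeholders = params.placeholder_keys()
    if placeholders:
        logger.warning(
            "config contains %d placeholder parameter(s) without a published "
            "main-text value: %s", len(placeholders), ", ".join(placeholders),
        )
    return params


def dump_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.model_dump(mode="json"), fh, sort_keys=False, allow_unicode=True)


def config_fingerprint(params: ModelParams) -> str:
    """Content hash of the canonicalized config (stable across key order)."""
    canon = yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
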