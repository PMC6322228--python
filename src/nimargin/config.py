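"""Scenario configuration files (YAML) and validation.

A single YAML file fully determines a run.  Every key is optional: an
empty file yields the default scenario (50-year-old low-risk adenoma
patients, 5-yearly vs 10-yearly surveillance to age 75, 1% expected
10-year incidence in the standard arm).  Unknown keys are rejected, and
validation errors carry full field paths.

Top-level sections::

    standard_arm / alternative_arm   exam schedules
    life_table                       other-cause mortality
    natural_history                  cancer hazard, protection, run control
    colonoscopy_burden               per-exam disutility, complications
    complication_model               age-risk anchors
    treatment_disutility             phase decrements
    economics                        unit costs, willingness-to-pay
    trial                            p_S, alpha, power, z rounding
    sweep                            uncertainty grid
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .cohort_model import LifeTableParams, NaturalHistoryParams, SurveillanceStrategy
from .qaly_accounting import (ColonoscopyBurden, ComplicationModel, EconParams,
                              TreatmentDisutility)
from .scenario import Scenario
from .sweeps import SweepGrid
from .trial_design import TrialDesign

__all__ = ["ScenarioConfig", "load_config", "config_hash"]


class ScenarioConfig(BaseModel):
    """Schema-validated run configuration with defaults filled in."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    schema_version: int = 1
    standard_arm: SurveillanceStrategy = SurveillanceStrategy(
        label="5-yearly surveillance", interval=5.0)
    alternative_arm: SurveillanceStrategy = SurveillanceStrategy(
        label="10-yearly surveillance", interval=10.0)
    life_table: LifeTableParams = LifeTableParams()
    natural_history: NaturalHistoryParams = NaturalHistoryParams()
    colonoscopy_burden: ColonoscopyBurden = ColonoscopyBurden()
    complication_model: ComplicationModel = ComplicationModel()
    treatment_disutility: TreatmentDisutility = TreatmentDisutility()
    economics: EconParams = EconParams()
    trial: TrialDesign = TrialDesign()
    sweep: SweepGrid = SweepGrid()

    def scenario(self) -> Scenario:
        """The two-arm scenario implied by this configuration; the
        standard arm's event rate comes from the trial section."""
        return Scenario(
            standard=self.standard_arm,
            alternative=self.alternative_arm,
            life=self.life_table,
            nh=self.natural_history,
            burden=self.colonoscopy_burden,
            complications=self.complication_model,
            treatment=self.treatment_disutility,
            econ=self.economics,
            p_S=self.trial.p_S,
        )


def load_config(path: str | Path | None = None) -> ScenarioConfig:
    """Load and validate a YAML scenario file.

    ``None`` or an empty file yields the full default configuration.
    Schema violations raise ``pydantic.ValidationError`` with field
    paths (e.g. ``standard_arm.interval``).
    """
    if path is None:
        return ScenarioConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return ScenarioConfig.model_validate(raw)


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable hash of the effective configuration, for run manifests."""
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]
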