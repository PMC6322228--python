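"""QALY and cost accounting for one trial arm.

Turns a :class:`~nimargin.cohort_model.CohortTrace` plus burden and
economic parameters into per-1000-patient totals decomposed as: life
years, QALYs lost to surveillance exams, QALYs lost to exam
complications, QALYs lost to cancer treatment, total QALYs, total costs
and exam counts.  The accounting identity

    qaly_total = life_years - (surveillance + complication + treatment losses)

holds exactly by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "DAYS_PER_YEAR",
    "ColonoscopyBurden",
    "ComplicationModel",
    "TreatmentDisutility",
    "EconParams",
    "ArmOutcomes",
    "per_colonoscopy_disutility",
    "complication_probability",
    "surveillance_losses",
    "treatment_losses",
    "assemble_outcomes",
]

DAYS_PER_YEAR = 365.25


class ColonoscopyBurden(BaseModel):
    """Per-exam disutility decomposition and complication consequences.

    Defaults encode three weeks of pre-procedure anxiety at a utility
    decrement of 0.1 plus two days of preparation and procedure at 0.5,
    i.e. 3.1 quality-adjusted days lost per exam for the average
    patient.  ``scaling`` rescales the per-exam burden to represent a
    different percentile of the population's disutility distribution
    (0.8 and 1.2 are conventional alternates).  Only exams with
    polypectomy carry complication risk; ``fatal_complication_probability``
    is per polypectomy exam.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    anxiety_duration: float = 21.0          # days
    anxiety_disutility: float = 0.1
    procedure_duration: float = 2.0         # days
    procedure_disutility: float = 0.5
    complication_qaly_loss: float = 14.0    # days per (non-fatal) complication
    fatal_complication_probability: float = 1.0 / 30000.0
    polypectomy_fraction: float = 0.3
    scaling: float = 1.0

    @field_validator("anxiety_disutility", "procedure_disutility")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("utility decrements must be in [0, 1]")
        return v

    @field_validator("fatal_complication_probability", "polypectomy_fraction")
    @classmethod
    def _probability(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        return v

    @field_validator("anxiety_duration", "procedure_duration", "complication_qaly_loss")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("durations must be >= 0")
        return v

    @field_validator("scaling")
    @classmethod
    def _pos_scaling(cls, v: float) -> float:
        if v < 0:
            raise ValueError("scaling must be >= 0")
        return v

    @property
    def fatal_per_exam(self) -> float:
        """Fatal complication probability per exam (all exams pooled)."""
        return self.polypectomy_fraction * self.fatal_complication_probability


class ComplicationModel(BaseModel):
    """Exponential age-risk of complications per polypectomy exam,
    anchored at 2/1000 at age 40 and 38/1000 at age 85."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    rate_at_40: float = 0.002
    rate_at_85: float = 0.038

    @field_validator("rate_at_40", "rate_at_85")
    @classmethod
    def _open_unit(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("anchor rates must be in (0, 1)")
        return v

    @property
    def slope(self) -> float:
        return math.log(self.rate_at_85 / self.rate_at_40) / 45.0


class TreatmentDisutility(BaseModel):
    """Utility decrements for life-years lived with diagnosed cancer.

    Phases: initial (first year after diagnosis), continuing (subsequent
    years until cure), terminal (the last year before a cancer death).
    The defaults are stylised placeholders of the usual magnitude for
    colorectal cancer care phases; they are configuration, not estimates.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    initial_phase_disutility: float = 0.30
    continuing_phase_disutility: float = 0.10
    terminal_phase_disutility: float = 0.45

    @field_validator("initial_phase_disutility", "continuing_phase_disutility",
                     "terminal_phase_disutility")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("utility decrements must be in [0, 1]")
        return v


class EconParams(BaseModel):
    """Unit costs (EUR) and the willingness-to-pay threshold per QALY."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    cost_per_colonoscopy: float = 500.0
    cost_per_complication: float = 5000.0
    cost_crc_initial_per_year: float = 25000.0
    cost_crc_continuing_per_year: float = 2500.0
    cost_crc_terminal_per_year: float = 30000.0
    wtp: float = 20000.0

    @field_validator("cost_per_colonoscopy", "cost_per_complication",
                     "cost_crc_initial_per_year", "cost_crc_continuing_per_year",
                     "cost_crc_terminal_per_year")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("costs must be >= 0")
        return v

    @field_validator("wtp")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("willingness-to-pay must be > 0")
        return v


@dataclass(frozen=True)
class ArmOutcomes:
    """Per-1000-patient outcome totals for one arm (one Table row)."""

    life_years: float
    qaly_lost_surveillance: float
    qaly_lost_complications: float
    qaly_lost_treatment: float
    qaly_total: float
    cost_total: float
    n_colonoscopies: float

    @classmethod
    def from_components(
        cls,
        life_years: float,
        qaly_lost_surveillance: float,
        qaly_lost_complications: float,
        qaly_lost_treatment: float,
        cost_total: float = 0.0,
        n_colonoscopies: float = 0.0,
    ) -> "ArmOutcomes":
        total = life_years - (qaly_lost_surveillance + qaly_lost_complications
                              + qaly_lost_treatment)
        return cls(life_years, qaly_lost_surveillance, qaly_lost_complications,
                   qaly_lost_treatment, total, cost_total, n_colonoscopies)

    def to_record(self) -> dict:
        """Column names mirroring the published table layout."""
        return {
            "Life-years (per 1000 pt)": self.life_years,
            "QALYs lost due to surveillance (per 1000 pt)": self.qaly_lost_surveillance,
            "QALYs lost due to complications (per 1000 pt)": self.qaly_lost_complications,
            "QALYs lost due to treatment (per 1000 pt)": self.qaly_lost_treatment,
            "QALYs (per 1000 pt)": self.qaly_total,
            "Costs (per 1000 pt)": self.cost_total,
            "Colonoscopies (per 1000 pt)": self.n_colonoscopies,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def per_colonoscopy_disutility(burden: ColonoscopyBurden) -> float:
    """Quality-adjusted days lost per exam.

    ``scaling * (anxiety_duration * anxiety_disutility +
    procedure_duration * procedure_disutility)``; 3.1 days at defaults.
    """
    return burden.scaling * (
        burden.anxiety_duration * burden.anxiety_disutility
        + burden.procedure_duration * burden.procedure_disutility
    )


def complication_probability(age, model: ComplicationModel):
    """Complication probability per polypectomy exam at ``age``.

    Exponential between the anchors, extrapolated beyond them, capped at 1.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    r = model.rate_at_40 * np.exp(model.slope * (age - 40.0))
    r = np.minimum(r, 1.0)
    return float(r) if r.ndim == 0 else r


def surveillance_losses(trace, burden: ColonoscopyBurden, model: ComplicationModel):
    """Per-1000 QALY losses from exams and their complications.

    Returns ``(qaly_lost_surveillance, qaly_lost_complications,
    complication_deaths)``; deaths feed the cohort model's mortality
    stream (and are already inside the trace when wired via a scenario).
    """
    ages = trace.ages[:-1]
    disc = trace.discount
    exams = trace.exams
    per_exam_years = per_colonoscopy_disutility(burden) / DAYS_PER_YEAR
    surv_loss = float(np.sum(exams * disc)) * per_exam_years * 1000.0
    compl = exams * burden.polypectomy_fraction * complication_probability(ages, model)
    compl_loss = float(np.sum(compl * disc)) * burden.complication_qaly_loss / DAYS_PER_YEAR * 1000.0
    deaths = float(np.sum(exams)) * burden.fatal_per_exam * 1000.0
    return surv_loss, compl_loss, deaths


def treatment_losses(trace, td: TreatmentDisutility) -> float:
    """Per-1000 QALYs lost to diagnosed person-time, by phase."""
    disc = trace.discount
    loss = (
        float(np.sum(trace.pt_diag_initial * disc)) * td.initial_phase_disutility
        + float(np.sum(trace.pt_diag_continuing * disc)) * td.continuing_phase_disutility
        + float(np.sum(trace.pt_diag_terminal * disc)) * td.terminal_phase_disutility
    )
    return loss * 1000.0


def assemble_outcomes(
    trace,
    burden: ColonoscopyBurden,
    model: ComplicationModel,
    td: TreatmentDisutility,
    econ: Optional[EconParams] = None,
) -> ArmOutcomes:
    """Full per-1000 outcome record for one arm."""
    econ = econ or EconParams()
    life_years = trace.life_years * 1000.0
    surv_loss, compl_loss, _ = surveillance_losses(trace, burden, model)
    treat_loss = treatment_losses(trace, td)

    disc = trace.discount
    ages = trace.ages[:-1]
    compl = trace.exams * burden.polypectomy_fraction * complication_probability(ages, model)
    cost = (
        float(np.sum(trace.exams * disc)) * econ.cost_per_colonoscopy
        + float(np.sum(compl * disc)) * econ.cost_per_complication
        + float(np.sum(trace.pt_diag_initial * disc)) * econ.cost_crc_initial_per_year
        + float(np.sum(trace.pt_diag_continuing * disc)) * econ.cost_crc_continuing_per_year
        + float(np.sum(trace.pt_diag_terminal * disc)) * econ.cost_crc_terminal_per_year
    ) * 1000.0
    n_colo = float(np.sum(trace.exams)) * 1000.0

    return ArmOutcomes.from_components(
        life_years=life_years,
        qaly_lost_surveillance=surv_loss,
        qaly_lost_complications=compl_loss,
        qaly_lost_treatment=treat_loss,
        cost_total=cost,
        n_colonoscopies=n_colo,
    )
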