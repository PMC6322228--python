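"""A fully specified two-arm comparison scenario.

Bundles the two surveillance strategies, natural history, life table,
exam burden, complication model, treatment disutilities and economics,
plus the standard arm's assumed cumulative event rate ``p_S``.  All
components are frozen, so a scenario is hashable and arm evaluations can
be cached.
"""

from __future__ import annotations

import functools
import hashlib

from pydantic import BaseModel, ConfigDict, field_validator

from .cohort_model import (
    CohortTrace,
    LifeTableParams,
    NaturalHistoryParams,
    SurveillanceStrategy,
    run_arm,
)
from .qaly_accounting import (
    ArmOutcomes,
    ColonoscopyBurden,
    ComplicationModel,
    EconParams,
    TreatmentDisutility,
    assemble_outcomes,
)

__all__ = ["Scenario", "evaluate_arm", "standard_outcomes"]


class Scenario(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    standard: SurveillanceStrategy = SurveillanceStrategy(label="5-yearly surveillance", interval=5.0)
    alternative: SurveillanceStrategy = SurveillanceStrategy(label="10-yearly surveillance", interval=10.0)
    life: LifeTableParams = LifeTableParams()
    nh: NaturalHistoryParams = NaturalHistoryParams()
    burden: ColonoscopyBurden = ColonoscopyBurden()
    complications: ComplicationModel = ComplicationModel()
    treatment: TreatmentDisutility = TreatmentDisutility()
    econ: EconParams = EconParams()
    p_S: float = 0.01

    @field_validator("p_S")
    @classmethod
    def _valid_p(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("p_S must be in [0, 1)")
        return v

    def hash(self) -> str:
        """Stable provenance hash of the full scenario."""
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def evaluate_arm(scenario: Scenario, strategy: SurveillanceStrategy,
                 target_p: float) -> tuple[CohortTrace, ArmOutcomes]:
    """Run one arm at a given cumulative event rate and account it.

    Fatal exam complications are wired from the burden parameters into
    the cohort's mortality stream, so complication deaths lose their
    remaining life expectancy inside the trace.
    """
    trace = run_arm(
        strategy,
        scenario.nh,
        scenario.life,
        target_p,
        fatal_complication_per_exam=scenario.burden.fatal_per_exam,
    )
    outcomes = assemble_outcomes(trace, scenario.burden, scenario.complications,
                                 scenario.treatment, scenario.econ)
    return trace, outcomes


@functools.lru_cache(maxsize=64)
def standard_outcomes(scenario: Scenario) -> ArmOutcomes:
    """Standard arm evaluated once at ``p_S`` (cached per scenario)."""
    return evaluate_arm(scenario, scenario.standard, scenario.p_S)[1]
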