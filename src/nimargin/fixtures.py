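"""Ready-made scenarios for examples and tests.

The default scenario mirrors a polyp-surveillance de-escalation trial:
50-year-old low-risk adenoma patients randomised to surveillance
colonoscopy every 5 years (standard) or every 10 years (alternative),
surveillance stopping at age 75, with an expected 10-year colorectal
cancer cumulative incidence of 1% in the standard arm, 90% power and a
one-sided alpha of 0.05.
"""

from __future__ import annotations

from .config import ScenarioConfig
from .scenario import Scenario
from .trial_design import TrialDesign

__all__ = ["default_config", "default_scenario", "default_trial",
           "zero_burden_scenario"]


def default_config() -> ScenarioConfig:
    return ScenarioConfig()


def default_scenario() -> Scenario:
    return ScenarioConfig().scenario()


def default_trial() -> TrialDesign:
    return TrialDesign()


def zero_burden_scenario() -> Scenario:
    """Arms differ in schedule only: no exam disutility, no
    complications, no protection effect.  The equipoise point is then
    exactly p_S (no burden to trade against extra cancers)."""
    base = default_scenario()
    burden = base.burden.model_copy(update={
        "anxiety_disutility": 0.0,
        "procedure_disutility": 0.0,
        "complication_qaly_loss": 0.0,
        "fatal_complication_probability": 0.0,
    })
    nh = base.nh.model_copy(update={"per_exam_protection": 0.0})
    return base.model_copy(update={"burden": burden, "nh": nh})
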