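"""Non-inferiority trial statistics: sample size and a power oracle.

Hypotheses, for event rates p_S (standard) and p_A (alternative) and
margin delta > 0:

    H0: p_A - p_S > delta     (alternative is inferior)
    Ha: p_A - p_S < delta     (alternative is non-inferior)

The sample size per arm is the standard two-proportion formula

    n = ceil( (z_{1-alpha} + z_{1-beta})^2
              * (p_S (1 - p_S) + p_A (1 - p_A)) / delta^2 )

with p_A the *assumed true* rate under Ha (equal to p_S by default:
equal true efficacy).  Normal quantiles are rounded to 3 decimals by
default (1.645, 1.282), the convention under which published
hand-calculated sizes are reproduced; full precision shifts n by a few
per arm.  A vectorised Monte-Carlo simulator of the one-sided Wald
(unpooled) test serves as an independent check of the formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator
from scipy.stats import norm

__all__ = ["TrialDesign", "SampleSize", "PowerResult",
           "required_sample_size", "simulate_power", "analytic_power"]


class TrialDesign(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    p_S: float = 0.01
    alpha_one_sided: float = 0.05
    power: float = 0.90
    assumed_true_p_A: Optional[float] = None   # None -> p_S
    z_rounding: Optional[int] = 3              # None -> full precision

    @field_validator("p_S")
    @classmethod
    def _p_open(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("p_S must be in (0, 1)")
        return v

    @field_validator("alpha_one_sided")
    @classmethod
    def _alpha(cls, v: float) -> float:
        if not (0.0 < v < 0.5):
            raise ValueError("alpha_one_sided must be in (0, 0.5)")
        return v

    @field_validator("power")
    @classmethod
    def _power(cls, v: float) -> float:
        if not (0.5 < v < 1.0):
            raise ValueError("power must be in (0.5, 1)")
        return v

    @property
    def true_p_A(self) -> float:
        return self.p_S if self.assumed_true_p_A is None else self.assumed_true_p_A

    def z(self, q: float) -> float:
        """Upper-tail standard-normal quantile at cumulative ``q``,
        rounded per the design's convention."""
        z = float(norm.ppf(q))
        return round(z, self.z_rounding) if self.z_rounding is not None else z


@dataclass(frozen=True)
class SampleSize:
    n_per_arm: int
    n_total: int
    delta: float
    p_S: float
    p_A: float
    alpha_one_sided: float
    power: float
    z_alpha: float
    z_beta: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    n_sim: int
    n_reject: int


def _ceil_tol(x: float, tol: float = 1e-9) -> int:
    """Ceiling that forgives floating-point overshoot just below an
    integer (so an exact real-valued solution is not inflated by 1)."""
    r = round(x)
    if abs(x - r) <= tol:
        return int(r)
    return int(math.ceil(x))


def required_sample_size(trial: TrialDesign, delta: float) -> SampleSize:
    """Per-arm and total sample size for the non-inferiority design."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    z_a = trial.z(1.0 - trial.alpha_one_sided)
    z_b = trial.z(trial.power)
    p_s, p_a = trial.p_S, trial.true_p_A
    var_sum = p_s * (1.0 - p_s) + p_a * (1.0 - p_a)
    n = _ceil_tol((z_a + z_b) ** 2 * var_sum / delta ** 2)
    return SampleSize(
        n_per_arm=n, n_total=2 * n, delta=delta, p_S=p_s, p_A=p_a,
        alpha_one_sided=trial.alpha_one_sided, power=trial.power,
        z_alpha=z_a, z_beta=z_b,
    )


def simulate_power(
    n_per_arm: int,
    trial: TrialDesign,
    delta: float,
    true_p_A: Optional[float] = None,
    n_sim: int = 100_000,
    seed: int = 0,
) -> PowerResult:
    """Empirical power of the one-sided Wald non-inferiority test.

    Each simulated trial draws binomial event counts per arm at the true
    rates and rejects H0 when
    ``(p_hat_A - p_hat_S - delta) / SE < -z_{1-alpha}`` with the
    unpooled standard error from the estimated rates.  With both
    estimates degenerate (SE = 0) the rejection reduces to the sign of
    the numerator.
    """
    rng = np.random.default_rng(seed)
    p_s = trial.p_S
    p_a = trial.true_p_A if true_p_A is None else true_p_A
    z_a = trial.z(1.0 - trial.alpha_one_sided)

    xs = rng.binomial(n_per_arm, p_s, size=n_sim)
    xa = rng.binomial(n_per_arm, p_a, size=n_sim)
    ps_hat = xs / n_per_arm
    pa_hat = xa / n_per_arm
    se = np.sqrt(ps_hat * (1 - ps_hat) / n_per_arm + pa_hat * (1 - pa_hat) / n_per_arm)
    num = pa_hat - ps_hat - delta
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(se > 0, num / np.where(se > 0, se, 1.0), np.where(num < 0, -np.inf, np.inf))
    reject = stat < -z_a
    k = int(np.sum(reject))
    p = k / n_sim
    return PowerResult(power=p, mc_se=math.sqrt(max(p * (1 - p), 1e-300) / n_sim),
                       n_sim=n_sim, n_reject=k)


def analytic_power(
    n_per_arm: int,
    trial: TrialDesign,
    delta: float,
    true_p_A: Optional[float] = None,
) -> float:
    """Normal-approximation power ``Phi((delta - (p_A - p_S))/SE - z_{1-alpha})``
    with the standard error evaluated at the true rates."""
    p_s = trial.p_S
    p_a = trial.true_p_A if true_p_A is None else true_p_A
    se = math.sqrt((p_s * (1 - p_s) + p_a * (1 - p_a)) / n_per_arm)
    z_a = trial.z(1.0 - trial.alpha_one_sided)
    return float(norm.cdf((delta - (p_a - p_s)) / se - z_a))
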