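"""Deterministic cohort state-transition model for colonoscopy surveillance.

This module is Step 1 of the margin-setting framework: given an exam
schedule and a *target* cumulative cancer incidence over a trial horizon,
it produces lifetime person-time, event counts and exam counts for a
closed cohort.  It is a deliberately simplified stand-in for a full
microsimulation natural-history model: colorectal cancer (CRC) diagnosis
is a single age-dependent hazard, scaled by a calibrated multiplier so
that the cohort hits the requested 10-year cumulative incidence in the
presence of competing other-cause mortality, and reduced by a scalar
per-exam protection factor between scheduled exams.

States
------
susceptible (alive, no CRC) -> diagnosed (excess mortality for
``cure_horizon`` years, then cured) -> dead (other cause / CRC /
fatal exam complication).  All arithmetic is on cohort fractions, so the
model is noise-free and suitable for root finding on the event rate.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "SurveillanceStrategy",
    "LifeTableParams",
    "NaturalHistoryParams",
    "CohortTrace",
    "build_schedule",
    "build_life_table",
    "life_expectancy_from_table",
    "calibrate_hazard_multiplier",
    "run_arm",
]

_ALIGN_TOL = 1e-6


class SurveillanceStrategy(BaseModel):
    """One trial arm's colonoscopy schedule.

    Exams happen at ``start_age + k * interval`` for k >= 1, truncated at
    ``stop_age`` (surveillance stops at a fixed age, e.g. 75).  The exam
    at ``start_age`` itself is the index colonoscopy that put the patient
    under surveillance and is common to both arms, so it is not part of
    the schedule.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str = "arm"
    start_age: float = 50.0
    interval: float = 5.0
    stop_age: float = 75.0

    @field_validator("interval")
    @classmethod
    def _interval_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("interval must be > 0")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "SurveillanceStrategy":
        if self.stop_age < self.start_age:
            raise ValueError("stop_age must be >= start_age")
        return self

    @property
    def exam_ages(self) -> tuple[float, ...]:
        return build_schedule(self)


def build_schedule(strategy: SurveillanceStrategy) -> tuple[float, ...]:
    """Sorted, duplicate-free exam ages in ``(start_age, stop_age]``.

    >>> build_schedule(SurveillanceStrategy(interval=10))
    (60.0, 70.0)
    """
    n_max = int(math.floor((strategy.stop_age - strategy.start_age) / strategy.interval + _ALIGN_TOL))
    return tuple(strategy.start_age + k * strategy.interval for k in range(1, n_max + 1))


class LifeTableParams(BaseModel):
    """Other-cause mortality, either Gompertz or a tabulated life table.

    The Gompertz hazard is ``a * exp(b * (age - reference_age))``; the
    defaults give a residual life expectancy at age 50 of about 22.4
    years, the right magnitude for a general adenoma-surveillance
    population.  ``table`` rows are ``(age, annual death probability)``
    with each probability covering ``[age, age + 1)``; beyond the last
    row the last hazard is held constant.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    model: Literal["gompertz", "tabulated"] = "gompertz"
    gompertz_a: float = 0.009
    gompertz_b: float = 0.09
    reference_age: float = 50.0
    table: Optional[tuple[tuple[float, float], ...]] = None

    @field_validator("gompertz_a", "gompertz_b")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("Gompertz parameters must be >= 0 (non-decreasing hazard)")
        return v

    @model_validator(mode="after")
    def _check_table(self) -> "LifeTableParams":
        if self.model == "tabulated":
            if not self.table:
                raise ValueError("tabulated model requires a non-empty table")
            ages = [a for a, _ in self.table]
            if sorted(ages) != ages:
                raise ValueError("table ages must be sorted")
            for _, q in self.table:
                if not (0.0 <= q < 1.0):
                    raise ValueError("annual death probabilities must be in [0, 1)")
        return self

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous other-cause mortality hazard (per year)."""
        if self.model == "gompertz":
            return self.gompertz_a * np.exp(self.gompertz_b * (np.asarray(age, dtype=float) - self.reference_age))
        ages = np.array([a for a, _ in self.table], dtype=float)
        haz = np.array([-math.log(1.0 - q) for _, q in self.table], dtype=float)
        idx = np.clip(np.searchsorted(ages, np.asarray(age, dtype=float), side="right") - 1, 0, len(ages) - 1)
        return haz[idx]


def build_life_table(params: LifeTableParams, min_age: int = 0, max_age: int = 120) -> pd.Series:
    """Annual death probabilities ``q_a = 1 - exp(-∫_a^{a+1} mu)`` by age.

    For the Gompertz model the integral is closed-form; for a tabulated
    model the stored probabilities are returned on the requested ages.
    """
    ages = np.arange(min_age, max_age)
    if params.model == "gompertz":
        a0, b, ref = params.gompertz_a, params.gompertz_b, params.reference_age
        if b == 0:
            cumhaz = np.full(ages.shape, a0, dtype=float)
        else:
            cumhaz = a0 / b * (np.exp(b * (ages + 1 - ref)) - np.exp(b * (ages - ref)))
        q = 1.0 - np.exp(-cumhaz)
    else:
        haz = np.asarray(params.hazard(ages + 0.5), dtype=float)
        q = 1.0 - np.exp(-haz)
    return pd.Series(q, index=pd.Index(ages, name="age"), name="annual_death_probability")


def life_expectancy_from_table(table: pd.Series, from_age: float) -> float:
    """Residual life expectancy at ``from_age`` by trapezoid summation of
    the survival curve implied by the annual death probabilities."""
    q = table.loc[table.index >= from_age].to_numpy()
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return float(np.sum((surv[:-1] + surv[1:]) / 2.0))


class NaturalHistoryParams(BaseModel):
    """Reduced-form CRC natural history and run-control parameters.

    The baseline diagnosis hazard is exponential in age (doubling every
    ``baseline_doubling_years``); only its shape matters, because the
    level is rescaled by a calibrated multiplier to hit the requested
    cumulative incidence.  ``per_exam_protection`` (rho) is the fraction
    by which one colonoscopy lowers the CRC hazard until the next
    scheduled exam (or for ``interval`` years after the last one), and
    ``sensitivity_multiplier`` (epsilon) scales rho for sensitivity
    sweeps.  Diagnosed persons face a constant ``excess_mortality_rate``
    for ``cure_horizon`` years, after which only background mortality
    applies.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    baseline_hazard_at_ref: float = 0.001
    baseline_doubling_years: float = 12.0
    reference_age: float = 50.0
    per_exam_protection: float = 0.5
    sensitivity_multiplier: float = 1.0
    excess_mortality_rate: float = 0.09
    cure_horizon: float = 5.0
    cycle_length: float = 1.0 / 12.0
    horizon_age: float = 100.0
    horizon_years: float = 10.0
    discount_rate: float = 0.0

    @field_validator(
        "baseline_hazard_at_ref", "excess_mortality_rate", "cure_horizon",
        "discount_rate", "per_exam_protection", "sensitivity_multiplier",
    )
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("rates and protections must be >= 0")
        return v

    @field_validator("cycle_length", "baseline_doubling_years", "horizon_years")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @model_validator(mode="after")
    def _protection_bounded(self) -> "NaturalHistoryParams":
        if self.per_exam_protection * self.sensitivity_multiplier > 1.0 + 1e-12:
            raise ValueError("per_exam_protection * sensitivity_multiplier must be <= 1")
        return self

    def baseline_hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.baseline_hazard_at_ref * np.exp(
            math.log(2.0) / self.baseline_doubling_years * (np.asarray(age, dtype=float) - self.reference_age)
        )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle bookkeeping of one arm, on cohort fractions (size 1).

    State snapshots (length ``n_cycles + 1``) are taken at cycle starts,
    before that cycle's exam; flows and person-time (length ``n_cycles``)
    accrue during the cycle.  Diagnosed person-time is partitioned into
    initial (first year), continuing (year 1 to cure), cured, and
    terminal (the last year before a CRC death, carved out of the
    others) so that phase-specific disutilities sum consistently.
    """

    ages: np.ndarray                 # cycle-start ages, length n+1
    cycle_length: float
    alive: np.ndarray                # susceptible at cycle start, length n+1
    diagnosed: np.ndarray            # alive diagnosed (incl. cured), length n+1
    dead_other: np.ndarray           # cumulative, length n+1
    dead_crc: np.ndarray             # cumulative, length n+1
    dead_complication: np.ndarray    # cumulative, length n+1
    exams: np.ndarray                # exams this cycle per initial person
    new_diagnoses: np.ndarray
    complication_deaths: np.ndarray
    pt_susceptible: np.ndarray       # person-years this cycle
    pt_diag_initial: np.ndarray
    pt_diag_continuing: np.ndarray
    pt_diag_cured: np.ndarray
    pt_diag_terminal: np.ndarray
    discount: np.ndarray             # mid-cycle discount factors
    hazard_multiplier: float = 1.0
    target_p: float = float("nan")

    @property
    def n_cycles(self) -> int:
        return len(self.exams)

    def state_sums(self) -> np.ndarray:
        """alive + diagnosed + dead compartments at every cycle start."""
        return self.alive + self.diagnosed + self.dead_other + self.dead_crc + self.dead_complication

    def cumulative_incidence(self, horizon_years: float) -> float:
        n = int(round(horizon_years / self.cycle_length))
        return float(np.sum(self.new_diagnoses[:n]))

    @property
    def life_years(self) -> float:
        """Total (discounted) person-years per initial person."""
        pt = (self.pt_susceptible + self.pt_diag_initial + self.pt_diag_continuing
              + self.pt_diag_cured + self.pt_diag_terminal)
        return float(np.sum(pt * self.discount))

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        wide = pd.DataFrame(
            {
                "age": self.ages[:-1],
                "alive_susceptible": self.alive[:-1],
                "alive_diagnosed": self.diagnosed[:-1],
                "dead_other": self.dead_other[:-1],
                "dead_crc": self.dead_crc[:-1],
                "dead_complication": self.dead_complication[:-1],
                "exams": self.exams,
                "new_diagnoses": self.new_diagnoses,
                "complication_deaths": self.complication_deaths,
                "pt_susceptible": self.pt_susceptible,
                "pt_diag_initial": self.pt_diag_initial,
                "pt_diag_continuing": self.pt_diag_continuing,
                "pt_diag_cured": self.pt_diag_cured,
                "pt_diag_terminal": self.pt_diag_terminal,
            }
        )
        wide.index.name = "cycle"
        if not tidy:
            return wide
        return wide.melt(id_vars=["age"], var_name="compartment", value_name="value", ignore_index=False).reset_index()


# ---------------------------------------------------------------------------
# grid preparation and the diagnosed-cohort unit response (cached)
# ---------------------------------------------------------------------------

def _grid(strategy: SurveillanceStrategy, nh: NaturalHistoryParams):
    delta = nh.cycle_length
    n = int(round((nh.horizon_age - strategy.start_age) / delta))
    if n <= 0:
        raise ConfigurationError("horizon_age must exceed start_age")
    ages = strategy.start_age + delta * np.arange(n + 1)
    return n, delta, ages


def _exam_indices(strategy: SurveillanceStrategy, nh: NaturalHistoryParams) -> np.ndarray:
    n, delta, _ = _grid(strategy, nh)
    idx = []
    for e in build_schedule(strategy):
        x = (e - strategy.start_age) / delta
        i = int(round(x))
        if abs(x - i) > _ALIGN_TOL:
            raise ConfigurationError(
                f"exam age {e} does not align with the cycle grid (cycle_length={delta})"
            )
        if i < n:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def _protection(strategy: SurveillanceStrategy, nh: NaturalHistoryParams) -> np.ndarray:
    """Per-cycle multiplicative hazard factor from exam protection."""
    n, delta, _ = _grid(strategy, nh)
    prot = np.ones(n)
    factor = 1.0 - nh.per_exam_protection * nh.sensitivity_multiplier
    exams = build_schedule(strategy)
    for j, e in enumerate(exams):
        until = exams[j + 1] if j + 1 < len(exams) else e + strategy.interval
        lo = int(round((e - strategy.start_age) / delta))
        hi = min(int(round((until - strategy.start_age) / delta)), n)
        prot[lo:hi] = factor
    return prot


@functools.lru_cache(maxsize=8)
def _diagnosed_unit(nh: NaturalHistoryParams, life: LifeTableParams, start_age: float):
    """Unit-mass response matrices for diagnosis cohorts.

    Row ``k`` describes a unit cohort diagnosed during cycle ``k`` (it
    enters the diagnosed state at the start of cycle ``k+1``).  These
    arrays are independent of the exam schedule and of the calibrated
    hazard multiplier, so they are computed once per (natural history,
    life table, start age) and reused across calibration and the
    equipoise search.
    """
    strategy = SurveillanceStrategy(start_age=start_age, interval=1.0, stop_age=start_age)
    n, delta, ages = _grid(strategy, nh)
    mu_b = np.asarray(life.hazard(ages[:-1] + delta / 2.0), dtype=float)
    m = max(int(round(1.0 / delta)), 1)  # cycles per year (terminal window)

    u_alive = np.zeros((n, n + 1))
    u_dcrc = np.zeros((n, n))
    u_dother = np.zeros((n, n))
    u_pt_init = np.zeros((n, n))
    u_pt_cont = np.zeros((n, n))
    u_pt_cured = np.zeros((n, n))
    u_pt_term = np.zeros((n, n))

    for k in range(n):
        first = k + 1
        u_alive[k, first:] = 1.0  # overwritten below where the cohort decays
        if first >= n:
            continue
        idx = np.arange(first, n)
        tau_mid = (idx - first) * delta + delta / 2.0
        mu_e = np.where(tau_mid < nh.cure_horizon, nh.excess_mortality_rate, 0.0)
        lam = mu_e + mu_b[idx]
        surv = np.exp(-lam * delta)
        alive = np.empty(len(idx) + 1)
        alive[0] = 1.0
        np.cumprod(surv, out=alive[1:])
        deaths = alive[:-1] * (1.0 - surv)
        with np.errstate(invalid="ignore", divide="ignore"):
            dcrc = np.where(lam > 0, deaths * mu_e / np.where(lam > 0, lam, 1.0), 0.0)
        dother = deaths - dcrc
        pt = delta * (alive[:-1] + alive[1:]) / 2.0

        # terminal person-time: each CRC death claims its last year alive
        c = np.cumsum(dcrc)
        j = np.arange(len(idx))
        upper = np.minimum(j + m - 1, len(idx) - 1)
        ahead = c[upper] - c[j]
        term = np.minimum(delta * (0.5 * dcrc + ahead), pt)

        init_mask = tau_mid < 1.0
        cont_mask = (tau_mid >= 1.0) & (tau_mid < nh.cure_horizon)
        cured_mask = tau_mid >= nh.cure_horizon
        base_minus_term = pt - term
        u_pt_init[k, idx] = np.where(init_mask, base_minus_term, 0.0)
        u_pt_cont[k, idx] = np.where(cont_mask, base_minus_term, 0.0)
        u_pt_cured[k, idx] = np.where(cured_mask, base_minus_term, 0.0)
        u_pt_term[k, idx] = term
        u_alive[k, first:] = alive
        u_dcrc[k, idx] = dcrc
        u_dother[k, idx] = dother

    return {
        "alive": u_alive, "dcrc": u_dcrc, "dother": u_dother,
        "pt_init": u_pt_init, "pt_cont": u_pt_cont,
        "pt_cured": u_pt_cured, "pt_term": u_pt_term,
    }


def _susceptible_pass(
    psi: float,
    h0: np.ndarray,
    prot: np.ndarray,
    mu_b: np.ndarray,
    exam_idx: np.ndarray,
    fatal_per_exam: float,
    delta: float,
    n: int,
):
    """Vectorised forward pass over the susceptible compartment."""
    h_crc = psi * h0 * prot
    lam = h_crc + mu_b
    surv = np.exp(-lam * delta)
    g = np.ones(n)
    if len(exam_idx):
        g[exam_idx] = 1.0 - fatal_per_exam
    s_minus = np.empty(n + 1)
    s_minus[0] = 1.0
    np.cumprod(g * surv, out=s_minus[1:])
    s_plus = g * s_minus[:-1]
    events = s_plus * (1.0 - surv)
    with np.errstate(invalid="ignore", divide="ignore"):
        newdiag = np.where(lam > 0, events * h_crc / np.where(lam > 0, lam, 1.0), 0.0)
    dother = events - newdiag
    exams = np.zeros(n)
    cdeaths = np.zeros(n)
    if len(exam_idx):
        exams[exam_idx] = s_minus[exam_idx]
        cdeaths[exam_idx] = s_minus[exam_idx] * fatal_per_exam
    pt_s = delta * (s_plus + s_minus[1:]) / 2.0
    return s_minus, s_plus, newdiag, dother, exams, cdeaths, pt_s


def _cumulative_incidence(psi, h0, prot, mu_b, exam_idx, fatal_per_exam, delta, n_h):
    out = _susceptible_pass(psi, h0[:n_h], prot[:n_h], mu_b[:n_h],
                            exam_idx[exam_idx < n_h], fatal_per_exam, delta, n_h)
    return float(np.sum(out[2]))


def calibrate_hazard_multiplier(
    nh: NaturalHistoryParams,
    life: LifeTableParams,
    strategy: SurveillanceStrategy,
    target_p: float,
    fatal_complication_per_exam: float = 0.0,
    tol: float = 1e-10,
) -> float:
    """Hazard multiplier psi such that the cohort's cumulative CRC
    incidence over ``nh.horizon_years`` (with competing other-cause
    mortality) equals ``target_p``.

    Monotone bracketed root finding (Brent); the achieved incidence is
    within ``tol`` of the target, well inside the 1e-8 contract.
    """
    if not (0.0 <= target_p < 1.0):
        raise ConfigurationError("target_p must be in [0, 1)")
    if target_p == 0.0:
        return 0.0
    n, delta, ages = _grid(strategy, nh)
    mid = ages[:-1] + delta / 2.0
    mu_b = np.asarray(life.hazard(mid), dtype=float)
    h0 = np.asarray(nh.baseline_hazard(mid), dtype=float)
    prot = _protection(strategy, nh)
    exam_idx = _exam_indices(strategy, nh)
    n_h = min(int(round(nh.horizon_years / delta)), n)

    def f(psi: float) -> float:
        return _cumulative_incidence(psi, h0, prot, mu_b, exam_idx,
                                     fatal_complication_per_exam, delta, n_h) - target_p

    hi = 1.0
    f_hi = f(hi)
    while f_hi < 0.0:
        hi *= 2.0
        if hi > 2.0 ** 40:
            achievable = f(hi) + target_p
            raise CalibrationError(
                f"target_p={target_p} unreachable; achievable cumulative "
                f"incidence range is [0, {achievable:.6g}]"
            )
        f_hi = f(hi)
    psi = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    # polish: brentq terminates on the x-scale; verify on the f-scale
    if abs(f(psi)) > tol:
        lo, up = max(psi * 0.5, 0.0), min(psi * 2.0, hi)
        psi = brentq(f, lo, up, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    return float(psi)


def run_arm(
    strategy: SurveillanceStrategy,
    nh: NaturalHistoryParams,
    life: LifeTableParams,
    target_p: float,
    fatal_complication_per_exam: float = 0.0,
    psi: Optional[float] = None,
) -> CohortTrace:
    """Run the cohort from ``start_age`` to ``horizon_age``.

    Exams are applied to alive, not-yet-diagnosed persons at exam ages;
    each exam carries an immediate fatal-complication probability and
    lowers the CRC hazard by the protection factor until the next
    scheduled exam.  The hazard multiplier is calibrated internally
    unless ``psi`` is supplied.
    """
    if psi is None:
        psi = calibrate_hazard_multiplier(nh, life, strategy, target_p,
                                          fatal_complication_per_exam)
    n, delta, ages = _grid(strategy, nh)
    mid = ages[:-1] + delta / 2.0
    mu_b = np.asarray(life.hazard(mid), dtype=float)
    h0 = np.asarray(nh.baseline_hazard(mid), dtype=float)
    prot = _protection(strategy, nh)
    exam_idx = _exam_indices(strategy, nh)

    s_minus, s_plus, newdiag, dother_s, exams, cdeaths, pt_s = _susceptible_pass(
        psi, h0, prot, mu_b, exam_idx, fatal_complication_per_exam, delta, n
    )

    unit = _diagnosed_unit(nh, life, strategy.start_age)
    d_alive = newdiag @ unit["alive"]
    dcrc_flow = newdiag @ unit["dcrc"]
    dother_diag_flow = newdiag @ unit["dother"]

    zero = np.zeros(1)
    dead_other = np.concatenate([zero, np.cumsum(dother_s + dother_diag_flow)])
    dead_crc = np.concatenate([zero, np.cumsum(dcrc_flow)])
    dead_compl = np.concatenate([zero, np.cumsum(cdeaths)])

    discount = np.exp(-nh.discount_rate * (mid - strategy.start_age))

    return CohortTrace(
        ages=ages,
        cycle_length=delta,
        alive=s_minus,
        diagnosed=d_alive,
        dead_other=dead_other,
        dead_crc=dead_crc,
        dead_complication=dead_compl,
        exams=exams,
        new_diagnoses=newdiag,
        complication_deaths=cdeaths,
        pt_susceptible=pt_s,
        pt_diag_initial=newdiag @ unit["pt_init"],
        pt_diag_continuing=newdiag @ unit["pt_cont"],
        pt_diag_cured=newdiag @ unit["pt_cured"],
        pt_diag_terminal=newdiag @ unit["pt_term"],
        discount=discount,
        hazard_multiplier=float(psi),
        target_p=float(target_p),
    )
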