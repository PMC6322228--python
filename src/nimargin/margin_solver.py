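"""Equipoise search: the event rate at which the two arms break even.

The non-inferiority margin is defined as delta = p_A* - p_S where p_A*
is the alternative-arm cumulative event rate at which total QALYs per
1000 patients (or net monetary benefit, for the cost-effectiveness
variant) are equal between arms.  The outcome gap

    gap(p_A) = outcome(alternative at p_A) - outcome(standard at p_S)

is positive at p_A = p_S whenever the alternative carries less burden,
and decreases as the alternative is made less effective; the margin is
its root.  Root finding is bracketed Brent on an expanding bracket, with
the convergence tolerance placed on the gap (QALYs per 1000) rather
than on p_A, because the gap's slope varies across scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Optional

from scipy.optimize import brentq

from .errors import EquipoiseError
from .scenario import Scenario, evaluate_arm, standard_outcomes

__all__ = ["MarginResult", "qaly_gap", "nmb_gap", "solve_equipoise",
           "solve_margin_qaly", "solve_margin_nmb"]

#: default absolute tolerance on the outcome gap (QALYs per 1000, or
#: currency per 1000 after dividing NMB by the willingness-to-pay)
DEFAULT_GAP_TOL = 1e-4

#: bracket expansion defaults: start width, and the largest admissible p_A
DEFAULT_BRACKET_WIDTH = 0.01
DEFAULT_MAX_P = 0.2


@dataclass(frozen=True)
class MarginResult:
    """Solved equipoise point and the implied non-inferiority margin."""

    p_S: float
    p_A_star: float
    delta: float
    criterion: str                       # "qaly" | "nmb"
    gap_at_solution: float
    solver_iterations: int
    bracket: tuple[float, float]
    wtp: Optional[float] = None
    sample_size: Optional["object"] = None  # trial_design.SampleSize when attached

    def to_json(self, scenario_hash: Optional[str] = None) -> str:
        rec = asdict(self)
        if scenario_hash is not None:
            rec["scenario_hash"] = scenario_hash
        return json.dumps(rec, indent=2)


def qaly_gap(p_A: float, scenario: Scenario) -> float:
    """QALYs per 1000 in the alternative arm at ``p_A`` minus the
    standard arm at ``p_S``.  Positive means the alternative is ahead."""
    alt = evaluate_arm(scenario, scenario.alternative, p_A)[1]
    std = standard_outcomes(scenario)
    return alt.qaly_total - std.qaly_total


def nmb_gap(p_A: float, scenario: Scenario, wtp: Optional[float] = None) -> float:
    """Net-monetary-benefit gap per 1000, expressed in QALY units
    (divided by the willingness-to-pay) so tolerances are comparable
    with :func:`qaly_gap`."""
    lam = scenario.econ.wtp if wtp is None else wtp
    alt = evaluate_arm(scenario, scenario.alternative, p_A)[1]
    std = standard_outcomes(scenario)
    nmb_alt = lam * alt.qaly_total - alt.cost_total
    nmb_std = lam * std.qaly_total - std.cost_total
    return (nmb_alt - nmb_std) / lam


def solve_equipoise(
    gap: Callable[[float], float],
    p_S: float,
    initial_width: float = DEFAULT_BRACKET_WIDTH,
    max_p: float = DEFAULT_MAX_P,
    gap_tol: float = DEFAULT_GAP_TOL,
) -> tuple[float, float, int, tuple[float, float]]:
    """Find the root of a decreasing ``gap`` to the right of ``p_S``.

    Returns ``(p_star, gap_at_solution, n_evaluations, bracket)``.
    The bracket starts at ``[p_S, p_S + initial_width]`` and doubles in
    width until the gap changes sign, failing beyond ``max_p``.
    """
    n_eval = 0

    def g(p: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return gap(p)

    g0 = g(p_S)
    if g0 <= 0.0:
        if g0 >= -gap_tol:
            return p_S, g0, n_eval, (p_S, p_S)
        raise EquipoiseError(
            "alternative never non-inferior: the outcome gap is already "
            f"negative ({g0:.6g} per 1000) at p_A = p_S = {p_S}"
        )

    lo, width = p_S, initial_width
    hi = min(p_S + width, max_p)
    g_hi = g(hi)
    while g_hi > 0.0:
        if hi >= max_p:
            raise EquipoiseError(
                "alternative dominates at all plausible rates: no sign "
                f"change of the outcome gap up to p_A = {max_p}"
            )
        lo, width = hi, width * 2.0
        hi = min(p_S + width, max_p)
        g_hi = g(hi)

    root = brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    n_eval_root = n_eval
    g_root = g(root)
    if abs(g_root) > gap_tol:  # pragma: no cover - slope would have to be ~1e8
        raise EquipoiseError(
            f"equipoise gap {g_root:.3g} per 1000 exceeds tolerance {gap_tol}"
        )
    return float(root), float(g_root), n_eval_root, (lo, hi)


def solve_margin_qaly(
    scenario: Scenario,
    trial=None,
    initial_width: float = DEFAULT_BRACKET_WIDTH,
    max_p: float = DEFAULT_MAX_P,
    gap_tol: float = DEFAULT_GAP_TOL,
) -> MarginResult:
    """Margin at QALY equipoise; attaches a sample size when a
    :class:`~nimargin.trial_design.TrialDesign` is supplied."""
    root, g_root, n_eval, bracket = solve_equipoise(
        lambda p: qaly_gap(p, scenario), scenario.p_S,
        initial_width=initial_width, max_p=max_p, gap_tol=gap_tol,
    )
    result = MarginResult(
        p_S=scenario.p_S, p_A_star=root, delta=root - scenario.p_S,
        criterion="qaly", gap_at_solution=g_root,
        solver_iterations=n_eval, bracket=bracket,
    )
    return _attach_sample_size(result, trial)


def solve_margin_nmb(
    scenario: Scenario,
    trial=None,
    wtp: Optional[float] = None,
    initial_width: float = DEFAULT_BRACKET_WIDTH,
    max_p: float = DEFAULT_MAX_P,
    gap_tol: float = DEFAULT_GAP_TOL,
) -> MarginResult:
    """Margin at net-monetary-benefit equipoise at willingness-to-pay
    ``wtp`` (defaults to the scenario's economic parameter)."""
    lam = scenario.econ.wtp if wtp is None else wtp
    root, g_root, n_eval, bracket = solve_equipoise(
        lambda p: nmb_gap(p, scenario, lam), scenario.p_S,
        initial_width=initial_width, max_p=max_p, gap_tol=gap_tol,
    )
    result = MarginResult(
        p_S=scenario.p_S, p_A_star=root, delta=root - scenario.p_S,
        criterion="nmb", gap_at_solution=g_root,
        solver_iterations=n_eval, bracket=bracket, wtp=lam,
    )
    return _attach_sample_size(result, trial)


def _attach_sample_size(result: MarginResult, trial) -> MarginResult:
    if trial is None or result.delta <= 0:
        return result
    from .trial_design import required_sample_size

    from dataclasses import replace
    return replace(result, sample_size=required_sample_size(trial, result.delta))
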