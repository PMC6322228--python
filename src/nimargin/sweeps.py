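"""One-way uncertainty sweeps over burden scaling and test sensitivity.

Repeats the equipoise search over a grid of per-exam disutility
scalings and protection (sensitivity) multipliers, producing the "line
of equipoise": for each level of exam burden, the alternative-arm event
rate at which the two arms' outcomes are equal, with the margin and the
sample size it implies.  Failed solves are recorded per row with an
explicit status, never dropped; the conservative summary is the largest
n_total over successful rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import CalibrationError, EquipoiseError
from .margin_solver import solve_margin_nmb, solve_margin_qaly
from .qaly_accounting import per_colonoscopy_disutility
from .scenario import Scenario

__all__ = ["SweepGrid", "SweepRow", "run_sweep", "sweep_to_frame",
           "write_sweep_csv", "max_n_total", "plot_equipoise_line"]


class SweepGrid(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    disutility_scalings: tuple[float, ...] = (0.5, 0.8, 1.0, 1.2, 1.5)
    sensitivity_multipliers: tuple[float, ...] = (0.95, 1.00, 1.05)
    criterion: str = "qaly"

    @field_validator("disutility_scalings", "sensitivity_multipliers")
    @classmethod
    def _positive_nonempty(cls, v):
        if not v:
            raise ValueError("grid axis must be non-empty")
        if any(x <= 0 for x in v):
            raise ValueError("grid values must be > 0")
        return v

    @field_validator("criterion")
    @classmethod
    def _criterion(cls, v: str) -> str:
        if v not in ("qaly", "nmb"):
            raise ValueError("criterion must be 'qaly' or 'nmb'")
        return v


@dataclass(frozen=True)
class SweepRow:
    scaling: float
    sensitivity: float
    per_exam_disutility_days: float
    p_A_star: float
    delta: float
    n_total: Optional[int]
    status: str                  # "ok" | "no_sign_change" | "calibration_failed"
    message: str = ""


def _point_scenario(scenario: Scenario, scaling: float, sensitivity: float) -> Scenario:
    burden = scenario.burden.model_copy(update={"scaling": scaling})
    nh = scenario.nh.model_copy(update={"sensitivity_multiplier": sensitivity})
    return scenario.model_copy(update={"burden": burden, "nh": nh})


def run_sweep(grid: SweepGrid, scenario: Scenario, trial=None) -> list[SweepRow]:
    """Solve the margin at every grid point, independently.

    Rows come back sorted by (scaling, sensitivity); the output is a
    pure function of its inputs (deterministic core, no shared state
    across points).
    """
    solve = solve_margin_qaly if grid.criterion == "qaly" else solve_margin_nmb
    rows: list[SweepRow] = []
    for s in sorted(grid.disutility_scalings):
        for m in sorted(grid.sensitivity_multipliers):
            point = _point_scenario(scenario, s, m)
            days = per_colonoscopy_disutility(point.burden)
            try:
                res = solve(point, trial)
                n_total = res.sample_size.n_total if res.sample_size is not None else None
                rows.append(SweepRow(s, m, days, res.p_A_star, res.delta, n_total, "ok"))
            except EquipoiseError as exc:
                rows.append(SweepRow(s, m, days, math.nan, math.nan, None,
                                     "no_sign_change", str(exc)))
            except CalibrationError as exc:
                rows.append(SweepRow(s, m, days, math.nan, math.nan, None,
                                     "calibration_failed", str(exc)))
    return rows


def sweep_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


def write_sweep_csv(rows: list[SweepRow], path: str | Path) -> Path:
    path = Path(path)
    sweep_to_frame(rows).to_csv(path, index=False)
    return path


def max_n_total(rows: list[SweepRow]) -> Optional[int]:
    """Conservative sample-size summary: the largest n_total on the grid."""
    sizes = [r.n_total for r in rows if r.status == "ok" and r.n_total is not None]
    return max(sizes) if sizes else None


def plot_equipoise_line(rows: list[SweepRow], path: str | Path | None = None):
    """Equipoise line: allowed event rate vs per-exam disutility, one
    line per sensitivity multiplier, annotated with sample sizes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = sweep_to_frame(rows)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for m, sub in df[df.status == "ok"].groupby("sensitivity"):
        sub = sub.sort_values("per_exam_disutility_days")
        ax.plot(sub.per_exam_disutility_days, 100 * sub.p_A_star, marker="o",
                label=f"sensitivity x{m:g}")
        for _, r in sub.iterrows():
            if r.n_total is not None and not math.isnan(r.p_A_star):
                ax.annotate(f"{int(r.n_total):,}", (r.per_exam_disutility_days, 100 * r.p_A_star),
                            textcoords="offset points", xytext=(4, 4), fontsize=7)
    ax.set_xlabel("per-colonoscopy disutility (days)")
    ax.set_ylabel("event rate at equipoise (%)")
    ax.set_title("Line of equipoise (annotations: total sample size)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
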