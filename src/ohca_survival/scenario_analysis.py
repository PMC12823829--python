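"""Cohort-level scenario tables, survival gains, and decline-rate sweeps.

Builds the per-municipality table of baseline survival and survival under
earlier-call scenarios (default shifts 1, 5 and 10 minutes), computes the
gains in percentage points, and sweeps the per-minute decline rate ``r``
over its literature range (5-12%) for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .decay_model import (
    DEFAULT_DELTAS,
    DecayParams,
    Municipality,
    format_percent,
    scenario_survival,
)

#: Literature range of the per-minute decline rate, used as the default
#: sensitivity sweep.
DEFAULT_R_GRID = (0.05, 0.07, 0.09, 0.12)


def _check_unique_names(cohort: Sequence[Municipality]) -> None:
    names = [m.name for m in cohort]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate municipality names: {sorted(dupes)}")


@dataclass(frozen=True)
class ScenarioTable:
    """Survival per municipality and early-call shift.

    ``data`` holds unrounded survival fractions: one row per municipality
    with columns ``municipality``, ``category``, ``response_min``,
    ``survival_0`` (baseline) and ``survival_<d>`` per shift ``d``.
    """

    data: pd.DataFrame
    r_used: float
    s0: float
    deltas: tuple[float, ...]

    def survival_columns(self) -> list[str]:
        cols = ["survival_0"]
        cols += [f"survival_{_fmt_delta(d)}" for d in self.deltas if d != 0.0]
        return cols

    def to_percent_frame(self, ndigits: int = 1) -> pd.DataFrame:
        """Human-readable twin: survival rendered as percent strings."""
        out = self.data.copy()
        for col in self.survival_columns():
            out[col] = out[col].map(lambda s: format_percent(s, ndigits))
        return out


@dataclass(frozen=True)
class SensitivityGrid:
    """Survival over a grid of decline rates.

    ``data`` is tidy: one row per (municipality, delta, r) with the
    resulting survival fraction.
    """

    data: pd.DataFrame
    r_values: tuple[float, ...]
    deltas: tuple[float, ...]


def _fmt_delta(d: float) -> str:
    return f"{d:g}".replace(".", "p")


def build_scenario_table(
    cohort: Sequence[Municipality],
    params: DecayParams | None = None,
    deltas: Sequence[float] = DEFAULT_DELTAS,
) -> ScenarioTable:
    """Survival table across a cohort for the configured shifts.

    Each cell equals :func:`~ohca_survival.decay_model.scenario_survival`
    for that (municipality, delta); the baseline column is delta=0.  An
    empty cohort yields an empty table.
    """
    params = params or DecayParams()
    _check_unique_names(cohort)
    if any(d < 0 for d in deltas):
        raise ValueError("deltas must be >= 0")
    rows = []
    for m in cohort:
        row = {
            "municipality": m.name,
            "category": m.category,
            "response_min": m.response_min,
            "survival_0": scenario_survival(m, params, 0.0).survival,
        }
        for d in deltas:
            row[f"survival_{_fmt_delta(d)}"] = scenario_survival(m, params, d).survival
        rows.append(row)
    columns = ["municipality", "category", "response_min", "survival_0"]
    for d in deltas:  # a zero shift aliases the baseline column
        col = f"survival_{_fmt_delta(d)}"
        if col not in columns:
            columns.append(col)
    data = pd.DataFrame(rows, columns=columns)
    return ScenarioTable(
        data=data, r_used=params.r, s0=params.s0, deltas=tuple(float(d) for d in deltas)
    )


def compute_gains(table: ScenarioTable) -> pd.DataFrame:
    """Percentage-point (and relative) gains versus the baseline column.

    ``gain_pp_<d>`` is ``100 * (S(d) - S(0))``; ``gain_rel_<d>`` is the
    relative gain ``S(d)/S(0) - 1``.
    """
    if "survival_0" not in table.data.columns:
        raise ValueError("table has no baseline column")
    out = table.data[["municipality"]].copy()
    base = table.data["survival_0"]
    for d in table.deltas:
        col = f"survival_{_fmt_delta(d)}"
        out[f"gain_pp_{_fmt_delta(d)}"] = 100.0 * (table.data[col] - base)
        out[f"gain_rel_{_fmt_delta(d)}"] = table.data[col] / base - 1.0
    return out


def sensitivity_over_r(
    cohort: Sequence[Municipality],
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    params: DecayParams | None = None,
) -> SensitivityGrid:
    """Sweep the per-minute decline rate over ``r_grid``.

    Returns a tidy grid of survival values; the slice at the table's own
    ``r`` reproduces :func:`build_scenario_table` cell-for-cell.  ``params``
    supplies ``s0`` and ``t0`` (``r`` is taken from the grid).
    """
    base = params or DecayParams()
    for r in r_grid:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"r must be in [0, 1), got {r}")
    _check_unique_names(cohort)
    records = []
    all_deltas = (0.0,) + tuple(d for d in deltas if d != 0.0)
    for r in r_grid:
        p = replace(base, r=r)
        for m in cohort:
            for d in all_deltas:
                res = scenario_survival(m, p, d)
                records.append(
                    {
                        "municipality": m.name,
                        "response_min": m.response_min,
                        "delta_min": d,
                        "r": r,
                        "survival": res.survival,
                    }
                )
    data = pd.DataFrame(
        records, columns=["municipality", "response_min", "delta_min", "r", "survival"]
    )
    return SensitivityGrid(
        data=data,
        r_values=tuple(float(r) for r in r_grid),
        deltas=tuple(float(d) for d in all_deltas),
    )
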