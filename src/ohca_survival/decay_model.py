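"""Exponential survival-decay model for out-of-hospital cardiac arrest.

Survival after cardiac arrest is extremely time-sensitive: each minute of
delay before treatment reduces the chance of survival by a roughly constant
fraction (literature range 5-12% per minute).  The model used throughout
this package is the standard exponential decay

    S(t) = s0 * (1 - r) ** (t - t0)

where ``t`` is the delay in minutes from the emergency call to treatment,
``r`` is the per-minute rate of decline, and ``s0`` is the survival
probability at the reference time ``t0``.  With the default parameterization
(s0=1, t0=0) the baseline survival of a municipality is simply
``(1 - r) ** T`` with ``T`` its mean ambulance response time; a relative
parameterization (per-municipality ``t0``) is available by setting the
fields directly.

Early-call scenarios shift the effective delay: a call placed ``delta``
minutes earlier yields an effective time ``max(T - delta, 0)``.  The delay
can never be negative, so survival is capped at ``s0`` and the result is
flagged as capped when ``delta >= T``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

#: Per-minute decline in survival used as the default: the midpoint of the
#: commonly reported 5-12% range.
DEFAULT_DECLINE_RATE = 0.07

#: Default early-call scenarios, in minutes.
DEFAULT_DELTAS = (1.0, 5.0, 10.0)


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the exponential survival-decay function.

    Parameters
    ----------
    s0 : float
        Baseline survival fraction at the reference time, in (0, 1].
    r : float
        Per-minute decline fraction, in [0, 1).
    t0 : float
        Reference time in minutes, >= 0.  The default 0 means ``s0`` is the
        survival probability at zero delay.
    """

    s0: float = 1.0
    r: float = DEFAULT_DECLINE_RATE
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.s0 <= 1.0:
            raise ValueError(f"s0 must be in (0, 1], got {self.s0}")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must be in [0, 1), got {self.r}")
        if self.t0 < 0.0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")


@dataclass(frozen=True)
class Municipality:
    """One geographic unit with its mean ambulance response time.

    ``response_min`` is the average time in minutes from the emergency call
    to ambulance arrival on scene; ``category`` is a free-text geography
    label (e.g. "big city", "mountain", "island", "rural").
    """

    name: str
    category: str
    response_min: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("municipality name must be non-empty")
        if not self.response_min > 0.0:
            raise ValueError(
                f"response_min must be > 0, got {self.response_min} "
                f"for {self.name!r}"
            )


@dataclass(frozen=True)
class ScenarioResult:
    """Survival under one (municipality, earlier-call shift) scenario.

    ``gain_pp`` is the survival gain versus the unshifted baseline in
    percentage points; ``capped`` is set when the shift exceeds the
    response time so the effective delay was clamped to zero.
    """

    municipality: str
    delta_min: float
    effective_time_min: float
    survival: float
    gain_pp: float
    capped: bool


def survival_at(params: DecayParams, t):
    """Survival probability at delay ``t`` minutes.

    Evaluates ``s0 * (1 - r) ** (t - t0)``.  ``t`` may be a scalar or an
    array; negative delays raise ``ValueError``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("delay t must be >= 0 minutes")
    out = params.s0 * (1.0 - params.r) ** (t_arr - params.t0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def scenario_survival(
    muni: Municipality, params: DecayParams, delta: float
) -> ScenarioResult:
    """Survival when the emergency call is placed ``delta`` minutes earlier.

    The effective delay is ``max(response_min - delta, 0)``; shifts larger
    than the response time cap survival at ``s0`` and set ``capped``.
    """
    if delta < 0.0:
        raise ValueError(f"delta must be >= 0 minutes, got {delta}")
    effective = muni.response_min - delta
    capped = effective <= 0.0
    effective = max(effective, 0.0)
    s = survival_at(params, effective)
    baseline = survival_at(params, muni.response_min)
    return ScenarioResult(
        municipality=muni.name,
        delta_min=float(delta),
        effective_time_min=float(effective),
        survival=float(s),
        gain_pp=100.0 * (float(s) - float(baseline)),
        capped=bool(capped),
    )


def survival_curve(params: DecayParams, t_grid) -> np.ndarray:
    """Deterministic survival curve over a time grid.

    ``t_grid`` must be non-empty, non-negative and strictly increasing.
    Returns an array of shape (n, 2) with columns (t, survival), pointwise
    equal to :func:`survival_at`.
    """
    grid = np.asarray(t_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if np.any(grid < 0.0):
        raise ValueError("t_grid must be non-negative")
    if grid.size > 1 and np.any(np.diff(grid) <= 0.0):
        raise ValueError("t_grid must be strictly increasing")
    return np.column_stack([grid, survival_at(params, grid)])


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), unlike builtin banker's
    rounding.  Used wherever survival fractions are rendered as percent."""
    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def to_percent(fraction: float, ndigits: int = 1) -> float:
    """Survival fraction -> percentage, rounded half-up to ``ndigits``."""
    return round_half_up(100.0 * fraction, ndigits)


def format_percent(fraction: float, ndigits: int = 1) -> str:
    """Render a survival fraction as e.g. ``'47.7%'``."""
    return f"{to_percent(fraction, ndigits):.{ndigits}f}%"
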