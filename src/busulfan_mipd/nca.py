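"""Non-compartmental AUC estimation and proportional dose adjustment.

These are the TDM primitives of the two pre-model-informed dosing eras:
trapezoidal AUC over the sampled window, log-linear terminal-slope
(lambda-z) extrapolation to infinity, and rescaling the previous dose by
the ratio of observed to target AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import (
    ConcObservation,
    InvalidInputError,
    TerminalFitError,
    round_to_step,
)

__all__ = [
    "NcaResult",
    "trapezoid_auc",
    "fit_lambda_z",
    "auc_to_infinity",
    "adjust_dose",
]


@dataclass(frozen=True)
class NcaResult:
    """Trapezoidal AUC over the sampled window plus the extrapolated tail."""

    auc_observed_window: float          # mg·h/L
    auc_extrapolated: float             # mg·h/L
    auc_total: float                    # mg·h/L
    lambda_z: float | None = None       # 1/h
    n_terminal_points: int = 0

    def __post_init__(self) -> None:
        if self.auc_extrapolated < 0:
            raise InvalidInputError("extrapolated AUC must be >= 0")
        if abs(self.auc_total - (self.auc_observed_window + self.auc_extrapolated)) > 1e-9 * max(
            1.0, abs(self.auc_total)
        ):
            raise InvalidInputError("auc_total must equal window + extrapolated AUC")


def _times_and_concs(obs: Sequence[ConcObservation]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([o.time for o in obs], dtype=float)
    c = np.array([o.concentration for o in obs], dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise InvalidInputError("observation times must be strictly increasing")
    return t, c


def trapezoid_auc(obs: Sequence[ConcObservation], log_down: bool = False) -> float:
    """Linear trapezoidal AUC over the observation window (mg·h/L).

    Exact for piecewise-linear profiles.  With ``log_down=True`` segments
    where the concentration declines use the log-trapezoidal formula
    instead (both endpoints must be positive; falls back to linear
    otherwise).  Observations flagged below the LLOQ enter as zero when
    flanked by quantifiable values and are dropped at the edges of the
    series (declared convention).
    """
    if len(obs) < 2:
        raise InvalidInputError("need >= 2 observations for a trapezoidal AUC")
    quant_idx = [i for i, o in enumerate(obs) if not o.below_lloq]
    if quant_idx:
        lo, hi = quant_idx[0], quant_idx[-1]
        obs = [o for i, o in enumerate(obs) if lo <= i <= hi]
    if len(obs) < 2:
        raise InvalidInputError("fewer than 2 usable observations after LLOQ handling")
    t, c = _times_and_concs(obs)
    c = np.where([o.below_lloq for o in obs], 0.0, c)
    if not log_down:
        return float(np.trapezoid(c, t))
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            total += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return float(total)


def fit_lambda_z(obs: Sequence[ConcObservation], n_points: int = 3) -> float:
    """Terminal elimination rate constant (1/h).

    Least-squares slope of ln(concentration) against time over the last
    ``n_points`` quantifiable observations; returns the negated slope.
    Raises :class:`TerminalFitError` on nonpositive concentrations in the
    window or a non-declining tail.
    """
    if n_points < 3:
        raise InvalidInputError("terminal fit needs n_points >= 3")
    usable = [o for o in obs if not o.below_lloq]
    if len(usable) < n_points:
        raise TerminalFitError(f"need {n_points} quantifiable points, have {len(usable)}")
    tail = usable[-n_points:]
    t, c = _times_and_concs(tail)
    if np.any(c <= 0):
        raise TerminalFitError("nonpositive concentration in terminal window")
    slope = stats.linregress(t, np.log(c)).slope
    if slope >= 0:
        raise TerminalFitError(f"terminal slope is non-declining ({slope:.4g}/h)")
    return float(-slope)


def auc_to_infinity(
    obs: Sequence[ConcObservation],
    lambda_z: float,
    n_terminal_points: int = 3,
    log_down: bool = False,
) -> NcaResult:
    """Trapezoidal AUC extrapolated to infinity by C_last / lambda_z."""
    if lambda_z <= 0:
        raise InvalidInputError("lambda_z must be > 0")
    window = trapezoid_auc(obs, log_down=log_down)
    quantifiable = [o for o in obs if not o.below_lloq]
    c_last = quantifiable[-1].concentration if quantifiable else 0.0
    extra = c_last / lambda_z
    return NcaResult(
        auc_observed_window=window,
        auc_extrapolated=extra,
        auc_total=window + extra,
        lambda_z=lambda_z,
        n_terminal_points=n_terminal_points,
    )


def adjust_dose(
    prev_dose: float,
    auc_obs: float,
    auc_target: float,
    granularity: float = 0.1,
) -> float:
    """Proportional dose scaling: new dose = prev · AUC_target / AUC_obs.

    Preserves dose/AUC proportionality before rounding; the result is
    rounded to the configured granularity (ties half up).
    """
    if prev_dose <= 0 or auc_obs <= 0 or auc_target <= 0:
        raise InvalidInputError("adjust_dose arguments must all be > 0")
    raw = prev_dose * auc_target / auc_obs
    return round_to_step(raw, granularity)
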