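"""Closed-form mathematics of the exponentially accelerating Poisson process.

A population of ``N0`` adherent cells growing at per-hour rate ``gamma``
produces mitotic events at instantaneous rate

    lambda(t) = gamma * N0 * exp(gamma * t)      [events / hour / field]

which is a nonhomogeneous Poisson process (NHPP) with cumulative intensity

    M(t) = N0 * (exp(gamma * t) - 1)             [expected events in (0, t]]

Averaged over a measurement period ``t'`` the rate is Lambda = M(t')/t',
and interevent gaps anywhere in the period are approximately exponential
with that rate: P(dt > tau) = exp(-Lambda * tau).  The population doubling
(intermitotic) time follows as t_IMT = ln(2)/gamma.

All times are hours; rates are events per hour for the whole imaged field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthModel",
    "AverageRate",
    "SyncSchedule",
    "rate",
    "cumulative_intensity",
    "average_rate",
    "survival",
    "imt_from_gamma",
    "gamma_from_imt",
    "gamma_from_lambda",
    "expected_cumulative",
]


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth of a cell population in a fixed field of view.

    Parameters
    ----------
    n0 : float
        Number of cells in the field at t = 0.  Must be positive.
    gamma : float
        Population growth rate in 1/hour.  Must be positive.
    """

    n0: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValueError(f"n0 must be positive, got {self.n0}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @property
    def imt(self) -> float:
        """Intermitotic (population doubling) time ln(2)/gamma in hours."""
        return imt_from_gamma(self.gamma)

    def ncell(self, t):
        """Expected cell count N0 * exp(gamma*t) at time ``t`` (hours)."""
        t = _check_time(t)
        return self.n0 * np.exp(self.gamma * t)


@dataclass(frozen=True)
class AverageRate:
    """Event rate averaged over a measurement period.

    ``lam_bar`` is Lambda = M(t')/t' in events/hour; ``horizon`` is the
    period t' in hours over which the average was taken.
    """

    lam_bar: float
    horizon: float

    def __post_init__(self) -> None:
        if not self.lam_bar >= 0:
            raise ValueError(f"lam_bar must be >= 0, got {self.lam_bar}")
        if not self.horizon > 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")


@dataclass(frozen=True)
class SyncSchedule:
    """Time windows in which only a fraction of the population divides.

    Each window is ``(start, end, fraction)`` with times in hours and
    fraction in [0, 1]: the fraction of cells following randomized
    (Poisson) division in that window.  ``1 - fraction`` is the
    synchronized fraction.  Outside every window the fraction is 1.
    Windows must be non-overlapping and ordered by construction.
    """

    windows: tuple[tuple[float, float, float], ...] = ()

    def __init__(self, windows: Sequence[Sequence[float]] = ()) -> None:
        wins = tuple(tuple(float(v) for v in w) for w in windows)
        for w in wins:
            if len(w) != 3:
                raise ValueError(f"window must be (start, end, fraction), got {w}")
            start, end, frac = w
            if not start < end:
                raise ValueError(f"window start must precede end, got {w}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction must lie in [0, 1], got {frac}")
        wins = tuple(sorted(wins, key=lambda w: w[0]))
        for (s0, e0, _), (s1, _, _) in zip(wins, wins[1:]):
            if s1 < e0:
                raise ValueError(f"windows overlap: ({s0}, {e0}) and starting {s1}")
        object.__setattr__(self, "windows", wins)

    def fraction_at(self, t: float) -> float:
        """Active (randomly dividing) fraction at time ``t``."""
        for start, end, frac in self.windows:
            if start <= t < end:
                return frac
        return 1.0


def _check_time(t, name: str = "t"):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{name} must be non-negative")
    return t


def rate(t, model: GrowthModel):
    """Instantaneous mitotic event rate lambda(t) = gamma*N0*exp(gamma*t).

    Parameters
    ----------
    t : float or array
        Time in hours, >= 0.
    model : GrowthModel

    Returns
    -------
    float or ndarray
        Events per hour for the whole field; strictly increasing in t.
    """
    t = _check_time(t)
    out = model.gamma * model.n0 * np.exp(model.gamma * t)
    return float(out) if out.ndim == 0 else out


def cumulative_intensity(t, model: GrowthModel):
    """Expected event count M(t) = N0*(exp(gamma*t) - 1) in (0, t].

    Uses ``expm1`` so the homogeneous limit gamma*t -> 0 is exact.
    """
    t = _check_time(t)
    out = model.n0 * np.expm1(model.gamma * t)
    return float(out) if out.ndim == 0 else out


def inverse_cumulative_intensity(m, model: GrowthModel):
    """Time at which the expected event count reaches ``m`` (inverse of M).

    t = ln(1 + m/N0) / gamma; the workhorse of the exact NHPP sampler.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("expected count must be non-negative")
    out = np.log1p(m / model.n0) / model.gamma
    return float(out) if out.ndim == 0 else out


def average_rate(horizon: float, model: GrowthModel) -> AverageRate:
    """Period-averaged rate Lambda = M(t')/t' over ``horizon`` hours."""
    if not horizon > 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return AverageRate(lam_bar=cumulative_intensity(horizon, model) / horizon, horizon=float(horizon))


def survival(tau, lam: AverageRate | float):
    """Interevent survival P(dt > tau) = exp(-Lambda*tau).

    ``lam`` may be an :class:`AverageRate` or a bare rate in 1/hour.
    """
    tau = _check_time(tau, "tau")
    lam_bar = lam.lam_bar if isinstance(lam, AverageRate) else float(lam)
    out = np.exp(-lam_bar * tau)
    return float(out) if out.ndim == 0 else out


def imt_from_gamma(gamma: float) -> float:
    """Intermitotic time t_IMT = ln(2)/gamma (hours)."""
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return math.log(2.0) / gamma


def gamma_from_imt(imt: float) -> float:
    """Growth rate gamma = ln(2)/t_IMT (1/hour)."""
    if not imt > 0:
        raise ValueError(f"imt must be positive, got {imt}")
    return math.log(2.0) / imt


def gamma_from_lambda(lam: AverageRate, n0: float) -> float:
    """Growth rate gamma solving Lambda = (N0/t')*(exp(gamma*t') - 1).

    The averaged-rate relation is monotone in gamma and inverts in closed
    form: gamma = ln(1 + Lambda*t'/N0) / t'.  ``log1p`` keeps the
    homogeneous limit (Lambda*t'/N0 -> 0, gamma -> Lambda/N0) accurate.

    Raises
    ------
    ValueError
        If Lambda <= 0 or n0 <= 0 (no positive gamma exists).
    """
    if not n0 > 0:
        raise ValueError(f"n0 must be positive, got {n0}")
    if not lam.lam_bar > 0:
        raise ValueError(f"lam_bar must be positive to recover gamma, got {lam.lam_bar}")
    return math.log1p(lam.lam_bar * lam.horizon / n0) / lam.horizon


def expected_cumulative(t, model: GrowthModel, schedule: SyncSchedule | None = None):
    """Expected accumulated events by time ``t`` under partial synchronization.

    The fractional multiplier of each schedule window scales the event
    accrual inside that window:

        C(t) = sum over pieces of f_piece * [M(piece_end) - M(piece_start)]

    with f = 1 outside every window.  Continuous and nondecreasing in t;
    equal to M(t) for an empty schedule.
    """
    t = _check_time(t)
    if schedule is None or not schedule.windows:
        return cumulative_intensity(t, model)

    def _single(tv: float) -> float:
        total = 0.0
        cursor = 0.0
        for start, end, frac in schedule.windows:
            if tv <= start:
                break
            # unsynchronized stretch before the window
            total += cumulative_intensity(min(tv, start), model) - cumulative_intensity(cursor, model)
            upper = min(tv, end)
            total += frac * (cumulative_intensity(upper, model) - cumulative_intensity(start, model))
            cursor = upper
            if tv <= end:
                break
        if tv > cursor:
            total += cumulative_intensity(tv, model) - cumulative_intensity(cursor, model)
        return total

    if t.ndim == 0:
        return _single(float(t))
    return np.array([_single(tv) for tv in t.ravel()]).reshape(t.shape)
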