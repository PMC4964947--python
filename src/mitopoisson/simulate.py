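"""Synthetic mitotic event streams.

Samples the exponentially accelerating NHPP by exact time rescaling: a
unit-rate homogeneous Poisson stream m_1 < m_2 < ... is drawn up to the
cumulative intensity M(horizon) and mapped through the closed-form inverse
t = ln(1 + m/N0)/gamma, so the sampled law is exact (no thinning, no
rejection).  Synchronization windows are applied afterwards by independent
binomial thinning, and spatial positions are placed uniformly over the
field, optionally avoiding a central circular void that mimics the
cell-free area of a scratch-wound assay.

All samplers take an explicit integer seed; ``derive_seeds`` splits one
master seed into independent per-stage streams.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .events import EventSeries
from .model import GrowthModel, SyncSchedule, cumulative_intensity, inverse_cumulative_intensity

__all__ = [
    "derive_seeds",
    "simulate_event_times",
    "apply_synchronization",
    "assign_positions",
    "simulate_series",
]


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def simulate_event_times(
    model: GrowthModel,
    horizon: float,
    seed: int,
    frame_interval: float = 0.25,
    field: tuple[float, float] = (640.0, 540.0),
) -> EventSeries:
    """Sample NHPP mitotic event times on [0, horizon].

    The number of events is Poisson with mean M(horizon); conditional on
    the count, the transformed variables M(t_i)/M(horizon) are iid uniform
    order statistics, so times are obtained by inverting M at sorted
    uniform draws scaled to M(horizon).  Bitwise reproducible given seed.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be non-negative, got {horizon}")
    rng = np.random.default_rng(seed)
    if horizon == 0:
        times = np.empty(0)
    else:
        total = cumulative_intensity(horizon, model)
        n = rng.poisson(total)
        marks = np.sort(rng.uniform(0.0, total, size=n))
        times = inverse_cumulative_intensity(marks, model)
        times = np.clip(times, 0.0, horizon)
    return EventSeries(times=times, horizon=max(horizon, np.finfo(float).tiny), frame_interval=frame_interval, field=field)


def apply_synchronization(series: EventSeries, schedule: SyncSchedule, seed: int) -> EventSeries:
    """Thin an event series according to a synchronization schedule.

    Each event falling in window k is kept independently with probability
    f_k (its active fraction); events outside all windows are kept.  The
    result is an NHPP with intensity f(t) * lambda(t).
    """
    if len(series) == 0 or not schedule.windows:
        return series
    rng = np.random.default_rng(seed)
    probs = np.array([schedule.fraction_at(t) for t in series.times])
    keep = rng.uniform(size=len(series)) < probs
    pos = series.positions[keep] if series.positions is not None else None
    return replace(series, times=series.times[keep], positions=pos)


def assign_positions(
    series: EventSeries,
    seed: int,
    field: Optional[tuple[float, float]] = None,
    void: Optional[tuple[float, float, float]] = None,
) -> EventSeries:
    """Place events uniformly over the field, avoiding an optional void.

    ``void`` is (cx, cy, radius): a circular exclusion zone (the scratch)
    inside which no event may fall; points are redrawn by rejection.

    Raises
    ------
    ValueError
        If the void covers the whole field (rejection could not finish).
    """
    w, h = field if field is not None else series.field
    if not (w > 0 and h > 0):
        raise ValueError("field extents must be positive")
    if void is not None:
        cx, cy, r = void
        corners = [(0, 0), (w, 0), (0, h), (w, h)]
        if all((x - cx) ** 2 + (y - cy) ** 2 <= r**2 for x, y in corners):
            raise ValueError("void circle covers the entire field")
    rng = np.random.default_rng(seed)
    n = len(series)
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(0.0, w, size=n)
    pos[:, 1] = rng.uniform(0.0, h, size=n)
    if void is not None:
        cx, cy, r = void
        inside = ((pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2) < r**2
        while np.any(inside):
            k = int(inside.sum())
            pos[inside, 0] = rng.uniform(0.0, w, size=k)
            pos[inside, 1] = rng.uniform(0.0, h, size=k)
            inside = ((pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2) < r**2
    return replace(series, positions=pos, field=(float(w), float(h)))


def simulate_series(
    model: GrowthModel,
    horizon: float,
    seed: int,
    frame_interval: float = 0.25,
    field: tuple[float, float] = (640.0, 540.0),
    schedule: Optional[SyncSchedule] = None,
    void: Optional[tuple[float, float, float]] = None,
) -> EventSeries:
    """One-call generator: times, optional thinning, and positions.

    Per-stage seeds are derived deterministically from ``seed`` so each
    stage (times / thinning / placement) has an independent stream.
    """
    s_time, s_thin, s_pos = derive_seeds(seed, 3)
    series = simulate_event_times(model, horizon, s_time, frame_interval=frame_interval, field=field)
    if schedule is not None and schedule.windows:
        series = apply_synchronization(series, schedule, s_thin)
    return assign_positions(series, s_pos, void=void)
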