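"""Event-series container and frame-interval censoring.

An :class:`EventSeries` is the point datum of the whole analysis: the
ordered times (and optionally positions and frame indices) of observed
mitoses in one field of view.  Because frames are acquired at a fixed
interval (15 min in the reference protocol), an observer reading the
frames can only resolve interevent gaps of at least one frame interval;
gaps between co-frame events are recorded merely as "below the interval"
— interval-censored observations handled by :class:`CensoredGaps`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["EventSeries", "CensoredGaps", "apply_frame_censoring", "accumulated_events"]


@dataclass(frozen=True)
class EventSeries:
    """Ordered mitotic events observed in one field of view.

    Parameters
    ----------
    times : ndarray
        Event times in hours, sorted ascending, within [0, horizon].
    horizon : float
        Total observed duration t' in hours.
    frame_interval : float
        Acquisition interval in hours (default 0.25 h = 15 min).
    positions : ndarray or None
        Per-event (x, y), shape (n, 2), in ``position_unit``.
    field : tuple
        (width, height) of the field in position units.
    position_unit : str
        "px" or "um"; carried as metadata, never guessed.

    Frame indices are derived, not stored: event at time t belongs to
    frame floor(t / frame_interval).  Interevent gaps and displacements
    are likewise always derived from ``times`` / ``positions``.
    """

    times: np.ndarray
    horizon: float
    frame_interval: float = 0.25
    positions: Optional[np.ndarray] = None
    field: tuple[float, float] = (640.0, 540.0)
    position_unit: str = "px"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if not self.horizon > 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError("times must be sorted ascending")
            if times[0] < 0 or times[-1] > self.horizon:
                raise ValueError("times must lie within [0, horizon]")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            object.__setattr__(self, "positions", pos)
            if pos.shape != (times.size, 2):
                raise ValueError(f"positions must have shape ({times.size}, 2), got {pos.shape}")
            w, h = self.field
            if pos.size and (pos[:, 0].min() < 0 or pos[:, 0].max() > w or pos[:, 1].min() < 0 or pos[:, 1].max() > h):
                raise ValueError("positions must lie within the field bounds")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return len(self)

    @property
    def frames(self) -> np.ndarray:
        """0-based frame index of each event: floor(t / frame_interval)."""
        return np.floor(self.times / self.frame_interval).astype(int)

    @property
    def gaps(self) -> np.ndarray:
        """Raw interevent gaps dt between consecutive events (hours)."""
        return np.diff(self.times)

    def restrict(self, start: float, end: float) -> "EventSeries":
        """Sub-series of events with start <= t < end, re-origined at ``start``.

        The returned series has horizon ``end - start``; use it to fit an
        unsynchronized reference phase of a longer experiment.
        """
        if not 0 <= start < end <= self.horizon + 1e-12:
            raise ValueError(f"invalid restriction ({start}, {end}) for horizon {self.horizon}")
        mask = (self.times >= start) & (self.times < end)
        pos = self.positions[mask] if self.positions is not None else None
        return replace(self, times=self.times[mask] - start, horizon=end - start, positions=pos)


@dataclass(frozen=True)
class CensoredGaps:
    """Interevent gaps after frame-interval censoring.

    ``exact`` holds gaps resolved to at least one frame interval (each a
    multiple of the interval); ``n_censored`` counts gaps known only to be
    shorter than one interval (consecutive events sharing a frame).
    """

    exact: np.ndarray
    n_censored: int
    frame_interval: float

    def __post_init__(self) -> None:
        exact = np.asarray(self.exact, dtype=float)
        object.__setattr__(self, "exact", exact)
        if self.n_censored < 0:
            raise ValueError("n_censored must be >= 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if exact.size and exact.min() < self.frame_interval - 1e-12:
            raise ValueError("exact gaps must be at least one frame interval")

    @property
    def n_exact(self) -> int:
        return int(self.exact.size)

    @property
    def n_total(self) -> int:
        return self.n_exact + self.n_censored


def apply_frame_censoring(series: EventSeries) -> CensoredGaps:
    """Reduce an event series to frame-resolution interevent gaps.

    Event times are snapped to their frame: consecutive events in frames
    i < j yield an exact gap (j - i) * frame_interval; consecutive events
    sharing a frame yield one censored gap (known only as below the
    interval).  A series with fewer than two events has no gaps.
    """
    frames = series.frames
    if frames.size < 2:
        return CensoredGaps(exact=np.empty(0), n_censored=0, frame_interval=series.frame_interval)
    dframes = np.diff(frames)
    exact = dframes[dframes > 0] * series.frame_interval
    return CensoredGaps(
        exact=exact.astype(float),
        n_censored=int(np.sum(dframes == 0)),
        frame_interval=series.frame_interval,
    )


def accumulated_events(series: EventSeries) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous counting process N(t) of the series.

    Returns ``(t, count)`` where ``t`` are the distinct event times and
    ``count[i]`` the number of events with time <= t[i]; the final value
    equals the total event count.  An empty series gives empty arrays.
    """
    if len(series) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    t, multiplicity = np.unique(series.times, return_counts=True)
    return t, np.cumsum(multiplicity)
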