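"""Event-series CSV format, image-stack loading and JSON reports.

There is no community standard for mitotic event lists, so the package
uses a plain CSV with header comment lines carrying the metadata::

    # horizon_h = 40.0
    # frame_interval_h = 0.25
    # field_width = 640.0
    # field_height = 540.0
    # position_unit = px
    time_h,x,y,frame

``time_h`` is required; ``x``/``y`` are optional positions in
``position_unit``; ``frame`` is optional and, when absent, derived as
floor(time_h / frame_interval).  Reports are JSON with all estimates,
seeds and parameters, reproducible byte-for-byte given the same inputs
except for the timestamp field.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .events import EventSeries
from .imaging import FrameStack

__all__ = [
    "EventCsvError",
    "MissingColumnError",
    "UnsortedTimesError",
    "TimeOutOfRangeError",
    "read_event_csv",
    "write_event_csv",
    "series_from_dataframe",
    "series_to_dataframe",
    "read_frame_stack",
    "write_report",
]


class EventCsvError(ValueError):
    """Base class for event-CSV schema problems."""


class MissingColumnError(EventCsvError):
    """A required column (time_h) is absent."""


class UnsortedTimesError(EventCsvError):
    """Times are not sorted ascending (row order is ambiguous)."""


class TimeOutOfRangeError(EventCsvError):
    """An event time lies outside [0, horizon]."""


_META_DEFAULTS = {
    "horizon_h": None,
    "frame_interval_h": 0.25,
    "field_width": 640.0,
    "field_height": 540.0,
    "position_unit": "px",
}


def series_from_dataframe(
    df: pd.DataFrame,
    horizon: Optional[float] = None,
    frame_interval: float = 0.25,
    field: tuple[float, float] = (640.0, 540.0),
    position_unit: str = "px",
) -> EventSeries:
    """Validate a DataFrame with ``time_h`` (and optional x, y) columns."""
    if "time_h" not in df.columns:
        raise MissingColumnError("required column 'time_h' is missing")
    times = df["time_h"].to_numpy(dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise UnsortedTimesError("time_h must be sorted ascending")
    if horizon is None:
        horizon = float(times[-1]) if times.size else 1.0
        horizon = max(horizon, np.finfo(float).tiny)
    if times.size and (times[0] < 0 or times[-1] > horizon):
        raise TimeOutOfRangeError(f"event times must lie within [0, {horizon}]")
    positions = None
    if "x" in df.columns and "y" in df.columns and df[["x", "y"]].notna().all().all():
        positions = df[["x", "y"]].to_numpy(dtype=float)
    return EventSeries(
        times=times,
        horizon=float(horizon),
        frame_interval=float(frame_interval),
        positions=positions,
        field=field,
        position_unit=position_unit,
    )


def series_to_dataframe(series: EventSeries) -> pd.DataFrame:
    df = pd.DataFrame({"time_h": series.times})
    if series.positions is not None:
        df["x"] = series.positions[:, 0]
        df["y"] = series.positions[:, 1]
    df["frame"] = series.frames if len(series) else np.array([], dtype=int)
    return df


def read_event_csv(path: Union[str, Path]) -> EventSeries:
    """Read an event series, taking metadata from '#' header lines."""
    path = Path(path)
    meta = dict(_META_DEFAULTS)
    with open(path) as fh:
        lines = fh.readlines()
    n_comments = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comments += 1
        body = line[1:].strip()
        if "=" in body:
            key, _, value = body.partition("=")
            key = key.strip()
            if key in meta:
                meta[key] = value.strip() if key == "position_unit" else float(value)
    df = pd.read_csv(path, skiprows=n_comments, float_precision="round_trip")
    if df.columns.size == 1 and df.columns[0].startswith("#"):
        raise MissingColumnError("file contains no header row after comments")
    return series_from_dataframe(
        df,
        horizon=meta["horizon_h"],
        frame_interval=meta["frame_interval_h"],
        field=(meta["field_width"], meta["field_height"]),
        position_unit=meta["position_unit"],
    )


def write_event_csv(series: EventSeries, path: Union[str, Path]) -> None:
    """Write an event series with metadata header comments."""
    path = Path(path)
    header = [
        f"# horizon_h = {series.horizon!r}",
        f"# frame_interval_h = {series.frame_interval!r}",
        f"# field_width = {series.field[0]!r}",
        f"# field_height = {series.field[1]!r}",
        f"# position_unit = {series.position_unit}",
    ]
    df = series_to_dataframe(series)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_frame_stack(path: Union[str, Path], frame_interval: float = 0.25, pixel_size: Optional[float] = None) -> FrameStack:
    """Load a multi-page TIFF, an .npy stack, or a directory of frames.

    Directory frames (PNG/TIFF) are taken in lexicographic order, which
    must equal time order.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        frames = np.stack([np.asarray(iio.imread(f), dtype=float) for f in files])
    elif path.suffix == ".npy":
        frames = np.load(path).astype(float)
    else:
        import tifffile

        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    timestamps = np.arange(frames.shape[0]) * frame_interval
    return FrameStack(frames=frames, timestamps=timestamps, pixel_size=pixel_size)


def write_frame_stack(stack: FrameStack, path: Union[str, Path]) -> None:
    """Write a stack as multi-page TIFF (or .npy if so suffixed)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, stack.frames)
    else:
        import tifffile

        arr = np.clip(stack.frames, 0.0, 1.0)
        tifffile.imwrite(path, (arr * 65535).astype(np.uint16))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: Union[str, Path], *, fit=None, sync=None, spatial=None, params: Optional[dict] = None) -> dict:
    """Write a JSON report of whatever results are present.

    At least one of ``fit`` (ProliferationResults or FitResult dict),
    ``sync`` (SynchronizationResults), ``spatial`` (SpatialAccumulation)
    must be given.  The report repeats all parameters and seeds used so a
    rerun with the same config reproduces it except for ``timestamp``.
    """
    if fit is None and sync is None and spatial is None:
        raise ValueError("nothing to report: provide at least one result")
    from . import __version__

    doc: dict = {"software": "mitopoisson", "version": __version__, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if params:
        doc["params"] = _jsonable(params)
    if fit is not None:
        doc["fit"] = _jsonable(fit.to_dict() if hasattr(fit, "to_dict") else fit)
    if sync is not None:
        doc["sync"] = _jsonable(sync.to_dict() if hasattr(sync, "to_dict") else sync)
    if spatial is not None:
        from .spatial import csr_deviation

        doc["spatial"] = _jsonable(
            {
                "center": list(spatial.center),
                "r_max": spatial.r_max,
                "radii": spatial.radii,
                "counts": spatial.counts,
                "density_per_area": spatial.density,
                "unit": spatial.unit,
                "csr_deviation": csr_deviation(spatial) if spatial.counts[-1] > 0 else None,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc
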