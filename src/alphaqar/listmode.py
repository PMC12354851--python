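"""List-mode detection events: data model, CSV I/O, session merging and pixel binning.

A position-sensitive alpha camera records each scintillation event individually
("list mode"): an estimated centroid position and a timestamp. Images are only
formed later, by binning events onto a pixel grid — a 2D histogram. Keeping the
raw events allows decay-exact quantification over arbitrary acquisition
schedules and splicing of interrupted recordings.

Coordinates are micrometres in the detector plane; time is seconds. Each event's
timestamp is relative to the start of its acquisition window, and windows are
placed on a common reference axis (t = 0 is the quantification reference time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionWindow",
    "AcquisitionSchedule",
    "EventList",
    "CountsImage",
    "read_listmode",
    "write_listmode",
    "bin_events",
    "merge_sessions",
]

#: the camera's native pixel pitch, micrometres
DEFAULT_PIXEL_SPACING_UM = 26.5


@dataclass(frozen=True)
class AcquisitionWindow:
    """A contiguous recording interval [t_start, t_end) on the reference time axis."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_start < self.t_end):
            raise ValueError(
                f"invalid acquisition window: need 0 <= t_start < t_end, "
                f"got [{self.t_start}, {self.t_end}]"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered, non-overlapping acquisition windows relative to a reference time."""

    windows: tuple[AcquisitionWindow, ...]
    reference_time_label: str = "reference time 0"

    def __post_init__(self) -> None:
        windows = tuple(self.windows)
        object.__setattr__(self, "windows", windows)
        if len(windows) == 0:
            raise ValueError("schedule must contain at least one window")
        starts = [w.t_start for w in windows]
        if starts != sorted(starts):
            raise ValueError("acquisition windows must be sorted by t_start")
        for prev, nxt in zip(windows, windows[1:]):
            if nxt.t_start < prev.t_end:
                raise ValueError(
                    f"overlapping acquisition windows: [{prev.t_start}, {prev.t_end}) "
                    f"and [{nxt.t_start}, {nxt.t_end})"
                )

    def __len__(self) -> int:
        return len(self.windows)

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[float, float]], reference_time_label: str = "reference time 0"
    ) -> "AcquisitionSchedule":
        return cls(tuple(AcquisitionWindow(a, b) for a, b in pairs), reference_time_label)

    def to_pairs(self) -> list[list[float]]:
        return [[w.t_start, w.t_end] for w in self.windows]


@dataclass
class EventList:
    """Detection events with per-event acquisition-window membership.

    ``x``, ``y`` are detector coordinates in micrometres; ``t`` is seconds since
    the start of the event's window; ``window_index`` maps each event into
    ``schedule.windows``.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    window_index: np.ndarray
    schedule: AcquisitionSchedule

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.window_index = np.asarray(self.window_index, dtype=np.intp)
        n = len(self.x)
        if not (len(self.y) == len(self.t) == len(self.window_index) == n):
            raise ValueError("event arrays must have equal length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("event positions must be finite")
        if n and (self.t < 0).any():
            raise ValueError("event timestamps must be non-negative")
        if n:
            lo, hi = self.window_index.min(), self.window_index.max()
            if lo < 0 or hi >= len(self.schedule):
                raise ValueError("window_index out of range for schedule")
            durations = np.array([w.duration for w in self.schedule.windows])
            if (self.t > durations[self.window_index]).any():
                raise ValueError("event time exceeds its acquisition window duration")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def absolute_time(self) -> np.ndarray:
        """Event times on the common reference axis (window start + offset)."""
        starts = np.array([w.t_start for w in self.schedule.windows])
        return starts[self.window_index] + self.t


@dataclass
class CountsImage:
    """Integer event counts on a square-pixel grid.

    ``origin`` is the physical position (micrometres) of the low edge of pixel
    (0, 0); row index maps to y, column index to x.
    """

    counts: np.ndarray
    pixel_spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    schedule: AcquisitionSchedule | None = None
    dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def read_listmode(path: str | Path, sidecar: str | Path | None = None) -> EventList:
    """Read a list-mode CSV (``x_um,y_um,t_s``) plus optional schedule sidecar JSON.

    When no sidecar is given, a single window spanning [0, max(t)] (or [0, 1] for
    an empty file) is assumed. Malformed rows raise with the offending line
    number; negative timestamps violate the event invariant and raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError as exc:  # pandas reports the bad line in its message
        raise ValueError(f"malformed list-mode file {path}: {exc}") from exc
    expected = ["x_um", "y_um", "t_s"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    bad = df[expected].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {int(np.flatnonzero(bad)[0]) + 2}")

    if sidecar is None:
        candidate = path.with_suffix(".json")
        sidecar = candidate if candidate.exists() else None
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        schedule = AcquisitionSchedule.from_pairs(
            [tuple(w) for w in meta["windows"]],
            meta.get("reference_time_label", "reference time 0"),
        )
    else:
        t_max = float(df["t_s"].max()) if len(df) else 1.0
        schedule = AcquisitionSchedule.from_pairs([(0.0, max(t_max, 1.0))])

    t = df["t_s"].to_numpy()
    if len(df) and "window" in df.columns:
        widx = df["window"].to_numpy(dtype=np.intp)
    else:
        # assign by absolute time against window spans (single-session files: all zeros)
        widx = np.zeros(len(df), dtype=np.intp)
        if len(schedule) > 1 and len(df):
            edges = np.array([w.t_start for w in schedule.windows])
            widx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(schedule) - 1)
            t = t - edges[widx]
    return EventList(df["x_um"].to_numpy(), df["y_um"].to_numpy(), t, widx, schedule)


def write_listmode(events: EventList, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write events as CSV (absolute timestamps) and the schedule as sidecar JSON."""
    path = Path(path)
    pd.DataFrame(
        {"x_um": events.x, "y_um": events.y, "t_s": events.absolute_time}
    ).to_csv(path, index=False)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "windows": events.schedule.to_pairs(),
                "reference_time_label": events.schedule.reference_time_label,
            }
        )
    )


def bin_events(
    events: EventList,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_UM,
    grid_shape: tuple[int, int] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> CountsImage:
    """Bin events into square pixels of ``pixel_spacing`` micrometres.

    Bins are half-open ``[edge, edge + spacing)``; events on the top/right outer
    edge or outside the grid are dropped and counted in ``CountsImage.dropped``.
    If ``grid_shape`` is None it is chosen to cover the event extent.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    ox, oy = origin
    if grid_shape is None:
        if len(events) == 0:
            grid_shape = (1, 1)
        else:
            ncol = int(np.floor((events.x.max() - ox) / pixel_spacing)) + 1
            nrow = int(np.floor((events.y.max() - oy) / pixel_spacing)) + 1
            grid_shape = (max(nrow, 1), max(ncol, 1))
    nrow, ncol = grid_shape

    col = np.floor((events.x - ox) / pixel_spacing).astype(np.int64)
    row = np.floor((events.y - oy) / pixel_spacing).astype(np.int64)
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    counts = np.bincount(row[inside] * ncol + col[inside], minlength=nrow * ncol)
    counts = counts.reshape(nrow, ncol)
    return CountsImage(
        counts=counts,
        pixel_spacing=pixel_spacing,
        origin=origin,
        schedule=events.schedule,
        dropped=int((~inside).sum()),
    )


def merge_sessions(lists: list[EventList], session_offsets: list[float]) -> EventList:
    """Splice recordings from multiple sessions onto a common reference axis.

    ``session_offsets[i]`` shifts every window of session ``i`` so that all
    sessions share the reference time of the merged schedule. Windows that
    overlap after offsetting indicate inconsistent offsets and raise.
    """
    if len(lists) != len(session_offsets):
        raise ValueError("one offset per session required")
    if not lists:
        raise ValueError("no sessions to merge")
    windows: list[tuple[float, float, int, int]] = []  # start, end, session, local idx
    for si, (el, off) in enumerate(zip(lists, session_offsets)):
        for wi, w in enumerate(el.schedule.windows):
            windows.append((w.t_start + off, w.t_end + off, si, wi))
    windows.sort()
    merged_sched = AcquisitionSchedule.from_pairs([(a, b) for a, b, _, _ in windows])

    # map (session, local window) -> merged window index
    remap = {(si, wi): k for k, (_, _, si, wi) in enumerate(windows)}
    xs, ys, ts, wids = [], [], [], []
    for si, el in enumerate(lists):
        xs.append(el.x)
        ys.append(el.y)
        ts.append(el.t)
        wids.append(np.array([remap[(si, int(w))] for w in el.window_index], dtype=np.intp))
    return EventList(
        np.concatenate(xs) if xs else np.empty(0),
        np.concatenate(ys),
        np.concatenate(ts),
        np.concatenate(wids),
        merged_sched,
    )


def write_counts_tiff(image: CountsImage, path: str | Path) -> None:
    """Write counts as 32-bit TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.counts.astype(np.float32))
    meta = {
        "pixel_spacing_um": image.pixel_spacing,
        "origin_um": list(image.origin),
        "dropped": image.dropped,
    }
    if image.schedule is not None:
        meta["windows"] = image.schedule.to_pairs()
    path.with_suffix(".json").write_text(json.dumps(meta))
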