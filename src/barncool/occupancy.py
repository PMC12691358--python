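"""Headgate occupancy extraction from per-frame detection records.

Converts a stream of bounding-box detections (class ``cow`` or ``empty``,
top-left corner in pixels) into per-section occupied/empty intervals,
applies the chunked-video subsampling and time scaling used when a long
recording is reduced to one-minute samples, and summarizes empty-interval
durations per section.

Section membership is decided by the bounding box's top-left corner: the
detector under study logs exactly that point, so the corner — not the box
center — is the canonical location key (center assignment is available via
``use_center=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Section",
    "SectionMap",
    "DetectionRecord",
    "OccupancyInterval",
    "OccupancySummary",
    "ChunkPlan",
    "DETECTION_COLUMNS",
    "assign_section",
    "assign_sections",
    "extract_intervals",
    "chunk_sample",
    "summarize_empty",
    "read_detections",
    "write_detections",
    "write_intervals",
]

#: Exact column order of the detection CSV interchange format.
DETECTION_COLUMNS = [
    "camera_id",
    "frame",
    "time_s",
    "class",
    "x_tl",
    "y_tl",
    "w",
    "h",
    "conf",
]

CLASSES = ("cow", "empty")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Section:
    """One headgate section: an axis-aligned pixel rectangle with an id.

    ``x0 <= x < x1`` and ``y0 <= y < y1`` define containment (half-open,
    so adjacent sections sharing an edge do not double-claim interior
    pixels; exact shared-edge ties are broken by lowest id in
    :func:`assign_section`).
    """

    box_id: int
    x0: float
    y0: float
    x1: float
    y1: float
    side: Literal["left", "right"]

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle for section {self.box_id}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class SectionMap:
    """The six headgate-section boxes with left/right grouping.

    The barn layout has sections 1-3 on the left side of the pen (1 top
    left) and 4-6 on the right (6 bottom right); three sprinklers serve
    each section.
    """

    sections: tuple[Section, ...]
    sprinklers_per_section: int = 3

    def __post_init__(self) -> None:
        ids = [s.box_id for s in self.sections]
        if len(ids) != len(set(ids)):
            raise ValueError("section box ids must be unique")
        if self.sprinklers_per_section < 1:
            raise ValueError("sprinklers_per_section must be >= 1")

    @property
    def box_ids(self) -> list[int]:
        return sorted(s.box_id for s in self.sections)

    def __getitem__(self, box_id: int) -> Section:
        for s in self.sections:
            if s.box_id == box_id:
                return s
        raise KeyError(box_id)

    @classmethod
    def default(cls, width: int = 1080, height: int = 1080,
                sprinklers_per_section: int = 3) -> "SectionMap":
        """Six equal boxes in a 2x3 grid: ids 1-3 left column, 4-6 right."""
        w2, h3 = width / 2, height / 3
        secs = []
        for i in range(3):
            secs.append(Section(i + 1, 0, i * h3, w2, (i + 1) * h3, "left"))
        for i in range(3):
            secs.append(Section(i + 4, w2, i * h3, width, (i + 1) * h3, "right"))
        return cls(tuple(secs), sprinklers_per_section)

    @classmethod
    def from_json(cls, path) -> "SectionMap":
        with open(path) as fh:
            data = json.load(fh)
        secs = tuple(
            Section(d["id"], d["x0"], d["y0"], d["x1"], d["y1"], d["side"])
            for d in data["sections"]
        )
        return cls(secs, data.get("sprinklers_per_section", 3))

    def to_json(self, path) -> None:
        data = {
            "sections": [
                {"id": s.box_id, "x0": s.x0, "y0": s.y0, "x1": s.x1,
                 "y1": s.y1, "side": s.side}
                for s in self.sections
            ],
            "sprinklers_per_section": self.sprinklers_per_section,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


@dataclass(frozen=True)
class DetectionRecord:
    """One per-frame detection: class, top-left bbox corner, size, confidence."""

    camera_id: str
    frame: int
    time_s: float
    cls: Literal["cow", "empty"]
    x_tl: float
    y_tl: float
    w: float
    h: float
    conf: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bbox width and height must be positive")


@dataclass(frozen=True)
class OccupancyInterval:
    """A maximal run of one state (occupied/empty) in one section."""

    box_id: int
    state: Literal["occupied", "empty"]
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("interval must have positive length")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class OccupancySummary:
    """Per-section and pooled mean/SD of empty-interval durations (seconds).

    SD is the population standard deviation (divide by n), so a single
    interval yields SD 0 rather than NaN. Sections with no empty interval
    are simply absent from ``per_section``.
    """

    per_section: dict[int, tuple[float, float, int]]  # box_id -> (mean, sd, n)
    overall_mean: float
    overall_sd: float
    n_intervals: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"box_id": b, "mean_empty_s": m, "sd_empty_s": s, "n_intervals": n}
            for b, (m, s, n) in sorted(self.per_section.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChunkPlan:
    """Chunked-video sampling: keep ``sample_s`` out of every ``period_s``.

    The farm sprinklers run one minute in every fifteen, so a one-minute
    sample per 15-minute window of footage observes exactly the windows in
    which water could have been dispensed. ``scale`` converts observed
    minutes back to daily sprinkler-on minutes and is rounded as printed
    (e.g. 600/105 -> 5.71) before any downstream arithmetic.
    """

    period_s: float = 900.0
    sample_s: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.sample_s <= self.period_s):
            raise ValueError("require 0 < sample_s <= period_s")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _record_point(rec, use_center: bool) -> tuple[float, float]:
    if use_center:
        return rec.x_tl + rec.w / 2.0, rec.y_tl + rec.h / 2.0
    return rec.x_tl, rec.y_tl


def assign_section(record: DetectionRecord, section_map: SectionMap,
                   use_center: bool = False) -> int | None:
    """Return the id of the section containing the record's corner, or None.

    A point lying on a shared edge of two sections is assigned to the
    lowest box id (deterministic tie-break).
    """
    x, y = _record_point(record, use_center)
    hits = [s.box_id for s in section_map.sections if s.contains(x, y)]
    return min(hits) if hits else None


def assign_sections(records: pd.DataFrame, section_map: SectionMap,
                    use_center: bool = False) -> pd.Series:
    """Vectorized :func:`assign_section` over a detection DataFrame.

    Returns a nullable-integer Series aligned with ``records`` (``<NA>``
    for unassigned records).
    """
    x = records["x_tl"].to_numpy(float)
    y = records["y_tl"].to_numpy(float)
    if use_center:
        x = x + records["w"].to_numpy(float) / 2.0
        y = y + records["h"].to_numpy(float) / 2.0
    out = np.full(len(records), -1, dtype=np.int64)
    # iterate sections in descending id so the lowest id wins on ties
    for s in sorted(section_map.sections, key=lambda s: -s.box_id):
        inside = (x >= s.x0) & (x <= s.x1) & (y >= s.y0) & (y <= s.y1)
        out[inside] = s.box_id
    ser = pd.Series(out, index=records.index, dtype="Int64")
    return ser.mask(ser == -1)


def extract_intervals(records: pd.DataFrame, fps: float,
                      gap_merge_s: float = 1.0,
                      box_id: int | None = None) -> list[OccupancyInterval]:
    """Run-length encode one section's per-frame classes into intervals.

    ``records`` must hold a single section's detections sorted by time.
    Each frame contributes ``1/fps`` seconds: a frame at time t covers
    ``[t, t + 1/fps)``. Consecutive same-class frames whose gap is at most
    ``gap_merge_s`` extend the current interval (absorbing short detector
    dropouts); longer gaps or a class change close it.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if len(records) == 0:
        return []
    t = records["time_s"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("records must be sorted by time_s")
    cls = records["class"].to_numpy()
    if box_id is None:
        ids = records["box_id"].unique() if "box_id" in records else [None]
        if len(ids) != 1:
            raise ValueError("extract_intervals expects a single section")
        box_id = int(ids[0]) if ids[0] is not None else -1

    dt = 1.0 / fps
    tol = 1e-9 * dt  # absorb float rounding in frame timestamps
    intervals: list[OccupancyInterval] = []
    start = t[0]
    end = t[0] + dt
    state = cls[0]
    for i in range(1, len(t)):
        gap = t[i] - end
        if cls[i] == state and gap <= gap_merge_s + tol:
            end = t[i] + dt
        else:
            intervals.append(_make_interval(box_id, state, start, end))
            start, end, state = t[i], t[i] + dt, cls[i]
    intervals.append(_make_interval(box_id, state, start, end))
    return intervals


def _make_interval(box_id: int, cls: str, start: float, end: float) -> OccupancyInterval:
    state = "occupied" if cls == "cow" else "empty"
    return OccupancyInterval(box_id, state, start, end)


def chunk_sample(records: pd.DataFrame, plan: ChunkPlan,
                 source_minutes: float,
                 daily_on_minutes: float) -> tuple[pd.DataFrame, float]:
    """Keep the first ``sample_s`` of every ``period_s`` window; return scale.

    The scale is the printed-precision ratio of daily sprinkler-on minutes
    to observed source minutes (600/105 -> 5.71, 600/90 -> 6.7, 420/105
    -> 4): rounding happens *here*, before any savings arithmetic, because
    the published savings figures are stated at that precision.
    """
    if source_minutes <= 0:
        raise ValueError("source_minutes must be positive")
    t = records["time_s"].to_numpy(float)
    keep = np.mod(t, plan.period_s) < plan.sample_s
    scale = _printed_scale(daily_on_minutes / source_minutes)
    return records.loc[keep], scale


def _printed_scale(ratio: float) -> float:
    """Round a minutes ratio to its printed precision.

    Convention: exact integers stay integers (420/105 -> 4); a ratio whose
    decimal expansion repeats a single digit is shown to one place
    (600/90 = 6.66... -> 6.7); anything else to two places
    (600/105 = 5.714... -> 5.71). Downstream savings arithmetic uses these
    printed values, which is the precision at which the published annual
    figures are stated.
    """
    if abs(ratio - round(ratio)) < 1e-9:
        return float(round(ratio))
    d = [int(ratio * 10**k) % 10 for k in (1, 2, 3)]
    if d[0] == d[1] == d[2]:
        return round(ratio, 1)
    return round(ratio, 2)


def summarize_empty(intervals: Iterable[OccupancyInterval]) -> OccupancySummary:
    """Mean and population SD of empty-interval durations, per section and pooled."""
    by_section: dict[int, list[float]] = {}
    for iv in intervals:
        if iv.state == "empty":
            by_section.setdefault(iv.box_id, []).append(iv.length_s)
    per_section = {}
    pooled: list[float] = []
    for b, lens in by_section.items():
        arr = np.asarray(lens, float)
        per_section[b] = (float(arr.mean()), float(arr.std(ddof=0)), len(arr))
        pooled.extend(lens)
    if pooled:
        p = np.asarray(pooled, float)
        overall_mean, overall_sd = float(p.mean()), float(p.std(ddof=0))
    else:
        overall_mean = overall_sd = 0.0
    return OccupancySummary(per_section, overall_mean, overall_sd, len(pooled))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection CSV missing columns: {missing}")
    return df[DETECTION_COLUMNS]


def write_detections(df: pd.DataFrame, path) -> None:
    df[DETECTION_COLUMNS].to_csv(path, index=False)


def write_intervals(intervals: Sequence[OccupancyInterval], path) -> None:
    pd.DataFrame(
        [
            {"box_id": iv.box_id, "state": iv.state,
             "start_s": iv.start_s, "end_s": iv.end_s}
            for iv in intervals
        ]
    ).to_csv(path, index=False)
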