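"""Synthetic occupancy processes, detection streams, and climate tables.

No farm footage accompanies this package, so every downstream stage is
exercised on simulated data with the statistical structure the analysis
assumes: each headgate section alternates between occupied and empty
dwells drawn from a configurable distribution (exponential by default —
a memoryless on/off process whose single parameter matches the published
per-section means); a detector observes the true state once per frame,
with configurable miss, false-positive, label-flip and bounding-box
jitter noise; and a daily climate table reproduces any given days/hours
summary for the two sprinkler-trigger temperature bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .occupancy import (
    DETECTION_COLUMNS,
    OccupancyInterval,
    SectionMap,
)
from .water_model import ClimateSummary

__all__ = [
    "DwellSpec",
    "TruthConfig",
    "NoiseConfig",
    "gen_occupancy_truth",
    "gen_detection_stream",
    "gen_climate",
    "summarize_climate",
    "write_climate",
]


@dataclass(frozen=True)
class DwellSpec:
    """Distribution of one state's dwell times (seconds).

    families: ``exponential`` (mean), ``lognormal`` (mean with coefficient
    of variation ``cv``), ``fixed`` (constant = mean).
    """

    family: Literal["exponential", "lognormal", "fixed"] = "exponential"
    mean_s: float = 60.0
    cv: float = 1.0  # lognormal only

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "lognormal", "fixed"):
            raise ValueError(f"unknown dwell family {self.family!r}")
        if self.mean_s <= 0:
            raise ValueError("dwell mean must be positive")
        if self.cv <= 0:
            raise ValueError("lognormal cv must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean_s, n)
        if self.family == "fixed":
            return np.full(n, self.mean_s)
        # lognormal parameterized by mean and cv
        sigma2 = np.log(1.0 + self.cv**2)
        mu = np.log(self.mean_s) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), n)


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth occupancy process for a set of sections."""

    sections: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    fps: float = 30.0
    duration_s: float = 6300.0  # 105 min of footage
    occupied_dwell: DwellSpec = field(
        default_factory=lambda: DwellSpec("exponential", 180.0))
    empty_dwell: DwellSpec = field(
        default_factory=lambda: DwellSpec("exponential", 71.0))
    start_state: Literal["occupied", "empty", "random"] = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.sections:
            raise ValueError("at least one section required")


@dataclass(frozen=True)
class NoiseConfig:
    """Detector imperfection model applied per truth frame."""

    miss_rate: float = 0.0
    false_rate: float = 0.0
    jitter_px: float = 0.0
    flip_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "false_rate", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")


def gen_occupancy_truth(config: TruthConfig,
                        section_map: SectionMap | None = None
                        ) -> dict[int, list[OccupancyInterval]]:
    """Sample per-section alternating occupied/empty interval sequences.

    Intervals are contiguous, start at 0, and exactly partition
    ``[0, duration_s]`` (the final dwell is clipped). Identical config and
    seed reproduce identical output bit for bit.
    """
    sections = (tuple(section_map.box_ids) if section_map is not None
                else tuple(config.sections))
    rng = np.random.default_rng(config.seed)
    out: dict[int, list[OccupancyInterval]] = {}
    for box_id in sections:
        if config.start_state == "random":
            state = "occupied" if rng.random() < 0.5 else "empty"
        else:
            state = config.start_state
        intervals: list[OccupancyInterval] = []
        t = 0.0
        while t < config.duration_s:
            spec = (config.occupied_dwell if state == "occupied"
                    else config.empty_dwell)
            d = float(spec.sample(rng, 1)[0])
            end = min(t + d, config.duration_s)
            if end > t:
                intervals.append(OccupancyInterval(box_id, state, t, end))
            t = end
            state = "empty" if state == "occupied" else "occupied"
        out[box_id] = intervals
    return out


def _state_at_frames(intervals: list[OccupancyInterval],
                     frame_times: np.ndarray) -> np.ndarray:
    """Truth state per frame time as a bool array (True = occupied).

    A frame at time t belongs to the interval covering [start, end); the
    terminal boundary t == duration falls to the last interval.
    """
    starts = np.array([iv.start_s for iv in intervals])
    occupied = np.array([iv.state == "occupied" for iv in intervals])
    idx = np.searchsorted(starts, frame_times, side="right") - 1
    idx = np.clip(idx, 0, len(intervals) - 1)
    return occupied[idx]


def gen_detection_stream(truth: dict[int, list[OccupancyInterval]],
                         section_map: SectionMap,
                         fps: float,
                         noise: NoiseConfig | None = None,
                         seed: int = 0,
                         camera_id: str = "cam1") -> pd.DataFrame:
    """Emit one detection record per section per frame, with noise.

    Each record's bounding-box top-left corner is drawn uniformly in its
    section rectangle (then jittered by up to ``jitter_px``); the class
    label equals the truth state unless flipped; a frame is silently
    dropped with probability ``miss_rate``; spurious records appear with
    probability ``false_rate`` per frame, with uniform class and a corner
    in a random section box.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if noise is None:
        noise = NoiseConfig()
    rng = np.random.default_rng(seed)

    duration = max(iv.end_s for ivs in truth.values() for iv in ivs)
    n_frames = int(round(duration * fps))
    frame_idx = np.arange(n_frames)
    frame_t = frame_idx / fps

    parts: list[pd.DataFrame] = []
    for box_id in sorted(truth):
        sec = section_map[box_id]
        occ = _state_at_frames(truth[box_id], frame_t)
        keep = rng.random(n_frames) >= noise.miss_rate
        n = int(keep.sum())
        cls = np.where(occ[keep], "cow", "empty")
        if noise.flip_rate > 0:
            flip = rng.random(n) < noise.flip_rate
            cls = np.where(flip, np.where(cls == "cow", "empty", "cow"), cls)
        # box roughly half the section, corner uniform so it stays inside
        w = (sec.x1 - sec.x0) * 0.5
        h = (sec.y1 - sec.y0) * 0.5
        x = rng.uniform(sec.x0, sec.x1, n)
        y = rng.uniform(sec.y0, sec.y1, n)
        if noise.jitter_px > 0:
            x = x + rng.uniform(-noise.jitter_px, noise.jitter_px, n)
            y = y + rng.uniform(-noise.jitter_px, noise.jitter_px, n)
        parts.append(pd.DataFrame({
            "camera_id": camera_id,
            "frame": frame_idx[keep],
            "time_s": frame_t[keep],
            "class": cls,
            "x_tl": x,
            "y_tl": y,
            "w": w,
            "h": h,
            "conf": rng.uniform(0.5, 1.0, n),
        }))

    if noise.false_rate > 0:
        fp = rng.random(n_frames) < noise.false_rate
        n = int(fp.sum())
        secs = [section_map[b] for b in section_map.box_ids]
        pick = rng.integers(0, len(secs), n)
        x = np.empty(n)
        y = np.empty(n)
        for i, s in enumerate(secs):
            m = pick == i
            x[m] = rng.uniform(s.x0, s.x1, int(m.sum()))
            y[m] = rng.uniform(s.y0, s.y1, int(m.sum()))
        parts.append(pd.DataFrame({
            "camera_id": camera_id,
            "frame": frame_idx[fp],
            "time_s": frame_t[fp],
            "class": np.where(rng.random(n) < 0.5, "cow", "empty"),
            "x_tl": x,
            "y_tl": y,
            "w": 50.0,
            "h": 50.0,
            "conf": rng.uniform(0.5, 1.0, n),
        }))

    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["time_s", "x_tl"], kind="stable").reset_index(drop=True)
    return df[DETECTION_COLUMNS]


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


def gen_climate(profile: ClimateSummary, year: int = 2022,
                seed: int | None = None) -> pd.DataFrame:
    """Expand a two-band climate summary into a per-day exposure table.

    Returns columns ``date, hours_above_22_2, hours_above_32_2``. Days in
    each band are placed contiguously in mid-summer; with a seed, daily
    hours are jittered in mean-preserving pairs so re-summarizing the
    table recovers the input profile exactly.
    """
    n_low = int(profile.days_above_low)
    n_high = int(profile.days_above_high)
    n_days = max(n_low, n_high, 1)
    start = pd.Timestamp(year=year, month=5, day=1)
    dates = pd.date_range(start, periods=n_days, freq="D")
    low = np.zeros(n_days)
    high = np.zeros(n_days)
    low[:n_low] = profile.hours_per_day_low
    high[:n_high] = profile.hours_per_day_high
    if seed is not None:
        rng = np.random.default_rng(seed)
        for arr, n, mean in ((low, n_low, profile.hours_per_day_low),
                             (high, n_high, profile.hours_per_day_high)):
            for i in range(0, n - 1, 2):
                d = rng.uniform(0, min(mean, 24 - mean) * 0.5)
                arr[i] += d
                arr[i + 1] -= d
    df = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "hours_above_22_2": low,
        "hours_above_32_2": high,
    })
    if n_low == 0 and n_high == 0:
        return df.iloc[0:0]
    return df


def summarize_climate(table: pd.DataFrame) -> ClimateSummary:
    """Recompute the two-band summary from a per-day exposure table."""
    low = table["hours_above_22_2"].to_numpy(float) if len(table) else np.array([])
    high = table["hours_above_32_2"].to_numpy(float) if len(table) else np.array([])
    low_days = low > 0
    high_days = high > 0
    return ClimateSummary(
        days_above_low=int(low_days.sum()),
        hours_per_day_low=float(low[low_days].mean()) if low_days.any() else 0.0,
        days_above_high=int(high_days.sum()),
        hours_per_day_high=float(high[high_days].mean()) if high_days.any() else 0.0,
    )


def write_climate(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
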