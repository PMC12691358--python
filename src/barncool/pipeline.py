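"""End-to-end convenience: detection stream -> occupancy -> water savings.

Glues the module stages together the way the full analysis runs: assign
each detection to a headgate section by its bounding-box corner, extract
per-section occupied/empty intervals, summarize empty durations, and feed
the mean into the sprinkler savings model for both temperature bands.
"""

from __future__ import annotations

import pandas as pd

from .occupancy import (
    ChunkPlan,
    OccupancySummary,
    SectionMap,
    assign_sections,
    chunk_sample,
    extract_intervals,
    summarize_empty,
)
from .water_model import (
    ClimateSummary,
    SavingsInputs,
    SavingsReport,
    SprinklerSchedule,
    scenario_report,
)

__all__ = ["occupancy_summary_from_detections", "savings_from_summary"]


def occupancy_summary_from_detections(
    detections: pd.DataFrame,
    section_map: SectionMap,
    fps: float,
    gap_merge_s: float = 1.0,
    plan: ChunkPlan | None = None,
    source_minutes: float | None = None,
    daily_on_minutes: float | None = None,
    use_center: bool = False,
) -> tuple[OccupancySummary, float | None]:
    """Detections -> per-section empty-duration summary (+ chunk scale).

    When ``plan`` is given the stream is first chunk-sampled (keeping
    ``sample_s`` out of every ``period_s``) and the printed-precision
    scale is returned alongside the summary; otherwise scale is None.
    """
    df = detections.copy()
    df["box_id"] = assign_sections(df, section_map, use_center=use_center)
    df = df.dropna(subset=["box_id"])
    scale = None
    if plan is not None:
        if source_minutes is None or daily_on_minutes is None:
            raise ValueError("chunk sampling needs source and daily on-minutes")
        df, scale = chunk_sample(df, plan, source_minutes, daily_on_minutes)
    intervals = []
    for box_id, grp in df.groupby("box_id", observed=True):
        grp = grp.sort_values("time_s", kind="stable")
        intervals.extend(
            extract_intervals(grp, fps, gap_merge_s, box_id=int(box_id)))
    return summarize_empty(intervals), scale


def savings_from_summary(
    mean_empty_s: float,
    low_scale: float,
    high_scale: float,
    climate: ClimateSummary | None = None,
    schedule: SprinklerSchedule | None = None,
) -> SavingsReport:
    """Annual savings scenario from one mean empty duration per section."""
    if climate is None:
        climate = ClimateSummary()
    low = SavingsInputs(mean_empty_s, low_scale, climate.days_above_low, 1)
    high = SavingsInputs(mean_empty_s, high_scale, climate.days_above_high, 3)
    return scenario_report(low, high, schedule)
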