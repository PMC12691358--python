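"""Section assignment, interval extraction, chunk scaling, and summaries."""

import numpy as np
import pandas as pd
import pytest

from barncool import (
    ChunkPlan,
    DetectionRecord,
    SectionMap,
    TruthConfig,
    assign_section,
    assign_sections,
    chunk_sample,
    extract_intervals,
    gen_detection_stream,
    gen_occupancy_truth,
    summarize_empty,
)
from barncool.synthetic_data import DwellSpec


def _rec(x, y, t=0.0, cls="empty", frame=0):
    return DetectionRecord("cam1", frame, t, cls, x, y, 50.0, 50.0, 0.9)


def _frames(classes, fps=30.0, t0=0.0, box_id=1, skip=()):
    rows = []
    for i, c in enumerate(classes):
        if i in skip:
            continue
        rows.append({"camera_id": "cam1", "frame": i, "time_s": t0 + i / fps,
                     "class": c, "x_tl": 10.0, "y_tl": 10.0, "w": 50.0,
                     "h": 50.0, "conf": 0.9, "box_id": box_id})
    return pd.DataFrame(rows)


class TestAssignSection:
    def test_interior_corner_assigned_to_containing_box(self, section_map):
        sec = section_map[1]
        r = _rec((sec.x0 + sec.x1) / 2, (sec.y0 + sec.y1) / 2)
        assert assign_section(r, section_map) == 1

    def test_corner_outside_all_boxes_unassigned(self, section_map):
        assert assign_section(_rec(-5.0, -5.0), section_map) is None

    def test_shared_edge_breaks_tie_to_lowest_id(self, section_map):
        s2, s3 = section_map[2], section_map[3]
        # sections 2 and 3 share the horizontal edge y = s2.y1 == s3.y0
        assert s2.y1 == s3.y0
        edge = _rec(s2.x0 + 1.0, s2.y1)
        candidates = [s.box_id for s in section_map.sections
                      if s.contains(edge.x_tl, edge.y_tl)]
        assert sorted(candidates) == [2, 3]
        assert assign_section(edge, section_map) == 2

    def test_vectorized_assignment_matches_scalar(self, section_map, rng):
        df = pd.DataFrame({
            "x_tl": rng.uniform(-50, 1130, 300),
            "y_tl": rng.uniform(-50, 1130, 300),
            "w": 50.0, "h": 50.0,
        })
        got = assign_sections(df, section_map)
        for i in range(len(df)):
            want = assign_section(_rec(df.x_tl[i], df.y_tl[i]), section_map)
            assert (got[i] is pd.NA and want is None) or got[i] == want

    def test_center_assignment_flag(self, section_map):
        sec = section_map[4]
        # corner in section 1, center (corner + 25 px) strictly in section 4
        r = _rec(sec.x0 - 20.0, sec.y0 + 10.0)
        assert assign_section(r, section_map) == 1
        assert assign_section(r, section_map, use_center=True) == 4


class TestExtractIntervals:
    def test_run_of_identical_frames_is_one_interval(self):
        ivs = extract_intervals(_frames(["empty"] * 30), fps=30.0)
        assert len(ivs) == 1
        assert ivs[0].state == "empty"
        assert ivs[0].length_s == pytest.approx(1.0)

    def test_short_gap_merged_long_gap_split(self):
        # empty run, 2-frame gap, empty run: gap (2/30 s) < 0.5 s -> merged
        df = _frames(["empty"] * 30, skip={10, 11})
        merged = extract_intervals(df, fps=30.0, gap_merge_s=0.5)
        assert len(merged) == 1
        assert merged[0].length_s == pytest.approx(1.0)
        split = extract_intervals(df, fps=30.0, gap_merge_s=0.01)
        assert len(split) == 2

    def test_alternating_classes_alternate_intervals(self):
        df = _frames(["cow", "empty"] * 10)
        ivs = extract_intervals(df, fps=30.0)
        assert len(ivs) == 20
        assert all(iv.length_s == pytest.approx(1 / 30.0) for iv in ivs)
        assert [iv.state for iv in ivs[:4]] == ["occupied", "empty"] * 2

    def test_unsorted_input_rejected(self):
        df = _frames(["empty"] * 5).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            extract_intervals(df, fps=30.0)

    def test_conservation_of_covered_time(self, section_map):
        cfg = TruthConfig(sections=(1,), fps=10.0, duration_s=500.0, seed=21)
        truth = gen_occupancy_truth(cfg)
        df = gen_detection_stream(truth, section_map, cfg.fps, seed=22)
        df["box_id"] = 1
        ivs = extract_intervals(df, cfg.fps, gap_merge_s=0.0)
        total = sum(iv.length_s for iv in ivs)
        assert total == pytest.approx(500.0, abs=1 / (2 * cfg.fps))

    def test_zero_noise_recovers_truth_up_to_frame_quantization(self, section_map):
        cfg = TruthConfig(sections=(2,), fps=10.0, duration_s=400.0, seed=31,
                          empty_dwell=DwellSpec("exponential", 30.0),
                          occupied_dwell=DwellSpec("exponential", 40.0))
        truth = gen_occupancy_truth(cfg)
        df = gen_detection_stream(truth, section_map, cfg.fps, seed=32)
        df["box_id"] = 2
        got = extract_intervals(df, cfg.fps, gap_merge_s=0.0, box_id=2)

        # independent oracle: sample the truth state at each frame time and
        # run-length encode by hand
        frame_t = np.arange(int(400.0 * cfg.fps)) / cfg.fps
        starts = np.array([iv.start_s for iv in truth[2]])
        states = [iv.state for iv in truth[2]]
        idx = np.clip(np.searchsorted(starts, frame_t, "right") - 1,
                      0, len(states) - 1)
        runs = []
        run_start = 0
        for i in range(1, len(idx) + 1):
            if i == len(idx) or states[idx[i]] != states[idx[run_start]]:
                runs.append((states[idx[run_start]],
                             frame_t[run_start],
                             frame_t[i - 1] + 1 / cfg.fps))
                run_start = i
        assert len(got) == len(runs)
        for g, (state, start, end) in zip(got, runs):
            assert g.state == state
            assert g.start_s == pytest.approx(start)
            assert g.end_s == pytest.approx(end)
        # and each boundary is within one frame of a true transition
        for g in got:
            assert np.min(np.abs(starts - g.start_s)) <= 1 / cfg.fps or g.start_s == 0.0


class TestChunkSample:
    @pytest.mark.parametrize("minutes,daily_on,n_chunks,scale", [
        (105, 600, 7, 5.71),
        (90, 600, 6, 6.7),
        (105, 420, 7, 4.0),
    ])
    def test_published_scales_and_chunk_counts(self, minutes, daily_on,
                                               n_chunks, scale):
        fps = 2.0
        n = int(minutes * 60 * fps)
        df = pd.DataFrame({"time_s": np.arange(n) / fps, "class": "empty"})
        kept, got_scale = chunk_sample(df, ChunkPlan(), minutes, daily_on)
        assert got_scale == scale
        # first 60 s of every 900 s window survives
        windows = np.unique(kept["time_s"].to_numpy() // 900)
        assert len(windows) == n_chunks
        assert (np.mod(kept["time_s"], 900) < 60).all()

    def test_scale_positive_source_required(self):
        df = pd.DataFrame({"time_s": [0.0]})
        with pytest.raises(ValueError):
            chunk_sample(df, ChunkPlan(), 0, 600)


class TestSummarizeEmpty:
    def test_single_interval_mean_sd(self):
        from barncool import OccupancyInterval
        s = summarize_empty([OccupancyInterval(1, "empty", 0.0, 71.0)])
        assert s.per_section[1] == (71.0, 0.0, 1)

    def test_two_interval_hand_arithmetic(self):
        from barncool import OccupancyInterval
        ivs = [OccupancyInterval(1, "empty", 0.0, 60.0),
               OccupancyInterval(1, "empty", 100.0, 182.0)]
        mean, sd, n = summarize_empty(ivs).per_section[1]
        assert (mean, sd, n) == (71.0, 11.0, 2)

    def test_sections_without_empty_intervals_absent(self):
        from barncool import OccupancyInterval
        s = summarize_empty([OccupancyInterval(5, "occupied", 0.0, 10.0)])
        assert s.per_section == {}
        assert s.n_intervals == 0

    def test_simulated_mean_recovered_within_3se(self, section_map):
        cfg = TruthConfig(sections=tuple(range(1, 7)), fps=10.0,
                          duration_s=20_000.0, seed=41,
                          empty_dwell=DwellSpec("exponential", 47.0))
        truth = gen_occupancy_truth(cfg)
        s = summarize_empty(iv for ivs in truth.values() for iv in ivs)
        se = 47.0 / np.sqrt(s.n_intervals)
        assert abs(s.overall_mean - 47.0) < 3 * se

    def test_overall_consistent_with_per_section(self, section_map):
        cfg = TruthConfig(sections=(1, 2, 3), fps=10.0, duration_s=3000.0,
                          seed=51)
        truth = gen_occupancy_truth(cfg)
        s = summarize_empty(iv for ivs in truth.values() for iv in ivs)
        weighted = sum(m * n for m, _, n in s.per_section.values())
        total_n = sum(n for *_, n in s.per_section.values())
        assert s.overall_mean == pytest.approx(weighted / total_n)
        assert s.n_intervals == total_n
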