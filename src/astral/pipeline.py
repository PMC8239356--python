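"""End-to-end orchestration of the event-analysis pipeline.

``run_pipeline`` chains the stages — optional pre-processing, grain-wise
detection, 3-D labelling (optional watershed), volume cleanup, event
cataloguing, neighbour/repeat analysis and the recording summary — and can
persist every artifact under its conventional filename. The pipeline is a
pure function of (stack, config): identical inputs produce identical
outputs and byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, event_catalog, neighbourhood, preprocess, summaries
from .config import Config
from .event_catalog import EventTable
from .neighbourhood import NeighbourRecord, RepeatClassification
from .stack_io import ImageStack, persist_artifacts
from .summaries import SummaryStats

__all__ = ["PipelineResult", "run_pipeline", "events_frame"]


@dataclass(frozen=True)
class PipelineResult:
    """Every stage output of one recording."""

    stack: ImageStack  # the (possibly pre-processed) stack the stages ran on
    mask: np.ndarray
    labels: np.ndarray
    table: EventTable
    neighbours: list[NeighbourRecord]
    classification: RepeatClassification
    summary: SummaryStats
    motion_trace: preprocess.MotionTrace | None = None

    @property
    def n_events(self) -> int:
        return len(self.table)


def events_frame(table: EventTable) -> pd.DataFrame:
    """One row per event: id, volume, onset/end, extents, centroid."""
    rows = [
        {
            "event_id": r.id,
            "volume_voxels": r.volume,
            "t_onset": r.t_onset,
            "t_end": r.t_end,
            "extent_x": r.extent_x,
            "extent_y": r.extent_y,
            "extent_t": r.extent_t,
            "centroid_t": r.centroid[0],
            "centroid_y": r.centroid[1],
            "centroid_x": r.centroid[2],
        }
        for r in table.records
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "volume_voxels", "t_onset", "t_end", "extent_x",
                 "extent_y", "extent_t", "centroid_t", "centroid_y", "centroid_x"],
    )


def run_pipeline(
    stack: ImageStack,
    config: Config | None = None,
    *,
    correct_motion: bool = False,
    correct_intensity: bool = False,
    motion_grid: int = 8,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on one recording.

    Pre-processing order is motion first, then intensity (zero-filled
    borders left by the translation would otherwise bias the frame means).
    With ``out_dir`` set, all artifacts are written there (waves.npy,
    labelled_waves.npy, black_and_white.tiff, events.csv, neighbours.csv,
    neighbour_statistics.csv, repeats.csv, singles.csv, summary.csv and,
    when motion correction ran, motion_trace.csv) plus a manifest of
    content checksums.
    """
    config = config or Config()
    trace = None
    if correct_motion:
        stack, trace = preprocess.correct_motion(stack, grid=motion_grid)
    if correct_intensity:
        stack = preprocess.correct_intensity(stack)

    mask = detection.extract_events(stack, config.grain_size, config.sd_threshold)
    labels = detection.create_masks(mask, config.use_watershed, stack)
    labels = detection.cleanup(labels, config.volume_threshold)
    mask = labels > 0  # post-cleanup foreground

    voxel_lists = event_catalog.label_events(labels)
    table = event_catalog.generate_metadata(voxel_lists, stack)
    neighbours = neighbourhood.find_neighbours(table, config.tolerance_xy, config.tolerance_t)
    classification = neighbourhood.find_repeats(neighbours, table, config.intersection_threshold)
    recording_minutes = stack.n_frames * stack.frame_interval / 60.0
    summary = summaries.summarise(
        table,
        neighbours,
        n_cells=config.n_cells,
        recording_minutes=recording_minutes,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )

    result = PipelineResult(
        stack=stack,
        mask=mask,
        labels=labels,
        table=table,
        neighbours=neighbours,
        classification=classification,
        summary=summary,
        motion_trace=trace,
    )
    if out_dir is not None:
        tables = {
            "events": events_frame(table),
            "neighbours": neighbourhood.neighbours_frame(neighbours),
            "neighbour_statistics": neighbourhood.neighbour_statistics_frame(neighbours, table),
            "repeats": neighbourhood.repeats_frame(classification, table),
            "singles": neighbourhood.singles_frame(classification, table),
            "summary": summary.to_frame(),
        }
        if trace is not None:
            tables["motion_trace"] = pd.DataFrame(
                {
                    "frame": np.arange(len(trace.shifts)),
                    "dy": trace.shifts[:, 0],
                    "dx": trace.shifts[:, 1],
                }
            )
        persist_artifacts(out_dir, mask=mask, labels=labels, tables=tables)
    return result
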