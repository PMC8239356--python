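"""Recording-level metrics for between-group comparison.

The per-recording quantities exported for external statistics are:

- **incidence** — detected events per cell per minute (needs a user-supplied
  cell count; cells are not segmented by this pipeline);
- **intercellular propagation speed** — centre-to-centre xy distance of a
  neighbour pair divided by its onset-time difference, in um/s; simultaneous
  pairs carry no propagation time and are excluded;
- **duration** — temporal extent of an event, in seconds;
- **distance travelled** — diagonal of an event's xy bounding box, in um;
- **neighbouring-wave count** — per event, the number of distinct neighbours
  with a *later* onset (consequent waves).

Medians are reported per recording; group testing is left to external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_catalog import EventTable
from .neighbourhood import NeighbourRecord
from .stack_io import DEFAULT_FRAME_INTERVAL, DEFAULT_PIXEL_SIZE

__all__ = [
    "SummaryStats",
    "incidence",
    "propagation_speeds",
    "durations_and_distances",
    "neighbour_counts",
    "summarise",
]


@dataclass(frozen=True)
class SummaryStats:
    """One recording's summary row; absent metrics are ``None``."""

    n_events: int
    n_neighbour_pairs: int
    incidence: float | None  # events / cell / min
    median_propagation_speed: float | None  # um/s
    median_duration: float | None  # s
    median_distance: float | None  # um
    mean_neighbour_count: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def incidence(
    table: EventTable, n_cells: int | None, recording_minutes: float
) -> float | None:
    """Events per cell per minute; ``None`` (with a warning) without a cell count."""
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be > 0")
    if n_cells is None:
        import warnings

        warnings.warn("n_cells not provided; incidence not computed", stacklevel=2)
        return None
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return len(table) / (n_cells * recording_minutes)


def propagation_speeds(
    neighbours: list[NeighbourRecord],
    table: EventTable,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> tuple[list[float], float | None]:
    """Speeds (um/s) of all unordered neighbour pairs with |Δonset| >= 1, and their median.

    speed = (centre distance in px * pixel_size) / (|Δonset| * frame_interval).
    Simultaneous pairs (Δonset = 0) carry no propagation time and are skipped.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    seen: set[tuple[int, int]] = set()
    speeds: list[float] = []
    for n in neighbours:
        key = (min(n.event_id, n.neighbour_id), max(n.event_id, n.neighbour_id))
        if key in seen or n.delta_onset == 0:
            continue
        seen.add(key)
        speeds.append(
            (n.centre_distance_xy * pixel_size) / (abs(n.delta_onset) * frame_interval)
        )
    return speeds, (float(np.median(speeds)) if speeds else None)


def durations_and_distances(
    table: EventTable,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> pd.DataFrame:
    """Per-event duration (s) and distance travelled (um).

    Duration is the temporal extent times the frame interval; distance
    travelled is the xy bounding-box diagonal scaled to microns (a
    single-voxel event, extent 1 by 1, travels sqrt(2) * pixel_size).
    """
    rows = [
        {
            "event_id": r.id,
            "duration_s": r.extent_t * frame_interval,
            "distance_um": math.hypot(r.extent_x, r.extent_y) * pixel_size,
        }
        for r in table.records
    ]
    return pd.DataFrame(rows, columns=["event_id", "duration_s", "distance_um"])


def neighbour_counts(
    neighbours: list[NeighbourRecord], table: EventTable
) -> tuple[dict[int, int], float | None]:
    """Per event, the number of distinct consequent neighbours (Δonset > 0),
    and the mean over events. Simultaneous neighbours do not count."""
    counts = {r.id: 0 for r in table.records}
    seen: set[tuple[int, int]] = set()
    for n in neighbours:
        if n.delta_onset > 0 and (n.event_id, n.neighbour_id) not in seen:
            seen.add((n.event_id, n.neighbour_id))
            counts[n.event_id] += 1
    mean = float(np.mean(list(counts.values()))) if counts else None
    return counts, mean


def summarise(
    table: EventTable,
    neighbours: list[NeighbourRecord],
    *,
    n_cells: int | None = None,
    recording_minutes: float | None = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> SummaryStats:
    """Compute the full :class:`SummaryStats` row for one recording."""
    speeds, med_speed = propagation_speeds(neighbours, table, pixel_size, frame_interval)
    dd = durations_and_distances(table, pixel_size, frame_interval)
    _, mean_nc = neighbour_counts(neighbours, table)
    inc = (
        incidence(table, n_cells, recording_minutes)
        if (recording_minutes is not None and n_cells is not None)
        else None
    )
    pairs = {(min(n.event_id, n.neighbour_id), max(n.event_id, n.neighbour_id))
             for n in neighbours}
    return SummaryStats(
        n_events=len(table),
        n_neighbour_pairs=len(pairs),
        incidence=inc,
        median_propagation_speed=med_speed,
        median_duration=float(dd["duration_s"].median()) if len(dd) else None,
        median_distance=float(dd["distance_um"].median()) if len(dd) else None,
        mean_neighbour_count=mean_nc,
    )
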