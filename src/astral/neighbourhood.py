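"""Neighbour discovery, repeat classification and CSV export.

A tolerance-padded box is drawn around every event: centred at the event's
centre of mass, with half-width along each axis equal to the event's own
maximum centroid-to-extreme-voxel distance plus the tolerance
(``tolerance_xy`` in x and y, ``tolerance_t`` in t). Any other event with at
least one voxel inside the box (boundaries inclusive) is a neighbour — a
candidate for intercellular propagation.

Neighbours whose xy footprints overlap by more than
``intersection_threshold`` are the same site firing again rather than
propagation to a new site: those events are classified "repeat" and chained
by transitive closure; everything else is "single".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .event_catalog import EventRecord, EventTable

__all__ = [
    "NeighbourRecord",
    "RepeatClassification",
    "find_neighbours",
    "find_repeats",
    "projection_overlap",
    "generate_csv",
]


@dataclass(frozen=True)
class NeighbourRecord:
    """One ordered (event, neighbour) relation."""

    event_id: int
    neighbour_id: int
    centre_distance_xy: float  # pixels
    delta_onset: int  # frames, neighbour onset - event onset
    neighbour_extent_x: int
    neighbour_extent_y: int
    neighbour_extent_t: int


@dataclass(frozen=True)
class RepeatClassification:
    """Per-event single/repeat category and the repeat chains.

    ``category`` maps event id -> "single" | "repeat"; ``chains`` maps a
    chain id (the smallest member id) to the chain's member ids sorted by
    onset; ``inter_repeat_gaps`` holds the onset-frame gaps between
    consecutive chain members.
    """

    category: dict[int, str]
    chains: dict[int, tuple[int, ...]]
    inter_repeat_gaps: dict[int, tuple[int, ...]]

    @property
    def n_repeats(self) -> int:
        return sum(1 for c in self.category.values() if c == "repeat")


def _in_box(record: EventRecord, other: EventRecord, tol_xy: float, tol_t: float) -> bool:
    """Does any voxel of ``other`` fall inside ``record``'s padded box?"""
    ht, hy, hx = record.half_widths()
    ct, cy, cx = record.centroid
    v = other.voxels
    inside = (
        (np.abs(v[:, 0] - ct) <= ht + tol_t)
        & (np.abs(v[:, 1] - cy) <= hy + tol_xy)
        & (np.abs(v[:, 2] - cx) <= hx + tol_xy)
    )
    return bool(inside.any())


def find_neighbours(
    table: EventTable, tolerance_xy: float = 50, tolerance_t: float = 5
) -> list[NeighbourRecord]:
    """All ordered (event, neighbour) pairs under the padded-box rule.

    Box membership is evaluated independently for each order — for events of
    unequal extent E may see F without F seeing E — and one record is emitted
    per ordered pair that qualifies. Zero tolerances are legal (the box is
    then the event's own centred bounding extent).
    """
    records = table.records
    out: list[NeighbourRecord] = []
    for e in records:
        for f in records:
            if f.id == e.id:
                continue
            if _in_box(e, f, tolerance_xy, tolerance_t):
                out.append(
                    NeighbourRecord(
                        event_id=e.id,
                        neighbour_id=f.id,
                        centre_distance_xy=table.distance(e.id, f.id),
                        delta_onset=f.t_onset - e.t_onset,
                        neighbour_extent_x=f.extent_x,
                        neighbour_extent_y=f.extent_y,
                        neighbour_extent_t=f.extent_t,
                    )
                )
    return out


def projection_overlap(a: EventRecord, b: EventRecord) -> float:
    """Overlap fraction of two xy footprints: |A ∩ B| / min(|A|, |B|).

    The min denominator makes the fraction symmetric, so "is a repeat of" is
    well defined regardless of which event fired first.
    """
    pa, pb = a.xy_projection, b.xy_projection
    return len(pa & pb) / min(len(pa), len(pb))


def find_repeats(
    neighbours: list[NeighbourRecord],
    table: EventTable,
    intersection_threshold: float = 0.8,
) -> RepeatClassification:
    """Classify events as "single" or "repeat" by footprint overlap.

    A neighbour pair is linked iff its overlap fraction strictly exceeds
    ``intersection_threshold``; chains are the connected components of
    linked pairs, so three or more recurrences at one site form one chain.
    """
    ids = [r.id for r in table.records]
    parent = {i: i for i in ids}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = {(min(n.event_id, n.neighbour_id), max(n.event_id, n.neighbour_id))
             for n in neighbours}
    for a, b in sorted(pairs):
        if projection_overlap(table.by_id(a), table.by_id(b)) > intersection_threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[int, list[int]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)

    category = {i: "single" for i in ids}
    chains: dict[int, tuple[int, ...]] = {}
    gaps: dict[int, tuple[int, ...]] = {}
    for root, members in groups.items():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda i: (table.by_id(i).t_onset, i))
        chain_id = min(members)
        chains[chain_id] = tuple(members)
        onsets = [table.by_id(i).t_onset for i in members]
        gaps[chain_id] = tuple(np.diff(onsets).astype(int))
        for i in members:
            category[i] = "repeat"
    return RepeatClassification(category=category, chains=chains, inter_repeat_gaps=gaps)


NEIGHBOUR_COLUMNS = [
    "event_id",
    "neighbour_id",
    "centre_distance_xy_px",
    "delta_onset_frames",
    "neighbour_extent_x",
    "neighbour_extent_y",
    "neighbour_extent_t",
]


def neighbours_frame(neighbours: list[NeighbourRecord]) -> pd.DataFrame:
    rows = [
        (n.event_id, n.neighbour_id, n.centre_distance_xy, n.delta_onset,
         n.neighbour_extent_x, n.neighbour_extent_y, n.neighbour_extent_t)
        for n in neighbours
    ]
    return pd.DataFrame(rows, columns=NEIGHBOUR_COLUMNS)


def neighbour_statistics_frame(
    neighbours: list[NeighbourRecord], table: EventTable
) -> pd.DataFrame:
    """Per-event neighbour count, mean centre distance and mean |Δonset|,
    plus a final recording-level mean row (event_id "ALL")."""
    rows = []
    for rec in table.records:
        mine = [n for n in neighbours if n.event_id == rec.id]
        rows.append(
            {
                "event_id": rec.id,
                "n_neighbours": len(mine),
                "mean_centre_distance_xy_px": (
                    float(np.mean([n.centre_distance_xy for n in mine])) if mine else np.nan
                ),
                "mean_abs_delta_onset_frames": (
                    float(np.mean([abs(n.delta_onset) for n in mine])) if mine else np.nan
                ),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "n_neighbours",
            "mean_centre_distance_xy_px",
            "mean_abs_delta_onset_frames",
        ],
    )
    if len(frame):
        summary = {
            "event_id": "ALL",
            "n_neighbours": frame["n_neighbours"].mean(),
            "mean_centre_distance_xy_px": frame["mean_centre_distance_xy_px"].mean(),
            "mean_abs_delta_onset_frames": frame["mean_abs_delta_onset_frames"].mean(),
        }
        frame = pd.concat([frame, pd.DataFrame([summary])], ignore_index=True)
    return frame


def _dims(rec: EventRecord) -> dict:
    return {
        "volume_voxels": rec.volume,
        "t_onset": rec.t_onset,
        "t_end": rec.t_end,
        "extent_x": rec.extent_x,
        "extent_y": rec.extent_y,
        "extent_t": rec.extent_t,
    }


def repeats_frame(classification: RepeatClassification, table: EventTable) -> pd.DataFrame:
    rows = []
    for chain_id, members in sorted(classification.chains.items()):
        gaps = classification.inter_repeat_gaps[chain_id]
        for k, event_id in enumerate(members):
            rows.append(
                {
                    "chain_id": chain_id,
                    "event_id": event_id,
                    **_dims(table.by_id(event_id)),
                    # gap from the previous chain member; first member has none
                    "gap_to_previous_frames": gaps[k - 1] if k else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chain_id", "event_id", "volume_voxels", "t_onset", "t_end",
                 "extent_x", "extent_y", "extent_t", "gap_to_previous_frames"],
    )


def singles_frame(classification: RepeatClassification, table: EventTable) -> pd.DataFrame:
    rows = [
        {"event_id": rec.id, **_dims(rec)}
        for rec in table.records
        if classification.category[rec.id] == "single"
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "volume_voxels", "t_onset", "t_end",
                 "extent_x", "extent_y", "extent_t"],
    )


def generate_csv(
    neighbours: list[NeighbourRecord],
    classification: RepeatClassification,
    table: EventTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write neighbours.csv, neighbour_statistics.csv, repeats.csv, singles.csv.

    Empty inputs produce header-only files. Returns name -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "neighbours": neighbours_frame(neighbours),
        "neighbour_statistics": neighbour_statistics_frame(neighbours, table),
        "repeats": repeats_frame(classification, table),
        "singles": singles_frame(classification, table),
    }
    written = {}
    for name, frame in frames.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written
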