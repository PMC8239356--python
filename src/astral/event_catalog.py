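"""Per-event geometry: voxels, extents, centres of mass, pairwise distances.

Each labelled event is reduced to an :class:`EventRecord` — its voxel list
with intensities, bounding-box extents in x, y (pixels) and t (frames), the
intensity-weighted centre of mass, onset/end frames and the xy footprint —
and an :class:`EventTable` additionally holds the full matrix of pairwise
xy centroid distances feeding the neighbour analysis.

All geometry is in pixels and frames; physical units are applied only in the
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .stack_io import ImageStack

__all__ = ["EventRecord", "EventTable", "label_events", "generate_metadata"]


@dataclass(frozen=True)
class EventRecord:
    """Geometry and intensity of one calcium event.

    ``voxels`` is an (n, 3) integer array of (t, y, x), lexicographically
    sorted; ``intensities`` the matching voxel intensities. Extents are
    bounding-box side lengths in voxel counts (a single-voxel event has
    extent 1 along every axis). ``centroid`` is the intensity-weighted
    (t, y, x) centre of mass; for a degenerate all-zero-intensity event the
    unweighted voxel mean is used and ``zero_intensity`` flags it.
    """

    id: int
    voxels: np.ndarray
    intensities: np.ndarray
    centroid: tuple[float, float, float]
    zero_intensity: bool = False

    @property
    def volume(self) -> int:
        return len(self.voxels)

    @property
    def t_onset(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def t_end(self) -> int:
        return int(self.voxels[:, 0].max())

    @property
    def extent_t(self) -> int:
        return self.t_end - self.t_onset + 1

    @property
    def extent_y(self) -> int:
        return int(self.voxels[:, 1].max() - self.voxels[:, 1].min()) + 1

    @property
    def extent_x(self) -> int:
        return int(self.voxels[:, 2].max() - self.voxels[:, 2].min()) + 1

    @property
    def xy_projection(self) -> frozenset[tuple[int, int]]:
        """Unique (y, x) pixels covered by the event, any frame."""
        return frozenset(map(tuple, self.voxels[:, 1:]))

    def half_widths(self) -> tuple[float, float, float]:
        """Max distance from the centroid to an extreme voxel, per (t, y, x) axis."""
        d = np.abs(self.voxels - np.asarray(self.centroid))
        return tuple(d.max(axis=0))


@dataclass(frozen=True)
class EventTable:
    """All events of one recording plus pairwise xy centroid distances."""

    records: tuple[EventRecord, ...]
    centre_distances: np.ndarray  # (K, K), pixels, symmetric, zero diagonal

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> EventRecord:
        return self.records[i]

    def index_of(self, event_id: int) -> int:
        for i, r in enumerate(self.records):
            if r.id == event_id:
                return i
        raise KeyError(event_id)

    def by_id(self, event_id: int) -> EventRecord:
        return self.records[self.index_of(event_id)]

    def distance(self, id_a: int, id_b: int) -> float:
        """Pairwise xy centroid distance between two events, in pixels."""
        return float(self.centre_distances[self.index_of(id_a), self.index_of(id_b)])


def label_events(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Collect each event's voxel coordinates.

    Returns ``{label: (n, 3) array of (t, y, x)}`` with rows in
    lexicographic (scan) order; every foreground voxel appears in exactly
    one list.
    """
    labels = np.asarray(labels)
    coords = np.argwhere(labels > 0)  # already lexicographic in (t, y, x)
    if coords.size == 0:
        return {}
    values = labels[tuple(coords.T)]
    order = np.argsort(values, kind="stable")
    coords = coords[order]
    values = values[order]
    splits = np.flatnonzero(np.diff(values)) + 1
    return dict(zip(values[np.r_[0, splits]].tolist(), np.split(coords, splits)))


def generate_metadata(
    voxel_lists: dict[int, np.ndarray], intensities: ImageStack | np.ndarray
) -> EventTable:
    """Build the :class:`EventTable` from voxel lists and the intensity stack.

    The intensity stack must be the same one detection ran on (pre-processed
    if pre-processing was applied), so centre-of-mass weights match what was
    thresholded.
    """
    data = intensities.data if isinstance(intensities, ImageStack) else np.asarray(intensities)
    records: list[EventRecord] = []
    for event_id in sorted(voxel_lists):
        vox = np.asarray(voxel_lists[event_id])
        if vox.ndim != 2 or vox.shape[1] != 3 or len(vox) == 0:
            raise ValueError(f"event {event_id}: voxel list must be (n, 3), n >= 1")
        inten = data[tuple(vox.T)].astype(np.float64)
        total = inten.sum()
        if total > 0:
            centroid = tuple((vox * inten[:, None]).sum(axis=0) / total)
            zero = False
        else:
            centroid = tuple(vox.mean(axis=0))
            zero = True
        records.append(
            EventRecord(
                id=int(event_id),
                voxels=vox,
                intensities=inten,
                centroid=centroid,
                zero_intensity=zero,
            )
        )
    k = len(records)
    if k == 0:
        dist = np.zeros((0, 0))
    elif k == 1:
        dist = np.zeros((1, 1))
    else:
        xy = np.array([(r.centroid[1], r.centroid[2]) for r in records])
        dist = squareform(pdist(xy))
    return EventTable(records=tuple(records), centre_distances=dist)
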