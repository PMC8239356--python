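"""ROI-free event detection and 3-D labelling.

Detection works without per-cell regions of interest. The field of view is
tiled into square "grains" of ``grain_size`` pixels; for every grain the
temporal trace of the block-mean intensity is reduced to its mean ``mu`` and
standard deviation ``sigma`` over the whole recording, and a grain is
foreground at frame ``t`` exactly when its block mean at ``t`` reaches
``mu + sd_threshold * sigma``. Adjacent foreground voxels (26-neighbourhood
in x, y, t) are then grouped into single calcium events and given unique
integer IDs; touching events can optionally be split by a 3-D watershed
seeded at local intensity maxima. Finally, events smaller than
``volume_threshold`` voxels are discarded as noise.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .stack_io import ImageStack

__all__ = ["extract_events", "create_masks", "cleanup", "relabel_by_first_voxel"]

# 26-neighbourhood in (t, y, x): waves move diagonally in space-time.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def _block_reduce_mean(frames: np.ndarray, grain: int) -> np.ndarray:
    """Mean over non-overlapping grain x grain blocks, per frame.

    Trailing partial blocks (frame size not divisible by ``grain``) are
    averaged over their actual pixel count.
    """
    n_t, h, w = frames.shape
    ey = np.arange(0, h, grain)
    ex = np.arange(0, w, grain)
    sums = np.add.reduceat(np.add.reduceat(frames, ey, axis=1), ex, axis=2)
    ny = np.minimum(ey + grain, h) - ey
    nx = np.minimum(ex + grain, w) - ex
    counts = np.multiply.outer(ny, nx).astype(float)
    return sums / counts


def extract_events(
    stack: ImageStack, grain_size: int = 1, sd_threshold: float = 5.0
) -> np.ndarray:
    """Threshold grain traces into a boolean event mask.

    Returns a boolean array of the stack's shape. All pixels of one grain
    block switch together (the decision is taken at block level); blocks with
    a perfectly constant trace (sigma = 0) are always background.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    data = np.asarray(stack.data, dtype=np.float64)
    n_t, h, w = data.shape
    if grain_size < 1 or grain_size > max(h, w):
        raise ValueError(f"grain_size {grain_size} does not fit a {h}x{w} frame")

    trace = _block_reduce_mean(data, grain_size)  # (t, nby, nbx)
    mu = trace.mean(axis=0)
    sigma = trace.std(axis=0)
    block_fg = (trace >= mu + sd_threshold * sigma) & (sigma > 0)

    # Expand block decisions back to pixel resolution.
    mask = np.repeat(np.repeat(block_fg, grain_size, axis=1), grain_size, axis=2)
    return np.ascontiguousarray(mask[:, :h, :w])


def relabel_by_first_voxel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by each event's first (t, y, x) scan-order voxel.

    Gives deterministic IDs independent of how the labels were produced.
    """
    labels = np.asarray(labels)
    flat = labels.ravel()
    fg = np.flatnonzero(flat)
    if fg.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    old = flat[fg]
    # first occurrence index of each label in scan order
    order = np.unique(old)
    first = np.full(order.max() + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, old, fg)
    ranks = np.argsort(first[order], kind="stable")
    mapping = np.zeros(order.max() + 1, dtype=np.int32)
    mapping[order[ranks]] = np.arange(1, order.size + 1, dtype=np.int32)
    return mapping[labels]


def _watershed_split(labels: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    """Partition each connected component by a seeded 3-D watershed.

    Seeds are the local maxima (3x3x3 neighbourhood) of the Gaussian-smoothed
    intensity (sigma = 1 px and 1 frame) inside each component; plateaus of
    maxima contribute one seed each, at their lowest linear voxel index. The
    inverted smoothed intensity is flooded within the component mask.
    Foreground voxels are neither created nor deleted.
    """
    from skimage.segmentation import watershed

    smoothed = ndimage.gaussian_filter(np.asarray(intensities, dtype=np.float64), sigma=1.0)
    mask = labels > 0
    is_max = (smoothed == ndimage.maximum_filter(smoothed, size=3)) & mask

    # One marker per plateau of local maxima; plateaus split by component.
    peak_labels, _ = ndimage.label(is_max, structure=STRUCTURE_26)
    # Restrict plateaus to a single source component (a plateau cannot span
    # two components since components are separated by background).
    markers = np.zeros_like(labels, dtype=np.int32)
    n_peaks = peak_labels.max()
    if n_peaks == 0:
        return labels.copy()
    # lowest linear index of each plateau = deterministic seed voxel
    flat_peaks = peak_labels.ravel()
    fg = np.flatnonzero(flat_peaks)
    first = np.full(n_peaks + 1, flat_peaks.size, dtype=np.int64)
    np.minimum.at(first, flat_peaks[fg], fg)
    seed_idx = first[1:]
    markers.ravel()[seed_idx] = np.arange(1, n_peaks + 1, dtype=np.int32)

    out = watershed(-smoothed, markers=markers, mask=mask, connectivity=STRUCTURE_26)
    # Watershed regions never cross component boundaries (mask-restricted),
    # but a component without any seed would be dropped; keep it intact.
    missing = mask & (out == 0)
    if missing.any():
        out = out.astype(np.int64)
        out[missing] = labels[missing] + n_peaks
    return out


def create_masks(
    mask: np.ndarray,
    use_watershed: bool = False,
    intensities: ImageStack | np.ndarray | None = None,
) -> np.ndarray:
    """Group adjacent foreground voxels into labelled 3-D events.

    Connectivity is the full 26-neighbourhood in (x, y, t). With
    ``use_watershed`` each component is further partitioned by a watershed
    seeded at local maxima of the smoothed intensity (``intensities`` is then
    required and must be the stack detection ran on). Labels are contiguous
    1..K, numbered by each event's first scan-order voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D (t, y, x)")
    labels, _ = ndimage.label(mask, structure=STRUCTURE_26)
    if use_watershed:
        if intensities is None:
            raise ValueError("watershed splitting requires the intensity stack")
        data = intensities.data if isinstance(intensities, ImageStack) else intensities
        if data.shape != mask.shape:
            raise ValueError("intensity stack shape must match the mask")
        labels = _watershed_split(labels, data)
    return relabel_by_first_voxel(labels)


def cleanup(labels: np.ndarray, volume_threshold: int = 40) -> np.ndarray:
    """Drop events strictly smaller than ``volume_threshold`` voxels.

    An event of exactly ``volume_threshold`` voxels is retained. Survivors
    are relabelled contiguously, preserving their original ordering.
    """
    labels = np.asarray(labels)
    if labels.max() == 0 or volume_threshold <= 1:
        return relabel_by_first_voxel(labels)
    counts = np.bincount(labels.ravel())
    keep = counts >= volume_threshold
    keep[0] = False
    mapping = np.zeros(counts.size, dtype=labels.dtype)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]
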