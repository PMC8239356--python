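"""Optional pre-processing: bleach/intensity matching and rigid motion correction.

Photobleaching and focus drift make the whole-frame mean wander over a
recording; ``correct_intensity`` rescales every frame so its mean matches
the mean of the preceding frame — which, cascaded, pins all frame means to
the frame-0 mean.

In-vivo or long in-vitro recordings also drift in XY. ``correct_motion``
estimates one integer (dy, dx) shift per frame from a *reference region*: a
cluster of subregions of the field of view that are bright but temporally
quiet (high mean, low SD — i.e. showing no calcium oscillations), selected
by ``select_reference``. Each frame's reference crop is registered against
frame 0 by cross-correlation and the whole field of view is translated by
the negative shift, vacated margins zero-filled.

When both corrections run, motion goes first: zero-filled borders would
otherwise bias the frame means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .stack_io import DegenerateInputError, ImageStack

__all__ = ["MotionTrace", "correct_intensity", "select_reference", "correct_motion"]


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame estimated rigid shift, frame 0 fixed at (0, 0).

    ``shifts[t]`` = (dy, dx) of frame t relative to frame 0, in pixels;
    ``failed[t]`` marks frames whose estimate exceeded half the frame size
    and was replaced by the previous frame's shift.
    """

    shifts: np.ndarray  # (T, 2) int
    reference_region: tuple[int, ...]  # flat indices of selected subregions
    grid: tuple[int, int]
    failed: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        if tuple(self.shifts[0]) != (0, 0):
            raise ValueError("frame 0 must have zero shift")


def correct_intensity(stack: ImageStack) -> ImageStack:
    """Match every frame's mean to the preceding frame's (hence frame 0's) mean.

    Each frame is rescaled multiplicatively, so its spatial pattern (frame
    divided by its own mean) is untouched; only the overall brightness drift
    — e.g. exponential photobleaching — is removed.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    means = data.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise DegenerateInputError("a frame has non-positive mean intensity")
    corrected = data * (means[0] / means)[:, None, None]
    return stack.with_data(corrected)


def _subregion_slices(height: int, width: int, grid: tuple[int, int]):
    gy, gx = grid
    ys = np.linspace(0, height, gy + 1).astype(int)
    xs = np.linspace(0, width, gx + 1).astype(int)
    for i in range(gy):
        for j in range(gx):
            yield i * gx + j, (slice(ys[i], ys[i + 1]), slice(xs[j], xs[j + 1]))


def select_reference(
    stack: ImageStack, grid: int | tuple[int, int] = 8
) -> tuple[int, ...]:
    """Pick the quiet-and-bright subregion cluster to register against.

    The frame is divided into a ``grid`` of subregions; for each, the
    temporal trace of the subregion mean is reduced to its mean and SD. The
    reference is the set of subregions with below-median SD *and*
    above-median mean. If that intersection is empty (e.g. a perfectly
    uniform stack where every subregion ties), the single subregion with the
    highest mean/(SD + eps) ratio — lowest flat index on ties — is returned.

    Returns flat subregion indices (row-major over the grid).
    """
    if isinstance(grid, int):
        grid = (grid, grid)
    gy, gx = grid
    if gy * gx < 4:
        raise ValueError("grid must divide the frame into at least 4 subregions")
    if gy > stack.height or gx > stack.width:
        raise ValueError(f"frame {stack.height}x{stack.width} too small for {gy}x{gx} grid")
    data = np.asarray(stack.data, dtype=np.float64)
    n = gy * gx
    means = np.empty(n)
    sds = np.empty(n)
    for idx, sl in _subregion_slices(stack.height, stack.width, grid):
        trace = data[:, sl[0], sl[1]].mean(axis=(1, 2))
        means[idx] = trace.mean()
        sds[idx] = trace.std()
    chosen = np.flatnonzero((sds < np.median(sds)) & (means > np.median(means)))
    if chosen.size == 0:
        score = means / (sds + 1e-12)
        chosen = np.array([int(np.argmax(score))])  # argmax: lowest index on ties
    return tuple(int(i) for i in chosen)


def _reference_bbox(height, width, grid, reference_region):
    """Bounding box (in pixels) of the union of selected subregions."""
    slices = dict(_subregion_slices(height, width, grid))
    y0 = min(slices[i][0].start for i in reference_region)
    y1 = max(slices[i][0].stop for i in reference_region)
    x0 = min(slices[i][1].start for i in reference_region)
    x1 = max(slices[i][1].stop for i in reference_region)
    return slice(y0, y1), slice(x0, x1)


def _translate(frame: np.ndarray, ty: int, tx: int) -> np.ndarray:
    """Translate content by (+ty, +tx) with zero fill of vacated margins."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    if abs(ty) >= h or abs(tx) >= w:
        return out
    yd = slice(max(ty, 0), min(h, h + ty))
    ys = slice(max(-ty, 0), min(h, h - ty))
    xd = slice(max(tx, 0), min(w, w + tx))
    xs = slice(max(-tx, 0), min(w, w - tx))
    out[yd, xd] = frame[ys, xs]
    return out


def correct_motion(
    stack: ImageStack,
    reference_region: tuple[int, ...] | None = None,
    grid: int | tuple[int, int] = 8,
) -> tuple[ImageStack, MotionTrace]:
    """Estimate and undo per-frame rigid XY motion.

    Each frame's reference-region crop is registered to frame 0's crop; the
    estimated shift is the integer arg-max of their cross-correlation (exact
    for noise-free integer translations). The frame is then translated by
    the negative shift, zero-filling vacated margins. Estimates larger than
    half the frame size are treated as failures: the frame is flagged and
    inherits the previous frame's shift.
    """
    if isinstance(grid, int):
        grid = (grid, grid)
    if reference_region is None:
        reference_region = select_reference(stack, grid)
    data = np.asarray(stack.data, dtype=np.float64)
    bbox = _reference_bbox(stack.height, stack.width, grid, reference_region)
    ref0 = data[0][bbox]
    # Mean subtraction removes the dominant DC term; the Hann window kills
    # the circular-wraparound artifacts of FFT correlation on non-periodic
    # content, which otherwise bias the peak on smooth textures.
    window = np.outer(np.hanning(ref0.shape[0]), np.hanning(ref0.shape[1]))
    ref0_w = (ref0 - ref0.mean()) * window
    n = stack.n_frames
    shifts = np.zeros((n, 2), dtype=int)
    failed = np.zeros(n, dtype=bool)
    half = (stack.height // 2, stack.width // 2)
    for t in range(1, n):
        crop = data[t][bbox]
        if np.allclose(crop, ref0):
            est = (0, 0)
        else:
            raw, _, _ = phase_cross_correlation(
                ref0_w, (crop - crop.mean()) * window,
                upsample_factor=1, normalization=None,
            )
            est = (int(round(-raw[0])), int(round(-raw[1])))  # crop's shift vs frame 0
        if abs(est[0]) > half[0] or abs(est[1]) > half[1]:
            failed[t] = True
            shifts[t] = shifts[t - 1]
        else:
            shifts[t] = est
    corrected = np.empty_like(data)
    corrected[0] = data[0]
    for t in range(1, n):
        corrected[t] = _translate(data[t], -int(shifts[t, 0]), -int(shifts[t, 1]))
    return stack.with_data(corrected), MotionTrace(
        shifts=shifts,
        reference_region=tuple(reference_region),
        grid=grid,
        failed=failed,
    )
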