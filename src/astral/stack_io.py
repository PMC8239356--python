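"""Reading time-lapse stacks and persisting pipeline artifacts.

A recording is a multi-page grayscale TIFF, one image per frame. Internally
every stage works on an :class:`ImageStack`: a ``(frame, row, column)`` array
plus the acquisition calibration (seconds per frame, microns per pixel).
Intensities are passed through bit-exactly — no rescaling on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "persist_artifacts",
    "DegenerateInputError",
    "UnsupportedFormatError",
]

#: Acquisition defaults: 5 frames/s and 0.586 um/px, the calibration of the
#: recordings the default parameters were tuned on.
DEFAULT_FRAME_INTERVAL = 0.2
DEFAULT_PIXEL_SIZE = 0.586


class DegenerateInputError(ValueError):
    """Input stack is too small or otherwise unusable (e.g. < 2 frames)."""


class UnsupportedFormatError(ValueError):
    """Input file is not a grayscale multi-page TIFF."""


@dataclass(frozen=True)
class ImageStack:
    """A grayscale time-lapse volume with acquisition metadata.

    Parameters
    ----------
    data:
        3-D non-negative intensity array indexed ``(frame, row, column)``.
    frame_interval:
        Seconds per frame (default 0.2, i.e. 5 frames/s).
    pixel_size:
        Microns per pixel (default 0.586).
    """

    data: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise UnsupportedFormatError(
                f"stack must have 3 axes (frame, row, column), got {data.ndim}"
            )
        if data.shape[0] < 2:
            raise DegenerateInputError(
                f"stack must have at least 2 frames, got {data.shape[0]}"
            )
        if not np.issubdtype(data.dtype, np.number):
            raise UnsupportedFormatError(f"non-numeric dtype {data.dtype}")
        if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
            raise ValueError("stack contains non-finite intensities")
        if data.min() < 0:
            raise ValueError("stack contains negative intensities")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Return a copy holding ``data`` but the same calibration."""
        return replace(self, data=data)


def read_stack(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Frames are kept in file order and intensities are preserved bit-exactly
    (8/16-bit integer or float pages alike). Multi-channel (RGB) input is
    rejected: event detection is defined on a single fluorescence channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        raise DegenerateInputError(
            f"{path.name}: single-frame TIFF; a time-lapse needs >= 2 frames"
        )
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"{path.name}: expected one grayscale image per page, got shape {data.shape}"
        )
    # A trailing small axis is a colour axis, not an image width.
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise UnsupportedFormatError(f"{path.name}: multi-channel TIFF not supported")
    return ImageStack(data, frame_interval=frame_interval, pixel_size=pixel_size)


def write_stack(stack: ImageStack | np.ndarray, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF, one page per frame."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    path = Path(path)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def persist_artifacts(
    out_dir: str | Path,
    *,
    mask: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    tables: dict[str, "object"] | None = None,
) -> dict[str, str]:
    """Write stage outputs under their conventional filenames.

    ``mask`` goes to ``waves.npy`` (boolean event mask), ``labels`` to
    ``labelled_waves.npy`` plus a 1-bit-style rendering ``black_and_white.tiff``
    of the mask, and every entry of ``tables`` (name -> pandas DataFrame) to
    ``<name>.csv``. Returns a manifest mapping each written filename to its
    SHA-256 content checksum; the manifest itself is saved as
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise IOError(f"not a directory: {out_dir}")

    written: list[Path] = []
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        p = out_dir / "waves.npy"
        np.save(p, mask)
        written.append(p)
        p = out_dir / "black_and_white.tiff"
        tifffile.imwrite(p, (mask.astype(np.uint8) * 255), photometric="minisblack")
        written.append(p)
    if labels is not None:
        p = out_dir / "labelled_waves.npy"
        np.save(p, np.asarray(labels))
        written.append(p)
    for name, frame in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    manifest = {p.name: _sha256(p) for p in written}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
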