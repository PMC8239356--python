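"""Pipeline configuration.

All tunable parameters of the pipeline live in one :class:`Config`. The
on-disk representation is a small JSON document (conventionally
``variables.json``) whose keys are the historical variable names
(``SD_threshold``, ``Grain_size``, ...); unknown keys are rejected and
missing keys take the defaults below, which were tuned for 5 frames/s
GCaMP6f recordings of cultured astrocytic monolayers at 0.586 um/px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .stack_io import DEFAULT_FRAME_INTERVAL, DEFAULT_PIXEL_SIZE

__all__ = ["Config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or out-of-range configuration."""


# JSON key -> Config attribute. Keys are the historical variable names.
_JSON_KEYS = {
    "Filename": "filename",
    "Intersection_threshold": "intersection_threshold",
    "Grain_size": "grain_size",
    "SD_threshold": "sd_threshold",
    "Tolerance_t": "tolerance_t",
    "Tolerance_xy": "tolerance_xy",
    "Use_watershed": "use_watershed",
    "Volume_threshold": "volume_threshold",
}


@dataclass(frozen=True)
class Config:
    """All pipeline parameters, in pixels and frames.

    Attributes
    ----------
    filename:
        Which file(s) of an input directory to process; ``"All"`` means the
        whole batch, in lexicographic name order.
    intersection_threshold:
        Minimum xy-projection overlap fraction (exclusive) for a neighbour to
        count as a repeat of an event, in ``(0, 1]``.
    grain_size:
        Side, in pixels, of the square pixel block pooled for the temporal
        statistics during detection; must be a power of two.
    sd_threshold:
        Detection threshold in multiples of the block-trace SD above its mean.
    tolerance_t:
        Padding, in frames, of the neighbour search box along time.
    tolerance_xy:
        Padding, in pixels, of the neighbour search box in x and y.
    use_watershed:
        Split touching events with a 3-D watershed after labelling.
    volume_threshold:
        Events smaller than this many voxels are discarded as noise.
    n_cells:
        Cell count of the field of view (user-supplied; needed only for the
        incidence summary).
    frame_interval, pixel_size:
        Physical calibration, used only when converting summaries to
        microns and seconds.
    """

    filename: str = "All"
    intersection_threshold: float = 0.8
    grain_size: int = 1
    sd_threshold: float = 5.0
    tolerance_t: int = 5
    tolerance_xy: int = 50
    use_watershed: bool = False
    volume_threshold: int = 40
    n_cells: int | None = None
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        if not (0 < self.intersection_threshold <= 1):
            raise ConfigError("Intersection_threshold must be in (0, 1]")
        g = self.grain_size
        if not (isinstance(g, int) and g >= 1 and (g & (g - 1)) == 0):
            raise ConfigError(f"Grain_size must be a power of two, got {g!r}")
        if not self.sd_threshold > 0:
            raise ConfigError("SD_threshold must be positive")
        if self.tolerance_t < 0 or self.tolerance_xy < 0:
            raise ConfigError("tolerances must be >= 0")
        if self.volume_threshold < 0:
            raise ConfigError("Volume_threshold must be >= 0")
        if self.n_cells is not None and self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1 when given")
        if not (self.frame_interval > 0 and self.pixel_size > 0):
            raise ConfigError("frame_interval and pixel_size must be > 0")

    def replace(self, **changes) -> "Config":
        return replace(self, **changes)

    def to_json_dict(self) -> dict:
        """Serialise the historical-variable subset to its JSON key names."""
        return {
            key: getattr(self, attr) if key != "Use_watershed" else int(self.use_watershed)
            for key, attr in _JSON_KEYS.items()
        }


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a :class:`Config` from a ``variables.json``-style document.

    ``path=None`` returns the defaults. Keys absent from the document keep
    their defaults; keys outside the known variable names raise
    :class:`ConfigError`, as do out-of-range values. Keyword ``overrides``
    (attribute names, e.g. ``n_cells=12``) are applied on top.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a JSON object")
        unknown = set(raw) - set(_JSON_KEYS)
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        for key, value in raw.items():
            attr = _JSON_KEYS[key]
            if attr == "use_watershed":
                if value not in (0, 1, True, False):
                    raise ConfigError("Use_watershed must be 0 or 1")
                value = bool(value)
            if attr in ("grain_size", "tolerance_t", "tolerance_xy", "volume_threshold"):
                if isinstance(value, bool) or not isinstance(value, int):
                    raise ConfigError(f"{key} must be an integer, got {value!r}")
            values[attr] = value
    values.update(overrides)
    try:
        return Config(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
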