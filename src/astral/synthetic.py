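"""Synthetic time-lapse generator with known ground truth.

Emulates the phenomenology of fluorescence recordings of astrocytic
monolayers: a noisy baseline, localized transients with a fast rise and
exponential decay, multi-cell propagating waves, repeated firing at one
site, exponential photobleaching and rigid XY drift. Every feature is
planted from an explicit :class:`SceneSpec`, so the true centres, onsets,
volumes and chain memberships are available for verification.

Scales are shrunk relative to a real recording (a 3-min, 5 frames/s,
960 x 608 px field) by roughly an order of magnitude so test suites run in
seconds; amplitudes are expressed in multiples of the baseline noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import _translate
from .stack_io import DEFAULT_FRAME_INTERVAL, DEFAULT_PIXEL_SIZE, ImageStack

__all__ = [
    "PlantedEvent",
    "SceneSpec",
    "generate_stack",
    "make_boundary_fixtures",
    "recovery_scene",
    "render_binary_events",
]


@dataclass(frozen=True)
class PlantedEvent:
    """One transient: a spatial Gaussian with exponential rise and decay.

    ``amplitude`` is the peak contribution in multiples of the scene's
    baseline noise SD; ``radius`` the spatial Gaussian sigma in pixels;
    ``rise`` and ``decay`` time constants in frames. A ``velocity``
    (vy, vx, px/frame) makes the transient travel — a propagating
    intercellular wave front; ``repeat_onsets`` fire the same site again
    (the repeats share the event's chain)."""

    centre: tuple[float, float]  # (y, x)
    onset: int
    amplitude: float = 20.0
    radius: float = 4.0
    rise: float = 0.5
    decay: float = 3.0
    velocity: tuple[float, float] | None = None
    repeat_onsets: tuple[int, ...] = ()
    chain: int | None = None  # shared id for members of one planted wave/repeat chain

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1 px")


@dataclass(frozen=True)
class SceneSpec:
    """Fully deterministic description of a synthetic recording."""

    shape: tuple[int, int, int]  # (frames, height, width)
    baseline: float = 100.0
    noise_sd: float = 2.0
    texture_sd: float = 0.0  # static spatial heterogeneity (cell bodies etc.)
    bleach_rate: float = 0.0  # fractional mean loss per frame
    drift: dict[int, tuple[int, int]] = field(default_factory=dict)  # frame -> (dy, dx)
    events: tuple[PlantedEvent, ...] = ()
    seed: int = 0
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE


def _time_profile(t: np.ndarray, onset: int, rise: float, decay: float) -> np.ndarray:
    """0 before onset; saturating rise times exponential decay from onset."""
    dt = t - onset
    p = (1.0 - np.exp(-(dt + 1.0) / max(rise, 1e-9))) * np.exp(-dt / max(decay, 1e-9))
    return np.where(dt >= 0, p, 0.0)


def _render_event(
    shape: tuple[int, int, int], ev: PlantedEvent, onset: int, noise_sd: float
) -> np.ndarray:
    """Noise-free contribution of one firing, in intensity units."""
    n_t, h, w = shape
    t = np.arange(n_t, dtype=float)
    prof = _time_profile(t, onset, ev.rise, ev.decay)
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros(shape)
    active = np.flatnonzero(prof > 1e-4)
    for ti in active:
        cy, cx = ev.centre
        if ev.velocity is not None:
            cy += ev.velocity[0] * (ti - onset)
            cx += ev.velocity[1] * (ti - onset)
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * ev.radius**2))
        out[ti] = prof[ti] * ev.amplitude * noise_sd * g
    return out


def generate_stack(spec: SceneSpec) -> tuple[ImageStack, pd.DataFrame]:
    """Render the scene and its ground-truth table.

    The stack is ``baseline * bleach(t) + sum(events) + N(0, noise_sd)``,
    then each frame is translated per the drift schedule (zero-filled
    margins, as a real stage jump would leave dark edges after correction).
    Intensities are clipped at zero.

    The ground truth lists, per firing: the true centre and onset, the
    voxel count of the rendered transient above half its maximum (a
    detector-independent notion of event volume), and the chain id shared
    by wave members and repeats (NaN for isolated events).
    """
    n_t, h, w = spec.shape
    for ev in spec.events:
        if not (0 <= ev.centre[0] < h and 0 <= ev.centre[1] < w):
            raise ValueError(f"event centre {ev.centre} outside the {h}x{w} field")
        for onset in (ev.onset, *ev.repeat_onsets):
            if not (0 <= onset < n_t):
                raise ValueError(f"onset {onset} outside the recording")

    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_t, dtype=float)
    bleach = (1.0 - spec.bleach_rate) ** t
    base = np.full((h, w), spec.baseline)
    if spec.texture_sd > 0:
        # static smoothed spatial pattern: cell bodies and processes that
        # bleach with the baseline and give motion correction its landmarks
        from scipy.ndimage import gaussian_filter

        texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=3.0)
        texture /= max(texture.std(), 1e-12)
        base = base + spec.texture_sd * texture
    signal = bleach[:, None, None] * base[None, :, :]

    truth_rows = []
    next_chain = max((ev.chain for ev in spec.events if ev.chain is not None), default=0)
    for i, ev in enumerate(spec.events):
        onsets = (ev.onset, *ev.repeat_onsets)
        chain = ev.chain
        if chain is None and len(onsets) > 1:
            next_chain += 1
            chain = next_chain
        for onset in onsets:
            contrib = _render_event(spec.shape, ev, onset, spec.noise_sd)
            signal += contrib
            peak = contrib.max()
            truth_rows.append(
                {
                    "event": i,
                    "onset": onset,
                    "centre_y": ev.centre[0],
                    "centre_x": ev.centre[1],
                    "amplitude_sd": ev.amplitude,
                    "volume_half_max": int((contrib >= peak / 2).sum()),
                    "chain": chain if chain is not None else np.nan,
                    "vy": ev.velocity[0] if ev.velocity else 0.0,
                    "vx": ev.velocity[1] if ev.velocity else 0.0,
                }
            )

    data = signal + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(data, 0.0, None, out=data)
    if spec.drift:
        for ti, (dy, dx) in spec.drift.items():
            data[ti] = _translate(data[ti], dy, dx)

    truth = pd.DataFrame(
        truth_rows,
        columns=["event", "onset", "centre_y", "centre_x", "amplitude_sd",
                 "volume_half_max", "chain", "vy", "vx"],
    )
    stack = ImageStack(data, frame_interval=spec.frame_interval, pixel_size=spec.pixel_size)
    return stack, truth


# ---------------------------------------------------------------------------
# Noise-free boundary fixtures
# ---------------------------------------------------------------------------

_BASELINE = 10.0
_SPIKE = 1000.0


def render_binary_events(
    shape: tuple[int, int, int], voxel_sets: list[np.ndarray]
) -> ImageStack:
    """Noise-free stack whose default-parameter detection mask is exactly
    the union of ``voxel_sets``.

    Listed voxels carry a large spike over a constant baseline. As long as
    no pixel is active on more than 1/26 of the frames, the grain-1
    mean + 5 SD rule recovers the planted voxels exactly: background pixels
    have zero temporal variance, and for a spiking pixel the spike frames
    (and only those) clear the full-trace threshold.
    """
    data = np.full(shape, _BASELINE)
    n_t = shape[0]
    for vox in voxel_sets:
        vox = np.asarray(vox)
        on_per_pixel = pd.DataFrame(vox, columns=["t", "y", "x"]).groupby(["y", "x"]).size()
        if (on_per_pixel / n_t).max() > 1 / 26:
            raise ValueError("a pixel is active too often for exact recovery")
        data[tuple(vox.T)] = _SPIKE
    return ImageStack(data)


def _blob(t: int, y0: int, x0: int, volume: int, width: int = 7) -> np.ndarray:
    """A connected single-frame blob of exactly ``volume`` pixels: full rows
    of ``width`` plus a partial last row."""
    rows = [(t, y0 + k // width, x0 + k % width) for k in range(volume)]
    return np.array(rows)


def make_boundary_fixtures() -> dict:
    """Deterministic noise-free stacks probing every default boundary.

    Returns a dict of fixture families:

    - ``volumes``: one stack; eleven events of exact volumes 35..45 voxels
      (probes the volume_threshold=40 cutoff).
    - ``xy_separation``: {s: stack} for s in 40..60 px; two simultaneous
      single-voxel events s apart in x (probes tolerance_xy=50).
    - ``t_gap``: {g: stack} for g in 1..10 frames; two single-voxel events
      3 px apart in x, g frames apart (probes tolerance_t=5; the small
      spatial offset keeps the pair from fusing into one 3-D component at
      gap 1).
    - ``overlap``: {f: stack} for f in 0.70..0.90 step 0.05; two 1x20-px
      strip events, 3 frames apart, horizontally offset so their footprints
      overlap by exactly the fraction f (probes intersection_threshold=0.8).
    - ``sd_sweep``: {k: (stack, trace)} for k in 3.0..7.0 step 0.5; a 1x1
      field whose deterministic baseline alternates +-1 around 10 (trace SD
      exactly 1) with a single deflection of k baseline-SD at mid-recording
      (probes the mean + SD_threshold * sigma rule on the full trace).
    """
    fixtures: dict = {}

    # (a) volumes 35..45, one blob per frame band, spaced out on an 80x80 field
    sets = []
    truth_volumes = []
    for i, vol in enumerate(range(35, 46)):
        t = 10 + i * 10
        y0 = 10 + (i % 3) * 25
        x0 = 10 + (i // 3) * 18
        sets.append(_blob(t, y0, x0, vol))
        truth_volumes.append(vol)
    fixtures["volumes"] = {
        "stack": render_binary_events((130, 80, 80), sets),
        "true_volumes": truth_volumes,
    }

    # (b) simultaneous single-voxel pairs at xy separations 40..60
    fixtures["xy_separation"] = {
        s: render_binary_events((60, 5, 80), [np.array([[10, 2, 5], [10, 2, 5 + s]])])
        for s in range(40, 61)
    }

    # (c) near-co-located single-voxel pairs at frame gaps 1..10
    fixtures["t_gap"] = {
        g: render_binary_events((60, 5, 12), [np.array([[10, 2, 4], [10 + g, 2, 7]])])
        for g in range(1, 11)
    }

    # (d) equal-area strips with footprint overlap 0.70..0.90 step 0.05
    area = 20
    fixtures["overlap"] = {}
    for offset in (6, 5, 4, 3, 2):
        frac = (area - offset) / area
        a = np.array([[10, 3, x] for x in range(0, area)])
        b = np.array([[13, 3, x] for x in range(offset, offset + area)])
        fixtures["overlap"][round(frac, 2)] = render_binary_events((60, 7, 40), [a, b])

    # (e) single-block traces with a k-SD deflection on a deterministic baseline
    fixtures["sd_sweep"] = {}
    n_t = 101
    for k in np.arange(3.0, 7.01, 0.5):
        trace = _BASELINE + np.where(np.arange(n_t) % 2 == 0, 1.0, -1.0)
        trace[50] = _BASELINE + k  # baseline of the other 100 frames has SD 1
        fixtures["sd_sweep"][float(k)] = (
            ImageStack(trace[:, None, None].copy()),
            trace.copy(),
        )
    return fixtures


# ---------------------------------------------------------------------------
# The parameter-recovery scene
# ---------------------------------------------------------------------------


def recovery_scene(seed: int = 0) -> SceneSpec:
    """Twenty planted transients on a 150-frame, 320 x 320 px field.

    The scene holds one four-cell propagating wave (members 40 px apart,
    firing 4 frames after one another — 29.3 um/s at the default
    calibration), one site firing twice 8 frames apart, and fourteen
    isolated transients laid out so that only the wave members and the
    repeat pair fall within the default neighbour tolerances. Amplitudes
    are 18-25 baseline-noise SD and half-maximum volumes far exceed the
    default volume threshold, i.e. clearly detectable events — the scene
    verifies recovery accuracy, not the detection limit.
    """
    events = [
        PlantedEvent(
            centre=(25.0, 30.0 + 40.0 * k),
            onset=20 + 4 * k,
            amplitude=20.0,
            radius=4.0,
            decay=3.0,
            chain=1,
        )
        for k in range(4)
    ]
    # One site firing twice (repeat pair), 5 frames apart. Two firings on one
    # pixel trace double its variance and push the detection threshold up, so
    # this site gets a stronger, faster transient than the single-firing ones;
    # the high amplitude also sharpens the footprint boundary, keeping the two
    # firings' xy footprints overlapping well above the repeat threshold.
    events.append(
        PlantedEvent(
            centre=(100.0, 30.0),
            onset=60,
            amplitude=30.0,
            radius=4.0,
            decay=2.0,
            repeat_onsets=(65,),
        )
    )
    # fourteen isolated transients on a sparse grid, 70+ px apart
    rng = np.random.default_rng(seed + 1)
    cells = [(y, x) for y in (100.0, 170.0, 240.0, 305.0) for x in (30.0, 105.0, 180.0, 255.0)]
    cells.remove((100.0, 30.0))  # occupied by the repeat site
    onsets = np.linspace(12, 135, 15).astype(int)
    for j, (y, x) in enumerate(cells[:14]):
        events.append(
            PlantedEvent(
                centre=(y + rng.uniform(-3, 3), x + rng.uniform(-3, 3)),
                onset=int(onsets[j]),
                amplitude=float(rng.uniform(18, 25)),
                radius=float(rng.uniform(3.0, 5.0)),
                decay=3.0,
            )
        )
    return SceneSpec(shape=(150, 320, 320), events=tuple(events), seed=seed)
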