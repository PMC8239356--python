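# Methods

## Detection model

Event detection is ROI-free: no cell segmentation is assumed or performed.
The field of view is tiled into non-overlapping square blocks ("grains") of
`Grain_size` pixels; trailing partial blocks at non-divisible frame edges
are processed with their actual pixel count. Per grain, the temporal trace
of the block-mean intensity is summarised by its mean μ and population
standard deviation σ over the *entire* recording, events included. A grain
is foreground at frame t iff its block mean reaches μ + k·σ (inclusive
comparison, k = `SD_threshold`); all pixels of a block switch together, and
blocks with σ = 0 are always background.

Two consequences of using full-trace statistics matter in practice:

- an event inflates its own σ, so the effective threshold rises with event
  strength and with the fraction of the recording the event occupies. A
  transient is reliably detected when its on-time is a small fraction of the
  trace (roughly < 1/26 of the frames for the default k = 5 in the
  noise-free limit) — appropriate for sparse transients in recordings of
  hundreds of frames, and the reason the test fixtures use 100–150-frame
  traces;
- detection is contrast-adaptive per grain: a static bright structure does
  not trigger, only temporal deviation from the grain's own history does.

A robust-baseline variant (excluding event frames from μ, σ) is deliberately
not offered; the implemented rule is the literal full-trace statistic.

## Segmentation

Foreground voxels are grouped with full 26-neighbourhood connectivity in
(x, y, t) — waves move diagonally in space-time, so the loosest adjacency is
the right default. Optionally, each connected component is re-partitioned by
a 3-D watershed: the intensity stack is Gaussian-smoothed (σ = 1 px and
1 frame), local maxima (3×3×3 neighbourhood) inside the component become
seeds (one per plateau, at its lowest linear voxel index), and the inverted
smoothed intensity is flooded within the component mask. The watershed
neither creates nor deletes foreground voxels. Event IDs are assigned by
each event's first scan-order voxel, making labels reproducible across
reruns and implementations.

Cleanup removes events *strictly* smaller than `Volume_threshold` voxels —
an event of exactly the threshold volume survives — and relabels survivors
contiguously in their original order.

## Event catalog

Per event: voxel list with intensities; bounding-box extents in x, y
(pixels) and t (frames), measured in voxel counts so a single-voxel event
has extent 1 along each axis; onset/end frames; the intensity-weighted
centre of mass (an event with zero total intensity — possible only on
degenerate input — falls back to the unweighted voxel mean and is flagged);
and the xy footprint (unique (y, x) pixels). Pairwise centre distances are
Euclidean in the xy plane only: time enters the analysis through the
tolerances and onset differences, not through a space-time metric.

## Neighbour and repeat analysis

The search box around event E is centred at E's centre of mass with
half-width per axis = (maximum distance from the centroid to E's extreme
voxel along that axis) + tolerance (`Tolerance_xy` in x and y, `Tolerance_t`
in t). F is a neighbour of E iff *any* voxel of F lies inside the box,
boundaries inclusive — so the tolerance itself is the reachable limit (two
single-voxel events exactly 50 px apart are neighbours at the default).
Membership is evaluated independently per order; for skewed events the
relation can be one-sided, and each qualifying ordered pair produces one
record.

Repeats: for each neighbour pair the footprint overlap fraction is
f = |P_E ∩ P_F| / min(|P_E|, |P_F|). The min denominator makes f symmetric,
so "is a repeat of" is well defined. The pair is linked iff f strictly
exceeds `Intersection_threshold` (exactly 0.8 at the default stays single);
repeat chains are the connected components of linked pairs (transitive
closure — three firings of one site form one chain), and inter-repeat gaps
are onset differences between time-ordered consecutive chain members.

## Summaries

- incidence = event count / (n_cells × recording minutes); the cell count
  is user-supplied since cells are never segmented.
- propagation speed, per unordered neighbour pair with |Δonset| ≥ 1 frame:
  (centre distance in px × pixel size) / (|Δonset| × frame interval).
  Simultaneous pairs carry no propagation time and are excluded.
- duration = temporal extent × frame interval.
- distance travelled = xy bounding-box diagonal × pixel size. The
  alternative (max pairwise voxel distance) was rejected as O(V²) per event
  for no analytical gain.
- neighbouring-wave count, per event: distinct neighbours with strictly
  later onset (consequent waves only).

Group statistics across recordings are intentionally out of scope: the
package exports per-recording values; testing is left to external tools.

## Pre-processing

Intensity: each frame is multiplied by (frame-0 mean / its own mean).
Cascading the matched-to-preceding-frame rule collapses to exactly this, and
the multiplicative form leaves each frame's spatial pattern untouched.

Motion: the field is divided into an 8×8 grid (overridable); subregions with
below-median temporal SD and above-median temporal mean — bright but showing
no calcium oscillations — form the reference region (deterministic fallback:
the single subregion maximising mean/(SD+ε), lowest index on ties). Each
frame's reference crop is registered to frame 0's by the integer arg-max of
their cross-correlation; crops are mean-subtracted and Hann-windowed first,
because on smooth textures the DC term and the circular-wraparound artifacts
of FFT correlation otherwise bias the peak by a pixel. Shifts are integer
only (no subpixel interpolation), registration is always against frame 0 to
avoid drift accumulation, frames whose estimate exceeds half the frame size
are flagged and inherit the previous frame's shift, and translated frames
are zero-filled at the vacated margins. When both corrections run, motion
goes first — zero-filled borders would bias frame means.

## Synthetic scenes

The generator plants transients with explicit ground truth on a noisy
baseline: each event is a spatial Gaussian (σ = `radius` px) with a
saturating rise (τ = `rise` frames) times an exponential decay
(τ = `decay` frames), amplitude expressed in multiples of the baseline noise
SD. Optional per-event velocity renders propagating wave fronts; repeat
onsets re-fire one site. Scene-level features: exponential photobleaching,
a rigid drift schedule, and a static smoothed spatial texture
(`texture_sd`) standing in for cell bodies — the landmarks motion
registration needs. Noise is additive Gaussian; photon-shot statistics,
realistic astrocyte morphology and biophysical Ca²⁺ dynamics are *not*
modelled, so passing recovery tests demonstrates correctness of the
pipeline's geometry and arithmetic on idealised transients, not detection
performance on real recordings.

Ground-truth event volume is the rendered contribution's support above half
its maximum — a detector-independent definition; thresholded volume depends
on detector settings and recording length.

Problem sizes: the defining recovery scene is 150 frames of 320×320 px with
20 planted transients (amplitudes 18–30 noise SD, half-max volumes well
above the 40-voxel cleanup threshold) — about an order of magnitude smaller
than a real 900-frame 960×608 recording, chosen so the whole verification
suite runs in seconds. The noise-free boundary fixtures place events
*exactly at* each default parameter's boundary (volumes 35–45 voxels,
separations 40–60 px, gaps 1–10 frames, overlaps 0.70–0.90, deflections
3–7 baseline SD); their construction guarantees the detection mask equals
the planted voxel set, so every boundary test isolates the semantics of one
rule. In the frame-gap family the two firings are offset by 3 px: truly
co-located voxels one frame apart would be 26-connected and merge into a
single event.

## Numerical choices and degenerate inputs

- Axis order (frame, row, column), 0-based; all geometry in pixels and
  frames; physical units (μm, s) applied only in summaries.
- Population SD (ddof = 0) throughout.
- Detection comparison ≥, neighbour box boundaries inclusive, repeat
  overlap strictly >, cleanup strictly <: each boundary's direction follows
  the parameter's documented meaning, and all are pinned by tests.
- Single-frame stacks, negative or non-finite intensities, multi-channel
  TIFFs, zero-mean frames, out-of-range configuration values and unknown
  configuration keys are rejected with specific errors rather than
  propagated.
- The pipeline is a pure function of (stack, config); reruns produce
  byte-identical artifacts, verified by content checksums in the manifest.

## Known limitations

- Events are not assigned to cells; in monolayer cultures some "neighbour"
  pairs may occur within one cell. Incidence requires a user-supplied cell
  count.
- Full-trace thresholding loses sensitivity for events occupying a large
  fraction of the recording, or for several strong events sharing one grain
  trace (the threshold rises with each firing).
- Motion correction is rigid and integer-valued; non-rigid deformation and
  subpixel drift are out of scope.
- The watershed split is heuristic: it separates touching events only where
  smoothed-intensity maxima are distinct.
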