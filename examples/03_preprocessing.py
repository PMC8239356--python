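"""Undo photobleaching drift and rigid XY motion before detection.

Builds a recording with 1 %/frame bleaching and a stage jump on frames
10-19, then shows that motion correction recovers the injected shift
exactly and intensity correction flattens the frame means.
"""

import numpy as np

from astral import SceneSpec, correct_intensity, correct_motion, generate_stack

drift = {t: (3, -2) for t in range(10, 20)}  # stage jump of (dy=3, dx=-2)
spec = SceneSpec(
    shape=(30, 64, 64),
    bleach_rate=0.01,
    drift=drift,
    noise_sd=0.5,
    texture_sd=15.0,  # static cell-body texture: the landmarks registration needs
    seed=4,
)
stack, _ = generate_stack(spec)

corrected, trace = correct_motion(stack, grid=4)
print("estimated shifts (dy, dx) per frame:")
print(trace.shifts.T)

flattened = correct_intensity(corrected)
means = flattened.data.mean(axis=(1, 2))
print(f"\nframe means before: {stack.data.mean(axis=(1, 2))[[0, 10, 29]].round(2)}")
print(f"frame means after : {means[[0, 10, 29]].round(2)}")
# The shift estimates should read (3, -2) exactly on frames 10-19 and (0, 0)
# elsewhere; after intensity correction every frame mean equals the frame-0
# mean, removing the exponential bleaching trend.
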