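"""Measure intercellular propagation in a planted multi-cell wave.

The scene plants a four-site wave (members 40 px apart, firing 4 frames
apart) plus one site firing twice. The pipeline finds which events are
neighbours, which are repeats of the same site, and how fast activity
travels between neighbouring events.
"""

from astral import Config, generate_stack, run_pipeline
from astral.synthetic import recovery_scene

stack, truth = generate_stack(recovery_scene(seed=1))
result = run_pipeline(stack, Config(n_cells=20))

s = result.summary
print(f"events detected          : {s.n_events}")
print(f"neighbour pairs          : {s.n_neighbour_pairs}")
print(f"median propagation speed : {s.median_propagation_speed:.2f} um/s")
print(f"incidence                : {s.incidence:.2f} events/cell/min")
print(f"median duration          : {s.median_duration:.2f} s")
print(f"median distance travelled: {s.median_distance:.2f} um")
print(f"repeat chains            : {result.classification.chains}")

planted = 40 * stack.pixel_size / (4 * stack.frame_interval)
print(f"\nplanted wave speed       : {planted:.2f} um/s")
# The median propagation speed is taken over neighbour pairs with distinct
# onsets (centre-to-centre distance / onset delay); on this scene the only
# neighbours are the wave members and the repeat pair, so the median should
# recover the planted speed to within a fraction of a percent.
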