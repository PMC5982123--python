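"""Render a small canopy scene and inspect its depth frame and ground truth.

Builds one tangerine-size fruit, a curled leaf touching it and a thin
branch behind, renders a 640x480 depth frame with 1 mm noise, and prints
what the virtual sensor saw.
"""

import numpy as np

from spherecut import (
    BranchCylinder,
    LeafPatch,
    Scene,
    SpheroidFruit,
    adhesion_level,
    make_sensor,
    render_depth,
)

sensor = make_sensor("F200")
fruit = SpheroidFruit(center=[20.0, -10.0, 420.0], Dp=44.0, De=55.0,
                      axis=[0.1, 0.95, 0.3])
leaf = LeafPatch(center=[22.0, 28.0, 415.0], semi_major=45.0, semi_minor=22.0,
                 normal=[0.2, -0.3, -0.93], curl_curvature=1.0 / 90.0)
branch = BranchCylinder(p0=[-150.0, -40.0, 480.0], p1=[160.0, 10.0, 500.0],
                        radius=5.0)
scene = Scene([fruit, leaf, branch], sensor)

frame, truth = render_depth(scene, seed=7)

valid = frame.values[frame.values > 0]
print(f"frame: {frame.shape[1]}x{frame.shape[0]} pixels, "
      f"{frame.n_valid} valid depths in [{valid.min():.0f}, {valid.max():.0f}] mm")
for code, name in [(1, "fruit"), (2, "leaf"), (3, "branch")]:
    print(f"  {name:6s} pixels: {int((truth.label_image == code).sum())}")
print(f"fruit visible fraction: {truth.visible_fraction[0]:.2f}")
print(f"contact pairs (surfaces within 2 mm): {truth.contact_pairs}")
print(f"fruit adhesion level: {adhesion_level(truth, 0)}")

# The visible fraction below 1.0 plus the fruit-leaf contact pair mean the
# leaf both hides part of the fruit surface and physically adjoins it —
# the conditions that make on-branch recognition hard.
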