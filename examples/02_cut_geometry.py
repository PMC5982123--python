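"""The depth-sphere cut of an ideal fruit, worked through numerically.

For a fruit of radius R whose closest point sits at radial distance RA,
cutting with a sphere of radius RC = RA + L intersects the fruit along a
circle; this script prints the chord offset b, the circle radius RC', the
closed-form recovery of L, and the expected point count N1 on the F200
sensor grid.
"""

import math

from spherecut import (
    chord_offset,
    circle_radius,
    cut_radius,
    expected_count,
    make_sensor,
    min_cut_depth,
)

R, RA, L = 27.5, 200.0, 5.0
sensor = make_sensor("F200")

RC = cut_radius(RA, L)
b = chord_offset(R, RA, L)
RCp = circle_radius(R, RA, L)
print(f"fruit R={R} mm at RA={RA} mm, cutting depth L={L} mm")
print(f"  cut-sphere radius    RC  = {RC:.1f} mm")
print(f"  chord offset         b   = {b:.3f} mm (fruit center to cut plane)")
print(f"  intersection circle  RC' = {RCp:.3f} mm")

L_back = RC - math.sqrt(RC**2 - RCp**2) + R - math.sqrt(R**2 - RCp**2)
print(f"  closed-form inverse recovers L = {L_back:.9f} mm")

n1 = expected_count(R, RA, L, sensor, ka=0.8)
print(f"  expected circle points N1 = {n1:.1f} (safety factor ka = 0.8)")

L_min = min_cut_depth(R, RA, sensor, ka=0.8, required=40.0)
print(f"  smallest integer L with 0.5*N1 >= 40 points: {L_min} mm")

# b and RC' satisfy b^2 + RC'^2 = R^2: the cut plane slices the fruit
# sphere exactly where the depth sphere crosses it.  N1 grows with L, so a
# deeper cut buys more evidence at the cost of needing more visible surface.
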