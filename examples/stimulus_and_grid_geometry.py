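"""Build the stimulus dartboard and the OCT posterior-pole grid.

The 60-element dartboard tiles the central 20 degrees of the visual field in
four rings; the 8x8 superpixel grid covers 30 x 25 degrees of the macula and
splits into three concentric areas plus four 13-superpixel quadrant sectors.
"""

import math
from collections import Counter

import mfphnr as m

elements = m.build_dartboard()
print(f"{len(elements)} stimulus elements")
print("per ring:", dict(Counter(e.ring_label for e in elements)))
total = m.geometry.total_stimulus_area(elements)
print(f"total area {total:.3f} deg^2 (20-deg disc = {math.pi * 400:.3f})")

grid = m.build_posterior_pole_grid()
areas = m.map_superpixels_to_areas(grid)
sectors = m.map_superpixels_to_sectors(grid, laterality="OD")
print("superpixels per area:", {a: len(v) for a, v in areas.items()})
print("superpixels per sector:", {s: len(v) for s, v in sectors.items()})
# The area counts show how the grid samples eccentricity; each quadrant
# sector holds exactly 13 superpixels after dropping the 3 foveal-most.
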