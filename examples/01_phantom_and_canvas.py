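"""Generate a synthetic skull slice and assemble the network input canvas.

The phantom is a curved bone plate: two dense cortical tables around a noisy
trabecular core, drawn in Hounsfield units on a water (0 HU) background. The
canvas is that slice clipped to non-negative HU, normalized by the corpus
maximum, with the transducer elements marked as a row of 1's, the target as a
single 1-pixel, and two anti-aliased waveguide lines joining the outermost
elements to the target.
"""

import numpy as np

from skullbeam import build_canvas, generate_skull_phantom
from skullbeam.pipeline import desk_setup

spec, array, config = desk_setup(grid_n=64)
sl = generate_skull_phantom(spec, seed=7)

print(f"phantom: {sl.shape[0]}x{sl.shape[1]} px at {sl.pixel_spacing_mm:.4f} mm/px")
print(f"  bone fraction     : {sl.skull_mask.mean():.3f}")
print(f"  HU range          : {sl.hu_grid.min():.0f} .. {sl.hu_grid.max():.0f}")

canvas = build_canvas(sl, array, target_rc=(44, 32),
                      dataset_max_hu=float(sl.hu_grid.max()))
n_ones = int((canvas.image == 1.0).sum())
print(f"canvas: values in [{canvas.image.min():.2f}, {canvas.image.max():.2f}], "
      f"{n_ones} saturated mark/waveguide pixels")
print(f"  element row       : {canvas.element_rcs[0][0]} "
      f"(3 mm standoff at {sl.pixel_spacing_mm:.3f} mm/px)")
print(f"  aperture          : {canvas.element_rcs[-1][1] - canvas.element_rcs[0][1]} px")
# The canvas is everything the surrogate network sees: anatomy, array
# geometry, and the intended focus, in one [0, 1] image.
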