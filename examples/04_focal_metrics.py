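"""Score a predicted pressure field against ground truth.

Compares the ray-traced correction's field to the time-reversal field with
the full focal-spot metric suite: FWHM-ellipse area error and IoU, peak and
focal pressure errors, Euclidean and modified Hausdorff focal distances, and
the tilt-projected axial/lateral errors.
"""

from skullbeam import (compute_metrics, generate_skull_phantom,
                       map_hu_to_medium, ray_trace_phases, simulate_forward,
                       time_reversal_phases)
from skullbeam.pipeline import desk_setup

spec, array, config = desk_setup(grid_n=64)
sl = generate_skull_phantom(spec, seed=8)
medium = map_hu_to_medium(sl)
target = (44, 32)

gt = simulate_forward(medium, array,
                      time_reversal_phases(medium, array, target, config).delays_s,
                      config)
pred = simulate_forward(medium, array,
                        ray_trace_phases(medium, array, target).delays_s, config)

report = compute_metrics(pred, gt, gt_focus_rc=target)
for key, value in report.as_dict().items():
    print(f"  {key:26s}: {value:8.3f}")
# Area error / IoU describe the FWHM spot shape; the pressure errors say how
# much amplitude the candidate correction recovers; Euclidean / MHD / axial /
# lateral describe where the spot landed relative to ground truth (mm).
# Note the peak-anywhere convention: for strongly reverberant skulls the
# window-wide peak (hence the FWHM spot) can sit in the near field rather
# than at the focus -- the focal_pressure error is the focus-specific number.
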