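# Methods

`skullbeam` is a desk-scale toolkit for 2D transcranial focused ultrasound:
it simulates linear acoustic propagation of a phased-array burst through a
skull cross-section, computes per-element phase aberration corrections, scores
focal spots with a standard metric suite, and trains a multi-task LSTM-Conv
surrogate network that predicts the corrected pressure field, its absolute
peak, and the correction delays directly from an image of the scene. This
note records the models, the numerical choices, and what the reduced-scale
experiments do and do not establish.

## Synthetic skull phantoms

Real calvarial CT data is not bundled; the `phantoms` module generates
procedural stand-ins. A phantom is the upper arc of an annulus: pixels whose
distance to a circle center (placed below the apex) lies in
[R, R + thickness], with outer and inner cortical bands at high HU framing a
trabecular core of lower HU plus smoothed Gaussian texture. Default ranges —
curvature radius 60–110 mm, total thickness 4–9 mm, cortical fraction
0.2–0.5, cortical 1200–1900 HU, trabecular 300–800 HU, texture scale 150 HU —
emulate adult parietal/temporal segments in cross-section. Background is 0 HU
(water/soft tissue); the skull mask is HU > 150. Everything is seeded and
bit-reproducible.

What the phantoms do *not* capture: sutures, diploë porosity statistics from
real CT, frontal/occipital geometry, CT artifacts. Tests passing on phantoms
therefore demonstrate the pipeline's correctness and the physics of
aberration/correction, not clinical-image robustness.

The input canvas for the surrogate follows the training-image convention:
HU clipped at 0 and divided by the corpus-wide maximum HU, element pixels and
the target pixel overwritten with 1, and two anti-aliased lines (Wu-style
two-pixel coverage) from the outermost elements to the target marking the
unaberrated propagation cone. A greedy mean-squared-error filter
(`diversity_filter`) prunes near-duplicate phantoms; the threshold is
configurable because no canonical value exists.

## Acoustic model and solver

Material maps: density from a two-segment piecewise-linear CT calibration
(−1000 HU → 1.293 kg/m³, 0 HU → 997, 1600 HU → 2000, linear extrapolation
above), clipped below at 997 kg/m³ so non-bone behaves as water; sound speed
c = 1.33 ρ + 166.67 (m/s); absorption 13.3 dB/(MHz·cm) on the skull mask and
0 elsewhere, applied as a frequency-independent amplitude decay evaluated at
the drive frequency (power-law exponent y = 1 read as a single per-MHz
constant).

The solver integrates the first-order linear acoustic system (pressure p,
particle velocity v) with Fourier spectral spatial derivatives, a split-field
PML, and sequential (symplectic-Euler) time stepping at CFL 0.3, the step
rounded down so one drive period is an integer number of samples. Two
deliberate departures from the most common k-space formulation:

* **Centered, non-staggered derivative operators** (Nyquist bin zeroed).
  Half-pixel staggering does not commute with the spatially varying PML and
  medium factors, which breaks reflection symmetry by ~0.3% in water and a
  few percent at bone interfaces. The centered operator anticommutes exactly
  with grid reflection, so the solver is mirror-equivariant to rounding
  error — a property the test suite asserts — while producing physically
  equivalent fields at our resolutions.
* **PML outside the window**: the material grids are edge-padded by
  `pml_px` (default 20 px full scale, 12 px desk scale) and cropped on
  return, so the 3 mm element standoff row and deep targets never sit inside
  the absorbing layer even on coarse grids.

Sources are additive pressure injections over each element's width (default
half a pitch), driving a 5-cycle Hann-windowed sine burst with per-element
delays; the injection scale c·Δt/Δx makes the drive track
`element_pressure_pa` up to a constant factor — only relative pressures and
same-solver comparisons enter any metric. The per-pixel running maximum |p|
(max-amplitude projection) stands in for the steady-state field; total time
defaults to burst + diagonal transit at the minimum speed + 20%. The
stated full-scale configuration — 6 cm/512 px window (0.117 mm), 80 elements
at 0.7 mm pitch, 500 kHz, 1 MPa, 3 mm standoff — is the default; tests run
reduced 32–128 px grids at 150–250 kHz with 16–40 elements, chosen so a
wavelength spans ≥ 5 px and the whole suite fits comfortably on one CPU.

## Aberration correction

* `geometric_focus_phases`: closed-form water-path delays (oracle).
* `ray_trace_phases`: straight-segment travel time ∫ds/c with bilinear speed
  lookup every quarter pixel; refraction deliberately ignored — this is the
  geometric baseline.
* `time_reversal_phases`: full-wave. A burst is emitted from the target and
  recorded at the array; emission delays are max(τ) − τ (the element that
  hears the pulse last fires first). Two details matter:
  * **Reciprocity of extended elements.** Receive traces are averaged over
    the same pixel group each element drives on transmit. Sampling only the
    element center measurably degrades the correction for finite-width
    elements (enough to fall behind ray tracing at desk scale).
  * **Arrival estimator.** Per element: coarse arrival from the envelope
    peak of the matched filter (cross-correlation with the emitted burst),
    refined by the phase of the Fourier component at f0 over a window around
    that arrival. The window keeps late reverberations out of the phase; the
    coarse estimate resolves the one-period ambiguity per element, avoiding
    fragile cross-array unwrapping. A pure envelope-peak estimator
    (`method="xcorr"`) is available; elements with trace amplitude below 5%
    of the array median are flagged and interpolated from neighbours.

`PhaseVector` stores nonnegative delays (min 0) in seconds; wrapped phases at
f0 and delays as fractions of a period in [0, 1) are derived views. The
fraction representation is the surrogate's training target — bounded, at the
cost of a wrap discontinuity that plain L1 ignores (a known caveat, accepted
because observed delay spreads stay within one period at desk scale).

## Focal-spot metrics

The binary focal mask is P ≥ 0.5 · Pmax (half maximum, peak taken anywhere
in the window). An ellipse is fit to the largest 8-connected component by
second-order image moments (full axis = 4√eigenvalue, a +1/12 px² integration
term keeping single pixels non-degenerate) and rasterized back to a mask; the
area-error and IoU terms are computed on these ellipse masks by default (raw
threshold masks by flag). Tilt θ is measured from the array normal, negative
to the right, reported 0 when the axis ratio is below 1.05. The modified
Hausdorff distance is the max of the two directed mean nearest-neighbour
distances between boundary pixels (component minus its 4-connected erosion).
Axial/lateral errors project the Cartesian peak offset onto the predicted
ellipse axes: axial = dy cos θ − dx sin θ, lateral = dy sin θ + dx cos θ.
Area error is |area(pred) − area(gt)|/area(gt)·100 — an area *difference*,
not an overlap measure (disjoint equal-area spots score 0). Peak-location
ties break to the first row-major occurrence.

## Surrogate network

Implemented on a small reverse-mode autodiff engine (`skullbeam.nn`) written
for this package: numpy tensors, im2col convolution, explicit-loop LSTM,
batch-norm, dropout, Adam, plateau LR scheduling. Gradients are verified
against numeric differentiation in the test suite.

Each LSTM-Conv cell scans its single-channel square input with four LSTMs
(top-down, bottom-up, left-right, right-left; hidden size = row length;
independent weights per direction unless tied by config), stacks the four
feature maps as channels, then applies conv(4→8, 3×3), conv(8→16, 3×3) with
stride-2 downsampling (encoder) or nearest ×2 upsampling + conv (decoder),
and a 1×1 conv back to one channel, with batch-norm + ReLU after every
convolution. Dropout 0.2 acts on the 16-channel intermediate features:
placing it on the single-channel output would delete a fifth of the cell's
entire signal at every one of the 10+ cells, which empirically froze
multi-sample training; the 16-channel placement regularizes without that
pathology. Final per-direction LSTM states are average-pooled or repeated to
the next cell's size and passed on.

The encoder stacks five down cells (grid → grid/32); the decoder five up
cells with skip connections (channel concatenation + 1×1 conv merge at each
matching resolution); a 1×1 conv + sigmoid head bounds the normalized field
to [0, 1]. The phase decoder consumes only the first encoder cell's output
through three further down cells, a flatten, and two fully-connected layers
with a sigmoid onto period fractions. The absolute-pressure decoder consumes
only the bottleneck embedding through a conv and two fully-connected layers,
scaled by 10⁶ (outputs in Pa). Absolute field = normalized field × scalar by
construction. A 1-layer → 4-layer LSTM transfer (`transfer_weights`) copies
all shared-shape parameters.

Losses: field — mean over pixels of W·(error)², with W = λ_skull(t) on rows
above the split (round(180/512 · grid) — the transducer/skull region) and
λ_focus(t) = 1 − λ_skull(t) below; λ_skull(t) = 0.5 for (1-based) epoch
t < 5, then 0.5^(t−4), so training progressively concentrates on the focal
region. Phase and absolute pressure use plain L1. Training is staged: field
first (encoder + decoder), then phase, then absolute pressure with the
encoder frozen — enforced by running it detached in inference mode and
audited by hashing its weights before/after. Adam (default lr 2e-4 at full
scale), ReduceLROnPlateau(0.1, patience 2, threshold 1e-3); the scheduler
monitors validation loss at *fixed* epoch-1 weights, because the λ schedule
otherwise changes the scale it compares across epochs.

### Reduced-scale training conditions

The packaged experiments run at 32×32 (6 cm window, 16 elements, 150 kHz):
10 phantoms × 6 targets whose bounding box covers ~45% of the window
(mirroring the full-scale lattice's coverage), split 8/2 by skull so
validation anatomy is never seen in training; batch size 2, lr 2e-2, staged
30/8/5 epochs, plateau patience 4. Small batches matter: the skull-region
structure must be learned during the uniform-weight phase (epochs 1–4), which
at full scale holds thousands of optimizer steps — batch 2 gives it ~100
steps here. At this scale the trained model overfits a single sample below
10⁻³ weighted loss (capacity), beats the mean-training-field predictor on
held-out normalized-field MSE, and beats the zero-delay baseline on held-out
phase L1. These are qualitative recoveries of the full-scale behavior; the
published-scale accuracy figures require the full 512×512, ~180k-sample GPU
training and are out of scope here.

## Pipeline conventions

Ground-truth records store the canvas, the self-normalized field (max exactly
1), its peak in Pa, and the time-reversal phase vector, with splits disjoint
by skull id. Benchmarks re-simulate each candidate correction (uncorrected /
ray / time-reversal / surrogate phases) and score it against the
time-reversal field; uncorrected and ray fields are computed on demand rather
than stored. The unseen-target analysis samples random targets in the
training lattice's bounding box, bins them by distance to the nearest
training point (equal-width annuli, 5 by default — exact edges are not
canonical), and reports per-bin mean errors plus a Spearman trend statistic
(reported, not asserted, for untrained models). Coordinates are 0-based
(row, col) with row 0 at the transducer side; all mm↔px conversions go
through `pixel_spacing_mm`.

## Known limitations

2D only; linear acoustics without shear conversion or dispersion; a single
flat array geometry; procedural phantoms rather than generative-model or real
CT anatomy; absolute source calibration defined up to a constant; the L1
phase loss ignores the wrap discontinuity; desk-scale grids (≤ 128 px) keep
wavelengths at 5–13 px, so fine speckle is under-resolved relative to the
full-scale configuration.
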