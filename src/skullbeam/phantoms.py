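"""Synthetic 2D skull phantoms and network input canvases.

Procedurally generated curved-plate skull slices stand in for generative-model
output: two high-attenuation cortical bands enclosing a noisy trabecular core,
parameterized to emulate parietal/temporal calvarial segments in cross section.
The module also builds the normalized input canvas (skull + transducer element
marks + target pixel + anti-aliased waveguide lines) consumed by the surrogate
network, regular target lattices, and rigid perturbations for robustness
studies.

Conventions: 0-based (row, col) indexing, row 0 at the top (transducer side);
all mm <-> pixel conversions go through ``pixel_spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SkullSlice",
    "PhantomSpec",
    "Canvas",
    "TargetGrid",
    "generate_skull_phantom",
    "upsample_nearest",
    "diversity_filter",
    "draw_line_wu",
    "rasterize_waveguides",
    "build_canvas",
    "make_target_grid",
    "perturb_slice",
]

DEFAULT_BONE_THRESHOLD_HU = 150.0


@dataclass
class SkullSlice:
    """A 2D skull CT cross-section in Hounsfield units.

    Attributes
    ----------
    hu_grid:
        2D float array of Hounsfield units. Background (water / soft tissue)
        is <= 0; bone is strongly positive.
    pixel_spacing_mm:
        Isotropic in-plane resolution, mm per pixel.
    skull_mask:
        Boolean array, True where ``hu_grid`` exceeds the bone threshold.
    provenance_seed:
        Seed the phantom generator used, for reproducibility (-1 if external).
    """

    hu_grid: np.ndarray
    pixel_spacing_mm: float
    skull_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance_seed: int = -1
    bone_threshold_hu: float = DEFAULT_BONE_THRESHOLD_HU

    def __post_init__(self) -> None:
        self.hu_grid = np.asarray(self.hu_grid, dtype=np.float64)
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.skull_mask is None:
            self.skull_mask = self.hu_grid > self.bone_threshold_hu
        self.skull_mask = np.asarray(self.skull_mask, dtype=bool)
        if self.skull_mask.shape != self.hu_grid.shape:
            raise ValueError("hu_grid and skull_mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu_grid.shape  # type: ignore[return-value]


@dataclass
class PhantomSpec:
    """Parameter ranges for the curved-plate skull generator.

    Ranges are (low, high) tuples sampled uniformly per phantom. Defaults
    emulate adult parietal/temporal bone: ~70-100 mm outer-table curvature,
    4-9 mm total thickness with cortical tables framing porous trabecular
    bone near 300-800 HU while cortical bone sits near 1200-1900 HU.
    """

    grid_size_native: int = 128
    pixel_spacing_mm: float = 0.625
    curvature_radius_mm: tuple[float, float] = (60.0, 110.0)
    total_thickness_mm: tuple[float, float] = (4.0, 9.0)
    cortical_fraction: tuple[float, float] = (0.2, 0.5)
    cortical_hu: tuple[float, float] = (1200.0, 1900.0)
    trabecular_hu: tuple[float, float] = (300.0, 800.0)
    trabecular_noise_scale: float = 150.0
    bone_threshold_hu: float = DEFAULT_BONE_THRESHOLD_HU
    apex_depth_mm: tuple[float, float] = (8.0, 14.0)
    center_col_jitter_mm: float = 4.0

    def validate(self) -> None:
        for name in ("curvature_radius_mm", "total_thickness_mm",
                     "cortical_fraction", "cortical_hu", "trabecular_hu",
                     "apex_depth_mm"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.total_thickness_mm[0] <= 0:
            raise ValueError("thickness must be positive")
        if not (0 < self.cortical_fraction[0] and self.cortical_fraction[1] < 1):
            raise ValueError("cortical_fraction must lie in (0, 1)")
        if self.cortical_hu[0] < self.trabecular_hu[0]:
            raise ValueError("cortical HU must not undercut trabecular HU")
        extent_mm = self.grid_size_native * self.pixel_spacing_mm
        if self.apex_depth_mm[1] + self.total_thickness_mm[1] >= extent_mm:
            raise ValueError("skull plate does not fit inside the grid")


@dataclass
class Canvas:
    """Normalized network-input image with element / target / waveguide marks."""

    image: np.ndarray
    target_rc: tuple[int, int]
    element_rcs: list[tuple[int, int]]
    dataset_max_hu: float
    waveguides_enabled: bool = True

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("canvas image must lie in [0, 1]")


@dataclass
class TargetGrid:
    """Regular lattice of focal targets below the skull."""

    points: list[tuple[int, int]]
    pitch_mm: float = 3.74
    layout: tuple[int, int] = (7, 8)


# ---------------------------------------------------------------------------
# phantom generation


def generate_skull_phantom(spec: PhantomSpec, seed: int) -> SkullSlice:
    """Generate one curved-plate skull slice.

    The plate is the upper arc of an annulus: pixels whose distance to a
    circle center (placed below the apex) lies in [R, R + thickness]. The
    outer and inner rims get cortical HU; the interior gets trabecular HU
    plus smoothed Gaussian texture. Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.grid_size_native
    dx = spec.pixel_spacing_mm

    radius = rng.uniform(*spec.curvature_radius_mm)
    thickness = rng.uniform(*spec.total_thickness_mm)
    cfrac = rng.uniform(*spec.cortical_fraction)
    hu_cort = rng.uniform(*spec.cortical_hu)
    hu_trab = min(rng.uniform(*spec.trabecular_hu), hu_cort)
    apex_depth = rng.uniform(*spec.apex_depth_mm)
    col_jitter = rng.uniform(-spec.center_col_jitter_mm, spec.center_col_jitter_mm)

    # circle center in mm, below the plate apex so the plate bulges upward
    center_r = apex_depth + radius
    center_c = (n - 1) * dx / 2.0 + col_jitter

    rr, cc = np.meshgrid(np.arange(n) * dx, np.arange(n) * dx, indexing="ij")
    dist = np.hypot(rr - center_r, cc - center_c)
    in_plate = (dist >= radius) & (dist <= radius + thickness) & (rr < center_r)

    cort_band = thickness * cfrac / 2.0
    outer_cort = in_plate & (dist <= radius + cort_band)
    inner_cort = in_plate & (dist >= radius + thickness - cort_band)
    trab = in_plate & ~outer_cort & ~inner_cort

    hu = np.zeros((n, n), dtype=np.float64)
    hu[outer_cort | inner_cort] = hu_cort
    if trab.any():
        noise = rng.standard_normal((n, n))
        if spec.trabecular_noise_scale > 0:
            noise = ndimage.gaussian_filter(noise, sigma=1.0)
            noise = noise / max(noise.std(), 1e-12) * spec.trabecular_noise_scale
        else:
            noise = np.zeros_like(noise)
        hu[trab] = np.clip(hu_trab + noise[trab], spec.bone_threshold_hu + 1.0, hu_cort)

    return SkullSlice(
        hu_grid=hu,
        pixel_spacing_mm=dx,
        skull_mask=hu > spec.bone_threshold_hu,
        provenance_seed=seed,
        bone_threshold_hu=spec.bone_threshold_hu,
    )


def upsample_nearest(sl: SkullSlice, factor: int) -> SkullSlice:
    """Nearest-neighbour upsampling: each pixel becomes a factor x factor block."""
    if not float(factor).is_integer() or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    hu = np.repeat(np.repeat(sl.hu_grid, factor, axis=0), factor, axis=1)
    mask = np.repeat(np.repeat(sl.skull_mask, factor, axis=0), factor, axis=1)
    return replace(sl, hu_grid=hu, skull_mask=mask,
                   pixel_spacing_mm=sl.pixel_spacing_mm / factor)


def diversity_filter(slices: Sequence[SkullSlice], mse_threshold: float) -> list[SkullSlice]:
    """Greedy diversity pruning by pairwise mean squared error.

    A slice is retained only if its MSE against every already-retained slice
    exceeds ``mse_threshold``; scanning order is input order, so the output
    is an order-stable subset.
    """
    kept: list[SkullSlice] = []
    for sl in slices:
        if kept and sl.hu_grid.shape != kept[0].hu_grid.shape:
            raise ValueError("all slices must share one shape")
        if all(np.mean((sl.hu_grid - k.hu_grid) ** 2) > mse_threshold for k in kept):
            kept.append(sl)
    return kept


# ---------------------------------------------------------------------------
# canvas construction


def draw_line_wu(image: np.ndarray, r0: float, c0: float, r1: float, c1: float) -> None:
    """Draw an anti-aliased line (Xiaolin Wu style) into ``image`` in place.

    For each step along the major axis the exact fractional crossing of the
    minor axis splits unit intensity between the two straddling pixels.
    Existing pixel values are kept where larger (lines never darken marks).
    """
    steep = abs(r1 - r0) > abs(c1 - c0)
    # work in (x, y) with x the major axis
    if steep:
        x0, y0, x1, y1 = r0, c0, r1, c1
    else:
        x0, y0, x1, y1 = c0, r0, c1, r1
    if x0 > x1:
        x0, x1, y0, y1 = x1, x0, y1, y0
    dx = x1 - x0
    grad = (y1 - y0) / dx if dx != 0 else 0.0

    def plot(x: int, y: int, v: float) -> None:
        if steep:
            r, c = x, y
        else:
            r, c = y, x
        if 0 <= r < image.shape[0] and 0 <= c < image.shape[1] and v > 0:
            image[r, c] = max(image[r, c], v)

    xs = int(round(x0))
    xe = int(round(x1))
    for x in range(xs, xe + 1):
        y = y0 + grad * (x - x0)
        yf = int(np.floor(y))
        frac = y - yf
        plot(x, yf, 1.0 - frac)
        plot(x, yf + 1, frac)


def rasterize_waveguides(canvas: Canvas) -> Canvas:
    """Draw the two waveguide lines from the outermost elements to the target.

    The lines mark the unaberrated propagation cone on the network input.
    Idempotent: intensities are merged with ``max``.
    """
    tr, tc = canvas.target_rc
    left = canvas.element_rcs[0]
    right = canvas.element_rcs[-1]
    if tr <= left[0]:
        raise ValueError("target must lie below the element row")
    img = canvas.image
    draw_line_wu(img, float(left[0]), float(left[1]), float(tr), float(tc))
    draw_line_wu(img, float(right[0]), float(right[1]), float(tr), float(tc))
    # marks stay saturated
    for r, c in canvas.element_rcs:
        img[r, c] = 1.0
    img[tr, tc] = 1.0
    return canvas


def element_positions(
    shape: tuple[int, int],
    pixel_spacing_mm: float,
    n_elements: int,
    pitch_mm: float,
    standoff_mm: float,
) -> list[tuple[int, int]]:
    """Pixel positions of a flat array: one row at the standoff depth,
    columns centered with the given pitch."""
    row = int(round(standoff_mm / pixel_spacing_mm))
    pitch_px = pitch_mm / pixel_spacing_mm
    center = (shape[1] - 1) / 2.0
    # round half away from the array center so the layout mirrors exactly
    # under column reflection (c -> ncols-1-c)
    cols = []
    for k in range(n_elements):
        off = (k - (n_elements - 1) / 2.0) * pitch_px
        col = center + off
        if off < 0:
            cols.append(int(np.floor(col + 0.5 - 1e-9)))
        else:
            cols.append(int(np.ceil(col - 0.5 + 1e-9)))
    if min(cols) < 0 or max(cols) >= shape[1]:
        raise ValueError("array aperture exceeds the grid")
    return [(row, c) for c in cols]


def build_canvas(
    sl: SkullSlice,
    array_spec,
    target_rc: tuple[int, int],
    dataset_max_hu: float,
    waveguides_enabled: bool = True,
) -> Canvas:
    """Assemble the normalized network input.

    The skull is clipped to non-negative HU and scaled by the corpus-wide
    maximum HU; element pixels and the target pixel are set to exactly 1;
    waveguides are drawn at their anti-aliased coverage intensity on top.
    """
    if dataset_max_hu <= 0:
        raise ValueError("dataset_max_hu must be positive")
    if dataset_max_hu < sl.hu_grid.max() - 1e-9:
        raise ValueError("dataset_max_hu below slice maximum: stale normalizer")
    tr, tc = target_rc
    if not (0 <= tr < sl.shape[0] and 0 <= tc < sl.shape[1]):
        raise ValueError("target outside grid")

    img = np.clip(sl.hu_grid, 0.0, None) / dataset_max_hu
    els = element_positions(sl.shape, sl.pixel_spacing_mm, array_spec.n_elements,
                            array_spec.pitch_mm, array_spec.standoff_mm)
    canvas = Canvas(image=img, target_rc=(tr, tc), element_rcs=els,
                    dataset_max_hu=dataset_max_hu,
                    waveguides_enabled=waveguides_enabled)
    for r, c in els:
        img[r, c] = 1.0
    img[tr, tc] = 1.0
    if waveguides_enabled:
        rasterize_waveguides(canvas)
    return canvas


def make_target_grid(
    layout: tuple[int, int],
    pitch_mm: float,
    anchor_rc: tuple[int, int],
    pixel_spacing_mm: float,
    shape: tuple[int, int],
) -> TargetGrid:
    """Regular target lattice anchored at its top-left point."""
    n_rows, n_cols = layout
    pitch_px = pitch_mm / pixel_spacing_mm
    points = []
    for i in range(n_rows):
        for j in range(n_cols):
            r = int(round(anchor_rc[0] + i * pitch_px))
            c = int(round(anchor_rc[1] + j * pitch_px))
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError("target lattice exceeds grid bounds")
            points.append((r, c))
    return TargetGrid(points=points, pitch_mm=pitch_mm, layout=layout)


def perturb_slice(sl: SkullSlice, rotation_deg: float, shift_mm: tuple[float, float]) -> SkullSlice:
    """Rigid rotation (about the grid center) + translation, nearest-neighbour
    resampled; content moved past the border is clipped away (filled with 0)."""
    if abs(rotation_deg) > 45:
        raise ValueError("|rotation_deg| must be <= 45")
    dx_px = shift_mm[0] / sl.pixel_spacing_mm  # column shift
    dy_px = shift_mm[1] / sl.pixel_spacing_mm  # row shift
    hu = sl.hu_grid
    if rotation_deg != 0:
        hu = ndimage.rotate(hu, rotation_deg, reshape=False, order=0, cval=0.0)
    if dx_px or dy_px:
        hu = ndimage.shift(hu, (dy_px, dx_px), order=0, cval=0.0)
    return replace(sl, hu_grid=hu, skull_mask=hu > sl.bone_threshold_hu)
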