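"""Focal-spot evaluation metrics for predicted vs ground-truth pressure fields.

The suite mirrors the standard descriptive comparison for transcranial
focusing: a half-maximum (FWHM) binary mask, an ellipse fit to its largest
connected component, and from those
  * focal area percent error (absolute area difference over ground-truth area),
  * intersection-over-union of the focal masks (percent),
  * peak pressure percent error (peak anywhere in the window),
  * focal pressure percent error (pressures at the ground-truth focus),
  * Euclidean distance between peak locations (mm),
  * modified Hausdorff distance between focal boundaries (mm),
  * axial/lateral focal position errors, the Euclidean offset projected onto
    the major/minor axes of the predicted FWHM ellipse (signed; a tilt to the
    right of the array normal counts negative).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .acoustics import PressureField

__all__ = [
    "FocalMask",
    "FocalEllipse",
    "MetricsReport",
    "half_max_mask",
    "largest_component_ellipse",
    "rasterize_ellipse",
    "focal_area_error",
    "iou",
    "peak_pressure_error",
    "focal_pressure_error",
    "euclidean_mm",
    "boundary_points",
    "modified_hausdorff_mm",
    "axial_lateral_mm",
    "compute_metrics",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass
class FocalMask:
    mask: np.ndarray
    source_peak_pa: float


@dataclass
class FocalEllipse:
    """Ellipse fit to the largest focal component by image moments.

    ``theta_deg`` is the tilt of the major axis measured from the array
    normal (the vertical / row axis); tilts to the right (+col with depth)
    are negative, tilts to the left positive; range (-90, 90].
    """

    center_rc: tuple[float, float]
    major_px: float
    minor_px: float
    theta_deg: float


@dataclass
class MetricsReport:
    focal_area_error_pct: float
    iou_pct: float
    peak_pressure_error_pct: float
    focal_pressure_error_pct: float
    euclidean_mm: float
    mhd_mm: float
    axial_mm: float
    lateral_mm: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------


def half_max_mask(field: PressureField | np.ndarray) -> FocalMask:
    """Binary mask of pixels at or above half the field's peak pressure."""
    arr = field.field if isinstance(field, PressureField) else np.asarray(field, dtype=float)
    peak = float(arr.max())
    if peak <= 0:
        raise ValueError("field has no positive pressure; half-max undefined")
    return FocalMask(mask=arr >= 0.5 * peak, source_peak_pa=peak)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise ValueError("empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def largest_component_ellipse(
    mask: FocalMask | np.ndarray,
    circular_ratio: float = 1.05,
) -> FocalEllipse:
    """Moment-based ellipse fit to the largest 8-connected component.

    Axis lengths follow the standard second-moment convention (full axis =
    4 sqrt(eigenvalue)). Near-circular components (axis ratio below
    ``circular_ratio``) report theta = 0 to keep the axial/lateral
    projection stable.
    """
    m = mask.mask if isinstance(mask, FocalMask) else np.asarray(mask, dtype=bool)
    comp = _largest_component(m)
    r, c = np.nonzero(comp)
    center = (float(r.mean()), float(c.mean()))
    # second central moments (+1/12 pixel-integration term keeps single
    # pixels and thin lines non-degenerate)
    mu_rr = ((r - center[0]) ** 2).mean() + 1.0 / 12.0
    mu_cc = ((c - center[1]) ** 2).mean() + 1.0 / 12.0
    mu_rc = ((r - center[0]) * (c - center[1])).mean()
    cov = np.array([[mu_rr, mu_rc], [mu_rc, mu_cc]])
    evals, evecs = np.linalg.eigh(cov)
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    v = evecs[:, 1]  # (dr, dc) of major axis
    if v[0] < 0:
        v = -v
    theta = -np.degrees(np.arctan2(v[1], v[0]))  # right of normal negative
    if theta <= -90.0:
        theta += 180.0
    if minor > 0 and major / minor < circular_ratio:
        theta = 0.0
    return FocalEllipse(center_rc=center, major_px=float(major),
                        minor_px=float(minor), theta_deg=float(theta))


def rasterize_ellipse(ellipse: FocalEllipse, shape: tuple[int, int]) -> np.ndarray:
    """Binary raster of the fitted ellipse (pixel centers inside)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - ellipse.center_rc[0]
    dc = cc - ellipse.center_rc[1]
    th = np.radians(-ellipse.theta_deg)  # back to math convention
    u = dr * np.cos(th) + dc * np.sin(th)  # along major axis
    w = -dr * np.sin(th) + dc * np.cos(th)
    a = max(ellipse.major_px / 2.0, 0.5)
    b = max(ellipse.minor_px / 2.0, 0.5)
    return (u / a) ** 2 + (w / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------


def _as_mask(m) -> np.ndarray:
    return m.mask if isinstance(m, FocalMask) else np.asarray(m, dtype=bool)


def focal_area_error(m_pred, m_gt) -> float:
    """| area(pred) - area(gt) | / area(gt) x 100."""
    a_pred = int(_as_mask(m_pred).sum())
    a_gt = int(_as_mask(m_gt).sum())
    if a_gt == 0:
        raise ValueError("empty ground-truth mask")
    return abs(a_pred - a_gt) / a_gt * 100.0


def iou(m_pred, m_gt) -> float:
    """Intersection over union of the focal masks, percent."""
    a, b = _as_mask(m_pred), _as_mask(m_gt)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks empty")
    return float(np.logical_and(a, b).sum() / union * 100.0)


def peak_pressure_error(pred: PressureField, gt: PressureField) -> float:
    """Percent error of the window-wide peak pressure."""
    if gt.peak_pa <= 0:
        raise ValueError("zero ground-truth peak pressure")
    return abs(pred.peak_pa - gt.peak_pa) / gt.peak_pa * 100.0


def focal_pressure_error(pred: PressureField, gt: PressureField,
                         gt_focus_rc: tuple[int, int]) -> float:
    """Percent error of the pressures at the ground-truth focus location."""
    p_gt = float(gt.field[gt_focus_rc])
    if p_gt <= 0:
        raise ValueError("zero ground-truth focal pressure")
    p_pred = float(pred.field[gt_focus_rc])
    return abs(p_pred - p_gt) / p_gt * 100.0


def euclidean_mm(pred_rc, gt_rc, pixel_spacing_mm: float) -> float:
    dr = (pred_rc[0] - gt_rc[0]) * pixel_spacing_mm
    dc = (pred_rc[1] - gt_rc[1]) * pixel_spacing_mm
    return float(np.hypot(dr, dc))


def boundary_points(mask) -> np.ndarray:
    """Outer contour pixels of the largest 8-connected component:
    component pixels with at least one 4-neighbour outside it."""
    comp = _largest_component(_as_mask(mask))
    eroded = ndimage.binary_erosion(comp, structure=ndimage.generate_binary_structure(2, 1))
    return np.argwhere(comp & ~eroded)


def modified_hausdorff_mm(m_pred, m_gt, pixel_spacing_mm: float) -> float:
    """Modified Hausdorff distance between focal boundaries, mm.

    max of the two directed mean nearest-neighbour distances between the
    boundary point sets of the largest connected components.
    """
    b_pred = boundary_points(m_pred).astype(float)
    b_gt = boundary_points(m_gt).astype(float)
    d_pg = cKDTree(b_gt).query(b_pred)[0].mean()
    d_gp = cKDTree(b_pred).query(b_gt)[0].mean()
    return float(max(d_pg, d_gp) * pixel_spacing_mm)


def axial_lateral_mm(dx_mm: float, dy_mm: float, theta_deg: float) -> tuple[float, float]:
    """Project a Cartesian focal offset onto the predicted-ellipse axes.

    dx is the lateral (column) offset, dy the depth (row) offset, theta the
    predicted-ellipse tilt. Axial = dy cos(theta) - dx sin(theta);
    lateral = dy sin(theta) + dx cos(theta). The rotation is an isometry:
    axial^2 + lateral^2 = dx^2 + dy^2.
    """
    th = np.radians(theta_deg)
    axial = dy_mm * np.cos(th) - dx_mm * np.sin(th)
    lateral = dy_mm * np.sin(th) + dx_mm * np.cos(th)
    return float(axial), float(lateral)


# ---------------------------------------------------------------------------


def compute_metrics(
    pred: PressureField,
    gt: PressureField,
    gt_focus_rc: tuple[int, int] | None = None,
    use_ellipse_masks: bool = True,
) -> MetricsReport:
    """Full report for a prediction / ground-truth field pair.

    With ``use_ellipse_masks`` (default) the area and IoU terms are computed
    on the rasterized fitted ellipses; otherwise on the raw half-max masks.
    ``gt_focus_rc`` defaults to the ground-truth peak location.
    """
    m_pred = half_max_mask(pred)
    m_gt = half_max_mask(gt)
    e_pred = largest_component_ellipse(m_pred)
    e_gt = largest_component_ellipse(m_gt)
    if use_ellipse_masks:
        a_pred = rasterize_ellipse(e_pred, pred.field.shape)
        a_gt = rasterize_ellipse(e_gt, gt.field.shape)
    else:
        a_pred, a_gt = m_pred.mask, m_gt.mask

    focus_rc = gt_focus_rc if gt_focus_rc is not None else gt.peak_rc
    spacing = gt.pixel_spacing_mm
    dx_mm = (pred.peak_rc[1] - gt.peak_rc[1]) * spacing
    dy_mm = (pred.peak_rc[0] - gt.peak_rc[0]) * spacing
    axial, lateral = axial_lateral_mm(dx_mm, dy_mm, e_pred.theta_deg)

    return MetricsReport(
        focal_area_error_pct=focal_area_error(a_pred, a_gt),
        iou_pct=iou(a_pred, a_gt),
        peak_pressure_error_pct=peak_pressure_error(pred, gt),
        focal_pressure_error_pct=focal_pressure_error(pred, gt, focus_rc),
        euclidean_mm=euclidean_mm(pred.peak_rc, gt.peak_rc, spacing),
        mhd_mm=modified_hausdorff_mm(a_pred, a_gt, spacing),
        axial_mm=axial,
        lateral_mm=lateral,
    )
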