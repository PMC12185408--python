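"""Segmentation, morphometrics and frame selection for cell image stacks.

A single adherent cell is imaged top-down while a pressure wave passes.
Each frame is segmented (Otsu threshold, morphological cleanup, largest
connected component, marching-squares subpixel contour); the contour is
reduced to the standard shape descriptors; and the initial/final frames
are selected in synchrony with the pressure waveform: the initial state
is the last frame before wave arrival, the final state the frame at the
pressure peak — or, if the cell detaches, the last adhered frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from ._geometry import (
    as_polygon,
    polygon_area,
    polygon_perimeter,
    polygon_second_moments,
)
from .synthdata import LoadingWaveform

__all__ = ["CellShape", "FrameSelection", "SegmentationResult",
           "segment_cell", "measure_shape", "select_frames", "compute_zeta"]


@dataclass(frozen=True)
class CellShape:
    """Contour plus scalar shape descriptors of one segmented cell.

    The contour is an ordered subpixel vertex list in µm; the angle is
    the principal-axis orientation measured from the flow (image x)
    axis, axial in [0, 180).  Dimensionless descriptors:
    elongation = 1 − λmin/λmax of the second-moment eigenvalues,
    circularity = 4πA/P² (≤ 1), compactness = P²/(4πA) (its inverse),
    convexity = P_hull/P (≤ 1), solidity = A/A_hull (≤ 1).
    """

    contour: np.ndarray
    area: float        # µm²
    perimeter: float   # µm
    angle: float       # degrees in [0, 180)
    elongation: float
    circularity: float
    convexity: float
    compactness: float
    solidity: float


@dataclass(frozen=True)
class SegmentationResult:
    """Subpixel contour (µm) and boolean mask of the segmented cell."""

    contour: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class FrameSelection:
    """Initial/final frame indices synchronized to the waveform."""

    initial_index: int
    final_index: int
    detached: bool
    p_at_final: float  # kPa

    def __post_init__(self):
        if self.initial_index >= self.final_index:
            raise ValueError("initial_index must precede final_index")


def segment_cell(
    frame: np.ndarray,
    pixel_size: float = 1.0,
    min_area_px: float = 20.0,
    opening_radius: int = 1,
) -> SegmentationResult | None:
    """Segment the single cell in one bright-field-like frame.

    Otsu threshold -> morphological open/close (disk footprint) ->
    largest connected component -> marching-squares subpixel contour,
    converted to µm.  The contour is traced on the intensity image at
    the midpoint between the component's interior and background
    levels: edge pixels carry intermediate intensities (the pixel
    aperture integrates over the boundary), so interpolating through
    them recovers the boundary position well below one pixel.  Falls
    back to the 0.5-level contour of the binary mask if the refinement
    finds nothing.  Returns None when no component reaches
    ``min_area_px`` or the image is degenerate.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if img.size == 0 or np.ptp(img) == 0:
        return None
    try:
        thr = threshold_otsu(img)
    except ValueError:
        return None
    mask = img > thr
    # reject degenerate scenes where Otsu merely splits sensor noise:
    # a real cell separates the classes by far more than their spread
    m0, m1 = img[~mask].mean(), img[mask].mean()
    spread = max(img[~mask].std(), img[mask].std(), 1e-12)
    if (m1 - m0) < 4.0 * spread:
        return None
    if opening_radius > 0:
        footprint = morphology.disk(opening_radius)
        mask = morphology.opening(mask, footprint)
        mask = morphology.closing(mask, footprint)
    labels = measure.label(mask)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area_px:
        return None
    component = labels == biggest
    contour_rc = _subpixel_contour(img, component)
    if contour_rc is None:
        contours = measure.find_contours(component.astype(float), 0.5)
        if not contours:
            return None
        contour_rc = max(contours, key=lambda c: c.shape[0])
    # (row, col) -> (x, y) in µm
    contour = np.column_stack([contour_rc[:, 1], contour_rc[:, 0]]) * pixel_size
    return SegmentationResult(contour=contour, mask=component)


def _subpixel_contour(img: np.ndarray, component: np.ndarray) -> np.ndarray | None:
    """Marching squares on the intensity image at the class-midpoint level.

    The image is clamped to the background level outside a dilated
    neighbourhood of the component so that sensor noise elsewhere
    cannot spawn spurious contours; the largest closed contour by
    enclosed area is returned (rows, cols), or None.
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    interior = binary_erosion(component, iterations=2)
    if interior.sum() < 4:
        interior = component
    outside = ~binary_dilation(component, iterations=3)
    if outside.sum() < 4:
        return None
    m_in = float(img[interior].mean())
    m_out = float(img[outside].mean())
    if m_in <= m_out:
        return None
    level = 0.5 * (m_in + m_out)
    work = np.where(binary_dilation(component, iterations=3), img, m_out)
    contours = [c for c in measure.find_contours(work, level)
                if len(c) >= 3 and np.allclose(c[0], c[-1])]
    if not contours:
        return None

    def enclosed(c):
        x, y = c[:, 1], c[:, 0]
        return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    return max(contours, key=enclosed)


def measure_shape(contour) -> CellShape:
    """Shape descriptors of a simple polygon contour (µm coordinates).

    Area by the shoelace formula, perimeter by edge-length sum, angle
    and elongation from the central second moments, the ratio
    descriptors from the convex hull.  Raises on self-intersection.
    """
    v = as_polygon(contour)
    if not ShapelyPolygon(v).is_valid:
        raise ValueError("self-intersecting contour")

    area = polygon_area(v)
    if area == 0:
        raise ValueError("degenerate contour with zero area")
    perim = polygon_perimeter(v)

    mxx, myy, mxy = polygon_second_moments(v)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    lam_min, lam_max = float(evals[0]), float(evals[1])
    major = evecs[:, 1]
    angle = np.degrees(np.arctan2(major[1], major[0])) % 180.0
    elongation = 1.0 - lam_min / max(lam_max, 1e-300)

    hull = ConvexHull(v)
    hull_pts = v[hull.vertices]
    hull_area = polygon_area(hull_pts)
    hull_perim = polygon_perimeter(hull_pts)

    return CellShape(
        contour=v,
        area=area,
        perimeter=perim,
        angle=float(angle),
        elongation=float(elongation),
        circularity=float(4.0 * np.pi * area / perim**2),
        convexity=float(hull_perim / perim),
        compactness=float(perim**2 / (4.0 * np.pi * area)),
        solidity=float(area / hull_area),
    )


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def select_frames(
    stack: np.ndarray,
    waveform: LoadingWaveform,
    pixel_size: float = 1.0,
    arrival_k: float = 3.0,
    iou_threshold: float = 0.3,
) -> FrameSelection:
    """Pick the initial and final analysis frames for one experiment.

    The initial state is the last frame whose pressure stays below
    baseline + k·(baseline noise sd); the final state is the frame at
    the pressure peak, unless segmentation reports detachment first
    (mask IoU with the previous frame below ``iou_threshold``, or no
    cell found), in which case the last adhered frame is used and its
    pressure is read from the waveform.
    """
    p = np.asarray(waveform.pressures, dtype=float)
    if len(stack) != p.size:
        raise ValueError("stack and waveform must be time-aligned (equal length)")

    baseline = p[: waveform.arrival_index]
    if baseline.size == 0:
        raise ValueError("waveform has no pre-arrival baseline segment")
    noise_sd = float(np.std(baseline))
    thresh = waveform.p0 + arrival_k * max(noise_sd, 1e-9 * max(waveform.p0, 1.0))
    above = np.nonzero(p > thresh)[0]
    if above.size == 0 or above[0] == 0:
        raise ValueError("wave arrival not detected in the waveform")
    initial_index = int(above[0]) - 1  # last frame before the detected arrival

    final_index = int(waveform.peak_index)
    detached = False
    prev_mask = None
    for i in range(initial_index, waveform.peak_index + 1):
        seg = segment_cell(stack[i], pixel_size=pixel_size)
        if seg is None or (prev_mask is not None and _mask_iou(seg.mask, prev_mask) < iou_threshold):
            final_index = i - 1
            detached = True
            break
        prev_mask = seg.mask
    if final_index <= initial_index:
        raise ValueError("cell detached before any loaded frame")

    return FrameSelection(
        initial_index=initial_index,
        final_index=final_index,
        detached=detached,
        p_at_final=float(p[final_index]),
    )


def compute_zeta(initial: CellShape, final: CellShape) -> float:
    """Final-to-initial projected area ratio ζ = A_final/A_initial."""
    if initial.area <= 0 or final.area <= 0:
        raise ValueError("areas must be positive")
    return final.area / initial.area
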