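"""Sliding-window single-cell segmentation for dense adherent monolayers.

MSC monolayers are thin, crowded and weakly delimited, which defeats the
usual instance segmenters; instead, candidate windows sized from ~50
measured cells are slid across the field at 10%-of-window steps and each
crop is screened:

    binarize -> morphological closing -> trace contours -> sort by area.

If a cell sits in the window, the largest contour is the cell outline and
the second largest is the nucleus (nuclei carry little signal and appear as
holes).  The convex hull of the second contour must be round enough
(circularity >= c_min) and close to the window centre; windows passing both
tests are single-cell detections.  Overlapping windows find the same cell
repeatedly, so detections are reduced by greedy non-maximum suppression on
nucleus-hull overlap, keeping the best-centred window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from enum import Enum
from math import ceil
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon as ShapelyPolygon

from ._imageops import (
    histogram_peak_threshold,
    polyline_length,
    shoelace_area,
    trace_contours,
)
from .synth import ImageField

#: 5x5 ellipse structuring element for the closing step
_CLOSING_FOOTPRINT = np.array(
    [
        [0, 0, 1, 0, 0],
        [0, 1, 1, 1, 0],
        [1, 1, 1, 1, 1],
        [0, 1, 1, 1, 0],
        [0, 0, 1, 0, 0],
    ],
    dtype=bool,
)
#: foreground components smaller than this are treated as noise speckle
_MIN_COMPONENT_PX = 20

__all__ = [
    "WindowSizeMatrix",
    "Contour",
    "CellDetection",
    "RejectionReason",
    "ScreenParams",
    "DetectionResult",
    "estimate_window_matrix",
    "slide_windows",
    "screen_crop",
    "deduplicate",
    "detect_cells",
    "detections_to_dataframe",
]

MIN_WINDOW_DIM = 32


class RejectionReason(str, Enum):
    NO_CONTOUR = "no_contour"
    LOW_CIRCULARITY = "low_circularity"
    OFF_CENTER = "off_center"
    DUPLICATE = "duplicate"


@dataclass(frozen=True)
class WindowSizeMatrix:
    """Candidate window dimensions, sorted ascending by area."""

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("window size matrix must be non-empty")
        if any(h < MIN_WINDOW_DIM or w < MIN_WINDOW_DIM for h, w in self.entries):
            raise ValueError(f"all window dimensions must be >= {MIN_WINDOW_DIM}")
        areas = [h * w for h, w in self.entries]
        if areas != sorted(areas):
            raise ValueError("entries must be sorted ascending by area")


@dataclass(frozen=True)
class Contour:
    """A closed contour with its shape descriptors (0-based row/col points)."""

    points: np.ndarray
    area: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]  # (row, col)

    @classmethod
    def from_polygon(cls, poly: ShapelyPolygon, points: np.ndarray) -> "Contour":
        area = poly.area
        perimeter = poly.length
        return cls(
            points=points,
            area=float(area),
            perimeter=float(perimeter),
            circularity=float(4.0 * np.pi * area / perimeter**2) if perimeter > 0 else 0.0,
            centroid=(float(poly.centroid.y), float(poly.centroid.x)),
        )


@dataclass
class CellDetection:
    """Outcome of screening one window (coordinates are field-global once
    produced by :func:`detect_cells`, crop-local from :func:`screen_crop`)."""

    window: tuple[int, int, int, int]  # (top, left, height, width)
    largest_contour: Contour | None
    second_contour: Contour | None  # nucleus convex hull
    accepted: bool
    rejection_reason: RejectionReason | None
    centroid_offset: float = float("inf")


@dataclass(frozen=True)
class ScreenParams:
    """Screening thresholds.

    ``c_min`` and ``r_max_frac`` are the two acceptance tests; the area
    guards encode the "largest = cell, second = nucleus" reading of the
    contour ranking so that speckle or window-interior texture cannot pose
    as a nucleus.
    """

    c_min: float = 0.7
    r_max_frac: float = 0.15  # of the window diagonal
    min_cell_area: float = 300.0
    min_nucleus_area: float = 40.0
    max_nucleus_frac: float = 0.5
    fg_frac_range: tuple[float, float] = (0.08, 0.85)
    center_fg_min: float = 0.15  # coverage of the central window quarter
    nms_iou: float = 0.3


def estimate_window_matrix(
    cell_sizes: list[tuple[float, float]],
    percentiles: tuple[float, ...] = (25.0, 50.0, 75.0, 95.0),
    inflate: float = 1.2,
) -> WindowSizeMatrix:
    """Window sizes covering the observed cell-size distribution.

    For each percentile of the measured bounding-box areas the closest
    measured (height, width) is taken and inflated by 20%, so each window
    comfortably encloses cells of that size class.  Windows within 20% of
    the area of an already-kept smaller window add nothing but redundant
    crops and are dropped, so unimodal size distributions collapse to one
    or two entries.
    """
    if len(cell_sizes) < 5:
        raise ValueError("need at least 5 measured cell sizes")
    sizes = np.asarray(cell_sizes, dtype=float)
    areas = sizes[:, 0] * sizes[:, 1]
    entries: set[tuple[int, int]] = set()
    for q in percentiles:
        target = np.percentile(areas, q)
        h, w = sizes[int(np.argmin(np.abs(areas - target)))]
        entries.add(
            (max(MIN_WINDOW_DIM, ceil(h * inflate)), max(MIN_WINDOW_DIM, ceil(w * inflate)))
        )
    ordered = sorted(entries, key=lambda hw: (hw[0] * hw[1], hw))
    kept: list[tuple[int, int]] = []
    for h, w in ordered:
        if kept and h * w < 1.2 * kept[-1][0] * kept[-1][1]:
            continue
        kept.append((h, w))
    return WindowSizeMatrix(entries=tuple(kept))


def _axis_positions(field_dim: int, win_dim: int, step: int) -> list[int]:
    positions = list(range(0, field_dim - win_dim + 1, step))
    if positions[-1] != field_dim - win_dim:
        positions.append(field_dim - win_dim)  # clamp so coverage is complete
    return positions


def slide_windows(
    field: ImageField | np.ndarray, wsm: WindowSizeMatrix
) -> Iterator[tuple[tuple[int, int, int, int], np.ndarray]]:
    """Yield (window bounds, crop view) at 10%-of-window steps per size.

    Window sizes larger than the field are skipped with a warning.
    """
    pixels = field.pixels if isinstance(field, ImageField) else field
    fh, fw = pixels.shape
    for h, w in wsm.entries:
        if h > fh or w > fw:
            warnings.warn(f"window {h}x{w} larger than field {fh}x{fw}; skipped",
                          stacklevel=2)
            continue
        step_r = ceil(0.1 * h)
        step_c = ceil(0.1 * w)
        for top in _axis_positions(fh, h, step_r):
            for left in _axis_positions(fw, w, step_c):
                yield (top, left, h, w), pixels[top : top + h, left : left + w]


def _sorted_contours(binary: np.ndarray) -> list[tuple[np.ndarray, float]]:
    """(points, area) per closed contour, largest first; equal areas break
    ties toward the rounder contour."""
    items = []
    for pts in trace_contours(binary):
        area = shoelace_area(pts)
        if area <= 0:
            continue
        perim = polyline_length(pts)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        items.append((pts, area, circ))
    items.sort(key=lambda it: (-it[1], -it[2]))
    return [(pts, area) for pts, area, _ in items]


def _contour_from_points(pts: np.ndarray) -> tuple[Contour, ShapelyPolygon]:
    poly = ShapelyPolygon(pts[:, ::-1])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return Contour.from_polygon(poly, pts), poly


def screen_crop(crop: np.ndarray, params: ScreenParams = ScreenParams()) -> CellDetection:
    """Screen one crop for a centred single cell; rejection is a value."""
    h, w = crop.shape
    window = (0, 0, h, w)

    def reject(reason: RejectionReason, largest=None, second=None) -> CellDetection:
        return CellDetection(
            window=window,
            largest_contour=largest,
            second_contour=second,
            accepted=False,
            rejection_reason=reason,
        )

    threshold = histogram_peak_threshold(crop)
    binary = crop > threshold
    fg = binary.mean()
    if not params.fg_frac_range[0] <= fg <= params.fg_frac_range[1]:
        return reject(RejectionReason.NO_CONTOUR)
    closed = ndimage.binary_closing(binary, structure=_CLOSING_FOOTPRINT)
    # erase sub-nucleus speckle so it cannot pose as a contour
    labels, n_comp = ndimage.label(closed, structure=np.ones((3, 3), dtype=bool))
    if n_comp == 0:
        return reject(RejectionReason.NO_CONTOUR)
    comp_sizes = np.bincount(labels.ravel())[1:]
    if comp_sizes.max() < params.min_cell_area:
        return reject(RejectionReason.NO_CONTOUR)
    small = np.flatnonzero(comp_sizes < _MIN_COMPONENT_PX) + 1
    if len(small):
        closed = closed & ~np.isin(labels, small)
    contours = _sorted_contours(closed)
    if len(contours) < 2:
        return reject(RejectionReason.NO_CONTOUR)
    cell_pts, cell_area = contours[0]
    nucleus_pts, nucleus_area = contours[1]
    cell, cell_poly = _contour_from_points(cell_pts)
    if cell.area < params.min_cell_area:
        return reject(RejectionReason.NO_CONTOUR)
    if (
        nucleus_area < params.min_nucleus_area
        or nucleus_area > params.max_nucleus_frac * cell_area
    ):
        return reject(RejectionReason.NO_CONTOUR, largest=cell)

    hull = ShapelyPolygon(nucleus_pts[:, ::-1]).convex_hull
    hull_pts = np.asarray(hull.exterior.coords)[:, ::-1]
    nucleus = Contour.from_polygon(hull, hull_pts)
    if nucleus.circularity < params.c_min:
        return reject(RejectionReason.LOW_CIRCULARITY, largest=cell, second=nucleus)
    if not cell_poly.contains(Point(nucleus.centroid[1], nucleus.centroid[0])):
        return reject(RejectionReason.OFF_CENTER, largest=cell, second=nucleus)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    offset = float(np.hypot(nucleus.centroid[0] - center[0], nucleus.centroid[1] - center[1]))
    r_max = params.r_max_frac * float(np.hypot(h, w))
    if offset > r_max:
        return reject(RejectionReason.OFF_CENTER, largest=cell, second=nucleus)
    return CellDetection(
        window=window,
        largest_contour=cell,
        second_contour=nucleus,
        accepted=True,
        rejection_reason=None,
        centroid_offset=offset,
    )


def _shift_contour(contour: Contour, top: int, left: int) -> Contour:
    return Contour(
        points=contour.points + np.array([top, left], dtype=float),
        area=contour.area,
        perimeter=contour.perimeter,
        circularity=contour.circularity,
        centroid=(contour.centroid[0] + top, contour.centroid[1] + left),
    )


def to_global(detection: CellDetection, top: int, left: int, h: int, w: int) -> CellDetection:
    """Re-express a crop-local detection in field coordinates."""
    return CellDetection(
        window=(top, left, h, w),
        largest_contour=(
            _shift_contour(detection.largest_contour, top, left)
            if detection.largest_contour
            else None
        ),
        second_contour=(
            _shift_contour(detection.second_contour, top, left)
            if detection.second_contour
            else None
        ),
        accepted=detection.accepted,
        rejection_reason=detection.rejection_reason,
        centroid_offset=detection.centroid_offset,
    )


def _nucleus_shape(detection: CellDetection) -> ShapelyPolygon:
    return ShapelyPolygon(detection.second_contour.points[:, ::-1])


def deduplicate(detections: list[CellDetection], nms_iou: float = 0.3) -> list[CellDetection]:
    """Greedy non-maximum suppression on nucleus-hull overlap.

    Detections are visited in order of increasing centroid offset; a
    detection whose nucleus hull overlaps an already-kept one with
    IoU > ``nms_iou`` is marked duplicate.
    """
    accepted = [d for d in detections if d.accepted]
    accepted.sort(key=lambda d: d.centroid_offset)
    kept: list[CellDetection] = []
    kept_shapes: list[ShapelyPolygon] = []
    for det in accepted:
        shape = _nucleus_shape(det)
        duplicate = False
        for other in kept_shapes:
            inter = shape.intersection(other).area
            if inter > 0:
                iou = inter / shape.union(other).area
                if iou > nms_iou:
                    duplicate = True
                    break
        if duplicate:
            det.accepted = False
            det.rejection_reason = RejectionReason.DUPLICATE
        else:
            kept.append(det)
            kept_shapes.append(shape)
    return kept


@dataclass
class DetectionResult:
    """Accepted single-cell detections for one field plus screening counts."""

    detections: list[CellDetection]
    n_windows: int = 0
    n_screened: int = 0
    rejection_counts: dict[str, int] = dc_field(default_factory=dict)


def detect_cells(
    field: ImageField | np.ndarray,
    wsm: WindowSizeMatrix,
    params: ScreenParams = ScreenParams(),
) -> DetectionResult:
    """Run the full sliding-window screen over a field and deduplicate.

    Windows whose global-threshold foreground fraction is outside
    ``fg_frac_range`` are skipped before the per-crop screen (an integral
    image makes this O(1) per window), which is what keeps dense fields
    tractable.
    """
    pixels = field.pixels if isinstance(field, ImageField) else field
    gbin = (pixels > histogram_peak_threshold(pixels)).astype(np.int64)
    integral = np.pad(gbin.cumsum(axis=0).cumsum(axis=1), ((1, 0), (1, 0)))

    def fg_fraction(top: int, left: int, h: int, w: int) -> float:
        s = (
            integral[top + h, left + w]
            - integral[top, left + w]
            - integral[top + h, left]
            + integral[top, left]
        )
        return s / (h * w)

    candidates: list[CellDetection] = []
    n_windows = 0
    n_screened = 0
    rejections: dict[str, int] = {}
    lo, hi = params.fg_frac_range
    for (top, left, h, w), crop in slide_windows(pixels, wsm):
        n_windows += 1
        if not lo <= fg_fraction(top, left, h, w) <= hi:
            continue
        # a centred cell must cover the central quarter of the window
        ct, cl, ch, cw = top + h // 4, left + w // 4, h // 2, w // 2
        if fg_fraction(ct, cl, ch, cw) < params.center_fg_min:
            continue
        n_screened += 1
        det = screen_crop(crop, params)
        if det.accepted:
            candidates.append(to_global(det, top, left, h, w))
        else:
            key = det.rejection_reason.value
            rejections[key] = rejections.get(key, 0) + 1
    kept = deduplicate(candidates, nms_iou=params.nms_iou)
    n_dups = len(candidates) - len(kept)
    if n_dups:
        rejections["duplicate"] = rejections.get("duplicate", 0) + n_dups
    return DetectionResult(
        detections=kept,
        n_windows=n_windows,
        n_screened=n_screened,
        rejection_counts=rejections,
    )


def detections_to_dataframe(result: DetectionResult) -> pd.DataFrame:
    """Flat per-detection table (window bounds, contour stats)."""
    rows = []
    for i, d in enumerate(result.detections):
        top, left, h, w = d.window
        rows.append(
            {
                "detection_id": i,
                "top": top,
                "left": left,
                "height": h,
                "width": w,
                "cell_area": d.largest_contour.area,
                "cell_perimeter": d.largest_contour.perimeter,
                "nucleus_area": d.second_contour.area,
                "nucleus_circularity": d.second_contour.circularity,
                "nucleus_row": d.second_contour.centroid[0],
                "nucleus_col": d.second_contour.centroid[1],
                "centroid_offset": d.centroid_offset,
                "accepted": d.accepted,
            }
        )
    return pd.DataFrame(rows)
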