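"""Single-cell mask construction and feature extraction.

For every accepted single-cell crop the mask is built the same way for both
modalities: adaptive histogram-peak thresholding, dilation with a kernel of
size 5, a 3x3 mean filter (re-binarized at 0.5), then the largest connected
component.  From the masked crop the clustering features are extracted:

* FLIM:  cell area (px^2), peak of the a2 distribution histogram, and the
  full width at half maximum (FWHM) of that histogram.
* SRS:   cell area, perimeter, circularity (4*pi*A/P^2) and the mean grey
  value of the cell region.

Feature tables are min-max normalized to [0, 1] before clustering; the
normalization parameters are retained so new cells can be projected into
the same space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, uniform_filter
from skimage import measure

from ._imageops import binarize, histogram_peak_threshold, polyline_length, trace_contours

__all__ = [
    "CellMask",
    "MaskFailureError",
    "FeatureFailureError",
    "FeatureTable",
    "build_mask",
    "a2_histogram_features",
    "morphology_features",
    "mean_gray",
    "normalize_features",
    "denormalize_features",
    "histogram_peak_threshold",
    "A2_HISTOGRAM_BIN_WIDTH",
    "MIN_MASK_PIXELS",
]

#: a2 histogram bin width — 1 percentage point over [0, 1]
A2_HISTOGRAM_BIN_WIDTH = 0.01
#: minimum masked pixels for histogram features
MIN_MASK_PIXELS = 50

FLIM_FEATURES = ("area", "a2_peak", "a2_fwhm")
SRS_FEATURES = ("area", "perimeter", "circularity", "mean_gray")


class MaskFailureError(RuntimeError):
    """Raised when no foreground survives thresholding."""


class FeatureFailureError(RuntimeError):
    """Raised when a cell has too few pixels for a feature."""


@dataclass(frozen=True)
class CellMask:
    """Binary single-cell mask (largest connected component of the crop)."""

    mask: np.ndarray
    largest_component: bool = True

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise ValueError("mask must be non-empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def build_mask(crop: np.ndarray) -> CellMask:
    """Cell-region mask: threshold -> dilate(5) -> mean-filter(3) -> largest CC."""
    if crop.size == 0:
        raise ValueError("crop is empty")
    threshold = histogram_peak_threshold(crop)
    binary = crop > threshold
    if not binary.any() or binary.all():
        raise MaskFailureError("thresholding produced no usable foreground")
    footprint = np.array(  # 5x5 ellipse, matching the closing kernel
        [
            [0, 0, 1, 0, 0],
            [0, 1, 1, 1, 0],
            [1, 1, 1, 1, 1],
            [0, 1, 1, 1, 0],
            [0, 0, 1, 0, 0],
        ],
        dtype=bool,
    )
    dilated = binary_dilation(binary, structure=footprint)
    smoothed = uniform_filter(dilated.astype(float), size=3) >= 0.5
    if not smoothed.any():
        raise MaskFailureError("mean filtering removed all foreground")
    labels = measure.label(smoothed, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return CellMask(mask=labels == largest)


def a2_histogram_features(
    crop: np.ndarray,
    mask: CellMask,
    bin_width: float = A2_HISTOGRAM_BIN_WIDTH,
) -> tuple[float, float]:
    """Peak and FWHM of the masked a2 distribution histogram.

    The peak is the centre of the modal bin of a fixed-width histogram over
    [0, 1].  The FWHM is the distance between the two half-maximum crossings
    of the histogram envelope around the global modal bin, located by linear
    interpolation; a crossing that runs off the histogram ends at the
    outermost bin centre.

    Exact zeros are excluded: the lifetime fitter writes a2 = 0 at pixels
    below its photon threshold, so zeros flag background, not a bound
    fraction of zero.
    """
    values = crop[mask.mask]
    values = values[values > 0.0]
    if len(values) < MIN_MASK_PIXELS:
        raise FeatureFailureError(
            f"only {len(values)} masked pixels; need >= {MIN_MASK_PIXELS}"
        )
    n_bins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_idx = int(np.argmax(counts))
    peak = float(centers[peak_idx])
    half = counts[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 <= i + direction < n_bins and counts[i + direction] >= half:
            i += direction
        j = i + direction
        if not 0 <= j < n_bins:
            return float(centers[i])
        # linear interpolation between bin centres i and j
        c_i, c_j = counts[i], counts[j]
        frac = (c_i - half) / max(c_i - c_j, 1e-12)
        return float(centers[i] + direction * frac * bin_width)

    fwhm = crossing(+1) - crossing(-1)
    return peak, float(max(fwhm, 0.0))


def morphology_features(mask: CellMask) -> tuple[float, float, float]:
    """(area, perimeter, circularity) of the mask.

    Area is the foreground pixel count; the perimeter is the length of the
    traced outer boundary polygon (sub-pixel marching-squares contour, so
    diagonal steps count as sqrt(2)); circularity is 4*pi*A/P^2.
    """
    area = float(mask.n_pixels)
    contours = trace_contours(mask.mask)
    if not contours:
        raise ValueError("mask has no boundary")
    outer = max(contours, key=len)
    perimeter = polyline_length(outer)
    circularity = 4.0 * np.pi * area / perimeter**2
    return area, float(perimeter), float(circularity)


def mean_gray(crop: np.ndarray, mask: CellMask) -> float:
    """Mean intensity of the cell region: sum of masked pixels / pixel count."""
    if mask.n_pixels == 0:
        raise ValueError("mask is empty")
    return float(crop[mask.mask].mean())


@dataclass
class FeatureTable:
    """A per-cell feature table with its normalization state.

    Clustering operates only on normalized tables; the ``normalized`` flag
    plus the stored min/max allow round-tripping and projection of new cells.
    """

    data: pd.DataFrame
    feature_columns: tuple[str, ...]
    normalized: bool = False
    norm_params: dict[str, tuple[float, float]] = dc_field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return self.data[list(self.feature_columns)].to_numpy(dtype=float)


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Min-max scale every feature column to [0, 1].

    Constant columns map to 0 (with a warning); the per-column (min, max)
    pairs are stored on the returned table for denormalization.
    """
    df = table.data
    if len(df) < 2:
        raise ValueError("need at least 2 rows to normalize")
    if df[list(table.feature_columns)].isna().any().any():
        raise ValueError("feature table contains missing values")
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in table.feature_columns:
        lo = float(df[col].min())
        hi = float(df[col].max())
        params[col] = (lo, hi)
        if hi == lo:
            warnings.warn(f"feature {col!r} is constant; mapped to 0", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (df[col] - lo) / (hi - lo)
    return FeatureTable(
        data=out,
        feature_columns=table.feature_columns,
        normalized=True,
        norm_params=params,
    )


def denormalize_features(table: FeatureTable) -> FeatureTable:
    """Invert :func:`normalize_features` using the stored parameters."""
    if not table.normalized:
        raise ValueError("table is not normalized")
    out = table.data.copy()
    for col in table.feature_columns:
        lo, hi = table.norm_params[col]
        if hi != lo:
            out[col] = out[col] * (hi - lo) + lo
        else:
            out[col] = lo
    return FeatureTable(data=out, feature_columns=table.feature_columns, normalized=False)


def extract_features(
    crop: np.ndarray,
    modality: str,
    mask: CellMask | None = None,
    extra_morphology: bool = False,
) -> dict[str, float]:
    """All features of one crop for the given modality, as a dict.

    ``extra_morphology=True`` appends perimeter and circularity to the FLIM
    set as well, enabling the ablation of clustering with and without the
    additional shape features (the metabolic features normally carry the
    signal, so the default set is the lean one).
    """
    if mask is None:
        mask = build_mask(crop)
    area, perimeter, circularity = morphology_features(mask)
    if modality == "FLIM_A2":
        peak, fwhm = a2_histogram_features(crop, mask)
        feats = {"area": area, "a2_peak": peak, "a2_fwhm": fwhm}
        if extra_morphology:
            feats.update({"perimeter": perimeter, "circularity": circularity})
        return feats
    if modality == "SRS":
        return {
            "area": area,
            "perimeter": perimeter,
            "circularity": circularity,
            "mean_gray": mean_gray(crop, mask),
        }
    raise ValueError(f"unknown modality {modality!r}")
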