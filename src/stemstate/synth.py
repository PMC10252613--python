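"""Synthetic FLIM/SRS microscopy fields with known per-cell ground truth.

Real acquisitions of mesenchymal stem cell (MSC) monolayers are dense fields
of elongated adherent cells with visible nuclei and unclear boundaries.  The
generator emulates the two modalities the analysis consumes:

* ``FLIM_A2`` — a per-pixel map of a2, the fractional amplitude of
  protein-bound NAD(P)H in a bi-exponential lifetime fit, values in [0, 1].
  Within a cell the a2 values are unimodal around a per-cell peak whose
  location and width shift with differentiation state (undifferentiated
  cells sit near 0.19, differentiated cells above 0.30).  Nuclei and
  background carry essentially no NAD(P)H signal and render as near-zero.
* ``SRS`` — a 16-bit lipid-channel (2850 cm^-1) intensity image with
  Poisson shot noise; lipid droplets appear as bright disks whose number
  and brightness grow with differentiation state.

Cells are perturbed ellipses (MSCs are spindle-shaped); nuclei are rounder
ellipses centred in the cell.  Cells may touch, nuclei never overlap, and
every rendered polygon is recorded exactly in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import Point, Polygon as ShapelyPolygon
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

__all__ = [
    "StateConfig",
    "TimepointMixture",
    "CellRecord",
    "GroundTruth",
    "ImageField",
    "DecayCurve",
    "PlacementError",
    "default_state_configs",
    "default_mixtures",
    "generate_field",
    "generate_decay",
    "sample_feature_table",
    "GAUSSIAN_FWHM_FACTOR",
]

MODALITIES = ("FLIM_A2", "SRS")

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) * sigma
GAUSSIAN_FWHM_FACTOR = float(2.0 * np.sqrt(2.0 * np.log(2.0)))

# Rendering constants (see docs/methods.md for the reasoning).
NUCLEUS_AREA_FRACTION = 0.0625  # nucleus area as a fraction of cell area
BOUNDARY_PERTURB_AMP = 0.06  # sinusoidal radial perturbation of the ellipse
FLIM_SPECKLE_FRAC = 0.02  # background pixels with residual dim signal
FLIM_SPECKLE_RANGE = (0.01, 0.04)
SRS_BACKGROUND_LAMBDA = 1500.0
SRS_CYTOPLASM_LAMBDA = 20000.0
SRS_DROPLET_RADIUS_PX = 3.0
SRS_MAX = 65535


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without nucleus overlap."""


@dataclass(frozen=True)
class StateConfig:
    """Per-state generative parameters for one differentiation state.

    Parameters are in image units: a2 quantities are fractions in [0, 1],
    areas are px^2, droplet intensities are 16-bit grey levels.
    """

    state_name: str
    a2_peak_mean: float
    a2_peak_sd: float
    a2_width_mean: float
    a2_width_sd: float
    droplet_count_mean: float
    droplet_intensity_mean: float
    cell_area_mean: float
    cell_area_sd: float
    eccentricity_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.a2_peak_mean < 1.0:
            raise ValueError("a2_peak_mean must lie in (0, 1)")
        for name in ("a2_peak_sd", "a2_width_sd", "cell_area_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.droplet_count_mean < 0:
            raise ValueError("droplet_count_mean must be >= 0")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity_range must be within [0, 1)")


@dataclass(frozen=True)
class TimepointMixture:
    """State composition of one induction timepoint (e.g. Day 7)."""

    day: int
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions.values()):
            raise ValueError("each fraction must lie in [0, 1]")

    def realized_counts(self, n_cells: int) -> dict[str, int]:
        """Largest-remainder rounding of ``fractions * n_cells``."""
        names = list(self.fractions)
        exact = np.array([self.fractions[s] * n_cells for s in names])
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for i in np.argsort(-remainder)[: n_cells - counts.sum()]:
            counts[i] += 1
        return dict(zip(names, counts.tolist()))


def default_state_configs() -> dict[str, StateConfig]:
    """The three differentiation states the analysis distinguishes.

    a2 peaks are anchored to the reported behaviour of adipogenic MSC
    monolayers: undifferentiated cells peak near 19% bound NAD(P)H,
    differentiated cells above 30%, with the transitional state in between.
    Lipid droplet counts rise steeply with state; cell area grows and the
    spindle shape relaxes (eccentricity drops) as cells mature.
    """
    return {
        "undiff": StateConfig(
            "undiff",
            a2_peak_mean=0.19, a2_peak_sd=0.02,
            a2_width_mean=0.030, a2_width_sd=0.004,
            droplet_count_mean=2.0, droplet_intensity_mean=45000.0,
            cell_area_mean=2600.0, cell_area_sd=350.0,
            eccentricity_range=(0.85, 0.95),
        ),
        "differentiating": StateConfig(
            "differentiating",
            a2_peak_mean=0.26, a2_peak_sd=0.02,
            a2_width_mean=0.045, a2_width_sd=0.004,
            droplet_count_mean=12.0, droplet_intensity_mean=50000.0,
            cell_area_mean=3500.0, cell_area_sd=400.0,
            eccentricity_range=(0.70, 0.88),
        ),
        "diff": StateConfig(
            "diff",
            a2_peak_mean=0.34, a2_peak_sd=0.02,
            a2_width_mean=0.060, a2_width_sd=0.005,
            droplet_count_mean=30.0, droplet_intensity_mean=55000.0,
            cell_area_mean=4600.0, cell_area_sd=500.0,
            eccentricity_range=(0.45, 0.75),
        ),
    }


def default_mixtures() -> list[TimepointMixture]:
    """State mixtures drifting from mostly-undifferentiated (Day 1) to
    mostly-differentiated (Day 28) over a five-timepoint induction course."""
    table = {
        1: (0.80, 0.10, 0.10),
        7: (0.15, 0.55, 0.30),
        14: (0.08, 0.57, 0.35),
        21: (0.06, 0.48, 0.46),
        28: (0.02, 0.30, 0.68),
    }
    names = ("undiff", "differentiating", "diff")
    return [
        TimepointMixture(day, dict(zip(names, fracs)))
        for day, fracs in table.items()
    ]


@dataclass
class CellRecord:
    """Ground truth for one rendered cell (coordinates 0-based, row/col)."""

    cell_id: int
    state_name: str
    centroid: tuple[float, float]
    cell_polygon: np.ndarray  # (N, 2) row/col
    nucleus_polygon: np.ndarray  # (M, 2) row/col
    a2_peak: float
    a2_width: float
    mean_srs: float
    area_px: int


@dataclass
class GroundTruth:
    """Scene description for one synthetic field."""

    records: list[CellRecord] = dc_field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [r.cell_id for r in self.records],
                "state": [r.state_name for r in self.records],
                "centroid_row": [r.centroid[0] for r in self.records],
                "centroid_col": [r.centroid[1] for r in self.records],
                "a2_peak": [r.a2_peak for r in self.records],
                "a2_width": [r.a2_width for r in self.records],
                "mean_srs": [r.mean_srs for r in self.records],
                "area_px": [r.area_px for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        scene = [
            {
                "cell_id": r.cell_id,
                "state": r.state_name,
                "centroid": list(r.centroid),
                "cell_polygon": r.cell_polygon.tolist(),
                "nucleus_polygon": r.nucleus_polygon.tolist(),
                "a2_peak": r.a2_peak,
                "a2_width": r.a2_width,
                "mean_srs": r.mean_srs,
                "area_px": r.area_px,
            }
            for r in self.records
        ]
        Path(path).write_text(json.dumps(scene, sort_keys=True))


@dataclass
class ImageField:
    """One 2-D microscopy frame plus modality tag and optional ground truth."""

    pixels: np.ndarray
    modality: str
    ground_truth: GroundTruth | None = None

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.pixels)

    @classmethod
    def load(cls, path: str | Path, modality: str) -> "ImageField":
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return cls(pixels=tifffile.imread(path), modality=modality)


@dataclass(frozen=True)
class DecayCurve:
    """Time-binned photon counts of a fluorescence decay.

    ``time_bins`` are uniformly spaced bin centres in ns; ``counts`` are
    non-negative integer photon counts per bin.
    """

    time_bins: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.time_bins) < 16:
            raise ValueError("a decay needs at least 16 time bins")
        steps = np.diff(self.time_bins)
        if not np.allclose(steps, steps[0]):
            raise ValueError("time bins must be uniformly spaced")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_bins[1] - self.time_bins[0])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


# ----------------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------------


def _perturbed_ellipse(
    center: np.ndarray,
    area: float,
    eccentricity: float,
    orientation: float,
    rng: np.random.Generator,
    n_vertices: int = 96,
    perturb: float = BOUNDARY_PERTURB_AMP,
) -> np.ndarray:
    """Ellipse of given area/eccentricity with a sinusoidal boundary ripple."""
    axis_ratio = np.sqrt(1.0 - eccentricity**2)  # b / a
    a = np.sqrt(area / (np.pi * axis_ratio))
    b = a * axis_ratio
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    lobes = rng.integers(3, 7)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    radial = 1.0 + perturb * np.sin(lobes * theta + phase)
    x = a * radial * np.cos(theta)
    y = b * radial * np.sin(theta)
    cos_o, sin_o = np.cos(orientation), np.sin(orientation)
    rows = center[0] + sin_o * x + cos_o * y
    cols = center[1] + cos_o * x - sin_o * y
    return np.column_stack([rows, cols])


def _as_shapely(poly_rc: np.ndarray) -> ShapelyPolygon:
    """Row/col polygon -> shapely (x=col, y=row)."""
    return ShapelyPolygon(poly_rc[:, ::-1])


def _raster_mask(poly_rc: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return draw_polygon(poly_rc[:, 0], poly_rc[:, 1], shape=shape)


# ----------------------------------------------------------------------------
# field generation
# ----------------------------------------------------------------------------


def _place_cells(
    height: int,
    width: int,
    states: list[StateConfig],
    rng: np.random.Generator,
    allow_touching: bool,
    border_margin: int,
    max_retries: int,
) -> list[dict]:
    """Sample non-conflicting cell/nucleus geometry for every requested cell."""
    placed: list[dict] = []
    nuclei_shapes: list[ShapelyPolygon] = []
    cell_shapes: list[ShapelyPolygon] = []
    for cfg in states:
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise PlacementError(
                    f"could not place cell of state {cfg.state_name!r} after "
                    f"{max_retries} retries (field too crowded)"
                )
            area = max(400.0, rng.normal(cfg.cell_area_mean, cfg.cell_area_sd))
            ecc = rng.uniform(*cfg.eccentricity_range)
            orient = rng.uniform(0.0, np.pi)
            center = np.array(
                [
                    rng.uniform(border_margin, height - 1 - border_margin),
                    rng.uniform(border_margin, width - 1 - border_margin),
                ]
            )
            cell_poly = _perturbed_ellipse(center, area, ecc, orient, rng)
            if (
                cell_poly.min() < border_margin
                or cell_poly[:, 0].max() > height - 1 - border_margin
                or cell_poly[:, 1].max() > width - 1 - border_margin
            ):
                continue
            nuc_area = NUCLEUS_AREA_FRACTION * area
            nuc_center = center + rng.uniform(-2.0, 2.0, size=2)
            nuc_poly = _perturbed_ellipse(
                nuc_center,
                nuc_area,
                rng.uniform(0.2, 0.5),
                rng.uniform(0.0, np.pi),
                rng,
                perturb=0.03,
            )
            cell_shape = _as_shapely(cell_poly)
            nuc_shape = _as_shapely(nuc_poly)
            if not cell_shape.contains(nuc_shape):
                continue
            if any(nuc_shape.buffer(2.0).intersects(n) for n in nuclei_shapes):
                continue
            if not allow_touching and any(
                cell_shape.buffer(1.0).intersects(c) for c in cell_shapes
            ):
                continue
            nuclei_shapes.append(nuc_shape)
            cell_shapes.append(cell_shape)
            placed.append(
                {
                    "config": cfg,
                    "center": center,
                    "cell_polygon": cell_poly,
                    "nucleus_polygon": nuc_poly,
                }
            )
            break
    return placed


def _cell_body_and_rim(
    poly: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Raster of a cell split into interior body and a 1-px margin rim.

    The rim emulates the optically thin cell margin whose photon (or Raman)
    signal drops below the background threshold, so touching cells stay
    visually adjacent yet carry a faint seam.
    """
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _raster_mask(poly, shape)
    mask[rr, cc] = True
    body = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    rim = mask & ~body
    return body, rim


def _render_flim(
    shape: tuple[int, int], placed: list[dict], rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    img = np.zeros(shape, dtype=np.float32)
    # residual dim speckle where the photon count barely clears the
    # background threshold of the lifetime fitter
    speckle = rng.random(shape) < FLIM_SPECKLE_FRAC
    img[speckle] = rng.uniform(*FLIM_SPECKLE_RANGE, size=int(speckle.sum()))
    per_cell = []
    for item in placed:
        cfg: StateConfig = item["config"]
        peak = float(np.clip(rng.normal(cfg.a2_peak_mean, cfg.a2_peak_sd), 0.02, 0.98))
        width = float(max(0.005, rng.normal(cfg.a2_width_mean, cfg.a2_width_sd)))
        body, rim = _cell_body_and_rim(item["cell_polygon"], shape)
        img[body] = np.clip(rng.normal(peak, width, size=int(body.sum())), 0.0, 1.0)
        img[rim] = 0.0  # photon-starved margin -> flagged background
        # nucleus: no NAD(P)H signal -> renders like background
        nr, nc = _raster_mask(item["nucleus_polygon"], shape)
        img[nr, nc] = 0.0
        nspeck = rng.random(len(nr)) < FLIM_SPECKLE_FRAC
        img[nr[nspeck], nc[nspeck]] = rng.uniform(
            *FLIM_SPECKLE_RANGE, size=int(nspeck.sum())
        )
        per_cell.append({"a2_peak": peak, "a2_width": width, "mean_srs": float("nan")})
    return img, per_cell


def _render_srs(
    shape: tuple[int, int], placed: list[dict], rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    lam = np.full(shape, SRS_BACKGROUND_LAMBDA, dtype=np.float64)
    cell_masks = []
    for item in placed:
        body, _rim = _cell_body_and_rim(item["cell_polygon"], shape)
        lam[body] = SRS_CYTOPLASM_LAMBDA
        cell_masks.append(np.nonzero(body))
    # second pass so nuclei stay dark where cells touch
    for item in placed:
        nr, nc = _raster_mask(item["nucleus_polygon"], shape)
        lam[nr, nc] = SRS_BACKGROUND_LAMBDA
    for item in placed:
        cfg: StateConfig = item["config"]
        n_droplets = int(rng.poisson(cfg.droplet_count_mean))
        cell_shape = _as_shapely(item["cell_polygon"])
        nuc_shape = _as_shapely(item["nucleus_polygon"])
        dropped = 0
        guard = 0
        while dropped < n_droplets and guard < 50 * max(n_droplets, 1):
            guard += 1
            minx, miny, maxx, maxy = cell_shape.bounds
            px = rng.uniform(minx, maxx)
            py = rng.uniform(miny, maxy)
            p = Point(px, py)
            if not cell_shape.contains(p) or nuc_shape.buffer(2.0).contains(p):
                continue
            amp = cfg.droplet_intensity_mean * rng.uniform(0.85, 1.15)
            rr, cc = draw_disk((py, px), SRS_DROPLET_RADIUS_PX, shape=shape)
            lam[rr, cc] += amp
            dropped += 1
        item["_n_droplets"] = dropped
    img = np.minimum(rng.poisson(lam), SRS_MAX).astype(np.uint16)
    per_cell = []
    for item, (rr, cc) in zip(placed, cell_masks):
        per_cell.append(
            {
                "a2_peak": float("nan"),
                "a2_width": float("nan"),
                "mean_srs": float(img[rr, cc].mean()),
            }
        )
    return img, per_cell


def generate_field(
    width_px: int,
    height_px: int,
    n_cells: int,
    mixture: TimepointMixture,
    state_configs: dict[str, StateConfig] | None = None,
    modality: str = "FLIM_A2",
    seed: int = 0,
    *,
    allow_touching: bool = True,
    border_margin: int = 24,
    max_retries: int = 300,
) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its exact scene description.

    Cells are perturbed ellipses with state-dependent size, shape and signal;
    they may touch unless ``allow_touching=False``, but nuclei never overlap.
    Raises :class:`PlacementError` when geometry becomes infeasible after
    ``max_retries`` placement attempts per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    if state_configs is None:
        state_configs = default_state_configs()
    missing = set(mixture.fractions) - set(state_configs)
    if missing:
        raise ValueError(f"mixture references unknown states: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    counts = mixture.realized_counts(n_cells)
    state_list = [
        state_configs[name] for name in mixture.fractions for _ in range(counts[name])
    ]
    shape = (height_px, width_px)
    placed = _place_cells(
        height_px, width_px, state_list, rng, allow_touching, border_margin, max_retries
    )
    if modality == "FLIM_A2":
        img, per_cell = _render_flim(shape, placed, rng)
    else:
        img, per_cell = _render_srs(shape, placed, rng)

    records = []
    for i, (item, extra) in enumerate(zip(placed, per_cell)):
        poly = item["cell_polygon"]
        rr, cc = _raster_mask(poly, shape)
        records.append(
            CellRecord(
                cell_id=i,
                state_name=item["config"].state_name,
                centroid=(float(poly[:, 0].mean()), float(poly[:, 1].mean())),
                cell_polygon=poly,
                nucleus_polygon=item["nucleus_polygon"],
                a2_peak=extra["a2_peak"],
                a2_width=extra["a2_width"],
                mean_srs=extra["mean_srs"],
                area_px=int(len(rr)),
            )
        )
    gt = GroundTruth(records=records)
    return ImageField(pixels=img, modality=modality, ground_truth=gt), gt


# ----------------------------------------------------------------------------
# decay generation
# ----------------------------------------------------------------------------


def generate_decay(
    a1: float,
    tau1_ns: float,
    a2: float,
    tau2_ns: float,
    n_photons: int,
    n_bins: int = 256,
    t_max_ns: float = 10.0,
    seed: int = 0,
) -> DecayCurve:
    """Multinomial photon-arrival histogram of a bi-exponential decay.

    The per-bin probability is the integral of
    ``a1*exp(-t/tau1) + a2*exp(-t/tau2)`` over the bin, normalized over the
    measurement window ``[0, t_max_ns]``.
    """
    if abs(a1 + a2 - 1.0) > 1e-9:
        raise ValueError("a1 + a2 must equal 1")
    if tau1_ns <= 0 or tau2_ns <= 0:
        raise ValueError("lifetimes must be positive")
    if tau1_ns > tau2_ns:
        raise ValueError("tau1 must not exceed tau2")
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000")
    if n_bins < 16:
        raise ValueError("need at least 16 bins")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, t_max_ns, n_bins + 1)
    p = decay_bin_probabilities(a1, tau1_ns, a2, tau2_ns, edges)
    counts = rng.multinomial(n_photons, p)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DecayCurve(time_bins=centers, counts=counts)


def decay_bin_probabilities(
    a1: float, tau1_ns: float, a2: float, tau2_ns: float, edges: np.ndarray
) -> np.ndarray:
    """Exact bin probabilities of the truncated bi-exponential density."""
    def mass(tau: float) -> np.ndarray:
        return np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)

    raw = a1 * tau1_ns * mass(tau1_ns) + a2 * tau2_ns * mass(tau2_ns)
    return raw / raw.sum()


# ----------------------------------------------------------------------------
# direct feature sampling (no rendering)
# ----------------------------------------------------------------------------


def _ellipse_perimeter(area: float, eccentricity: float) -> float:
    """Ramanujan approximation, inflated slightly for the boundary ripple."""
    axis_ratio = np.sqrt(1.0 - eccentricity**2)
    a = np.sqrt(area / (np.pi * axis_ratio))
    b = a * axis_ratio
    h = ((a - b) / (a + b)) ** 2
    p = np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    return float(p * (1.0 + 2.0 * BOUNDARY_PERTURB_AMP**2))


def sample_feature_table(
    n_cells_per_day: int,
    mixtures: list[TimepointMixture] | None = None,
    state_configs: dict[str, StateConfig] | None = None,
    modality: str = "FLIM_A2",
    seed: int = 0,
    n_fields: int = 3,
) -> pd.DataFrame:
    """Per-cell feature table drawn directly from the generative model.

    This samples the same per-cell distributions that :func:`generate_field`
    renders, skipping rasterization; it is the fast route for exercising the
    clustering stages at realistic sample sizes.  Columns: ``day``, ``field``,
    ``state`` (ground truth) plus the modality's feature set.
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    if mixtures is None:
        mixtures = default_mixtures()
    if state_configs is None:
        state_configs = default_state_configs()
    rng = np.random.default_rng(seed)
    rows = []
    for mix in mixtures:
        counts = mix.realized_counts(n_cells_per_day)
        for name, n_state in counts.items():
            cfg = state_configs[name]
            for _ in range(n_state):
                area = max(400.0, rng.normal(cfg.cell_area_mean, cfg.cell_area_sd))
                row = {
                    "day": mix.day,
                    "field": int(rng.integers(0, n_fields)),
                    "state": name,
                    "area": area,
                }
                if modality == "FLIM_A2":
                    width = max(0.005, rng.normal(cfg.a2_width_mean, cfg.a2_width_sd))
                    row["a2_peak"] = float(
                        np.clip(rng.normal(cfg.a2_peak_mean, cfg.a2_peak_sd), 0.02, 0.98)
                    )
                    row["a2_fwhm"] = GAUSSIAN_FWHM_FACTOR * width
                else:
                    ecc = rng.uniform(*cfg.eccentricity_range)
                    perimeter = _ellipse_perimeter(area, ecc)
                    n_droplets = rng.poisson(cfg.droplet_count_mean)
                    droplet_px = np.pi * SRS_DROPLET_RADIUS_PX**2
                    mean_gray = (
                        SRS_CYTOPLASM_LAMBDA
                        + n_droplets
                        * droplet_px
                        * cfg.droplet_intensity_mean
                        * rng.uniform(0.85, 1.15)
                        / area
                    )
                    row["perimeter"] = perimeter
                    row["circularity"] = float(4.0 * np.pi * area / perimeter**2)
                    row["mean_gray"] = float(min(mean_gray, SRS_MAX))
                rows.append(row)
    return pd.DataFrame(rows)
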