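"""Bi-exponential fluorescence-decay fitting and lifetime quantities.

NAD(P)H autofluorescence decays as a mixture of a short free-NAD(P)H
component (lifetime tau1) and a long protein-bound component (tau2):

    I(t) = A * [ a1 * exp(-t/tau1) + a2 * exp(-t/tau2) ],   a1 + a2 = 1

The bound fraction a2 is the metabolic readout the downstream clustering
consumes, and the amplitude-weighted mean lifetime is

    tau_m = a1*tau1 + a2*tau2.

Fits are Poisson-weighted nonlinear least squares on binned photon counts,
parameterized as (amplitude, a2, tau1, tau2) with a1 = 1 - a2 enforced by
construction and tau1 <= tau2 enforced by box bounds covering the standard
NAD(P)H ranges.  No instrument-response deconvolution is performed: the
synthetic decays are ideal (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synth import DecayCurve, ImageField, decay_bin_probabilities

__all__ = [
    "BiExpFit",
    "FitFailureError",
    "fit_biexponential",
    "mean_lifetime",
    "build_a2_map",
    "read_decay_stack",
    "write_a2_map",
    "DEFAULT_TAU1_BOUNDS",
    "DEFAULT_TAU2_BOUNDS",
    "MIN_PHOTONS_PER_PIXEL",
]

#: standard free / bound NAD(P)H lifetime windows (ns)
DEFAULT_TAU1_BOUNDS = (0.1, 1.0)
DEFAULT_TAU2_BOUNDS = (1.0, 6.0)
#: pixels with fewer photons than this are treated as background
MIN_PHOTONS_PER_PIXEL = 100


class FitFailureError(RuntimeError):
    """Raised when a decay is too degenerate to fit."""


@dataclass(frozen=True)
class BiExpFit:
    """Result of one bi-exponential decay fit (lifetimes in ns)."""

    a1: float
    a2: float
    tau1_ns: float
    tau2_ns: float
    tau_m_ns: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a1 <= 1.0 and 0.0 <= self.a2 <= 1.0):
            raise ValueError("amplitude fractions must lie in [0, 1]")
        if abs(self.a1 + self.a2 - 1.0) > 1e-6:
            raise ValueError("a1 + a2 must equal 1")
        if not 0.0 < self.tau1_ns <= self.tau2_ns:
            raise ValueError("need 0 < tau1 <= tau2")
        if abs(self.tau_m_ns - (self.a1 * self.tau1_ns + self.a2 * self.tau2_ns)) > 1e-9:
            raise ValueError("tau_m inconsistent with a1*tau1 + a2*tau2")


def mean_lifetime(a1: float, tau1_ns: float, a2: float, tau2_ns: float) -> float:
    """Amplitude-weighted mean lifetime ``tau_m = a1*tau1 + a2*tau2`` (ns)."""
    if abs(a1 + a2 - 1.0) > 1e-6:
        raise ValueError("amplitude fractions must sum to 1")
    if tau1_ns <= 0 or tau2_ns <= 0:
        raise ValueError("lifetimes must be positive")
    return a1 * tau1_ns + a2 * tau2_ns


def _model_counts(
    amplitude: float, a2: float, tau1: float, tau2: float, edges: np.ndarray
) -> np.ndarray:
    p = decay_bin_probabilities(1.0 - a2, tau1, a2, tau2, edges)
    return amplitude * p


def fit_biexponential(
    decay: DecayCurve,
    init: tuple[float, float, float] | None = None,
    tau1_bounds: tuple[float, float] = DEFAULT_TAU1_BOUNDS,
    tau2_bounds: tuple[float, float] = DEFAULT_TAU2_BOUNDS,
    fixed_lifetimes: tuple[float, float] | None = None,
) -> BiExpFit:
    """Poisson-weighted least-squares fit of a bi-exponential decay.

    Parameters
    ----------
    decay
        Time-binned photon counts.
    init
        Optional (a2, tau1, tau2) starting point.  By default a2 is seeded
        from the empirical mean arrival time and the lifetimes from the
        centres of their bound windows.
    fixed_lifetimes
        When given, tau1/tau2 are held at these values and only the
        amplitude and a2 are fitted (global-lifetime mode).

    Raises
    ------
    FitFailureError
        If fewer than 4 bins are non-empty or all counts fall in one bin.
    """
    counts = np.asarray(decay.counts, dtype=float)
    nonempty = int(np.count_nonzero(counts))
    if nonempty < 4:
        raise FitFailureError(f"only {nonempty} non-empty bins; need >= 4")
    half = decay.bin_width_ns / 2.0
    edges = np.concatenate([decay.time_bins - half, [decay.time_bins[-1] + half]])
    total = counts.sum()
    weights = np.sqrt(np.maximum(counts, 1.0))

    if fixed_lifetimes is not None:
        tau1_0, tau2_0 = fixed_lifetimes
        if not 0.0 < tau1_0 <= tau2_0:
            raise ValueError("fixed lifetimes must satisfy 0 < tau1 <= tau2")
    else:
        tau1_0 = 0.5 * sum(tau1_bounds)
        tau2_0 = 0.5 * sum(tau2_bounds)

    if init is not None:
        a2_0, tau1_i, tau2_i = init
        if fixed_lifetimes is None:
            tau1_0, tau2_0 = tau1_i, tau2_i
    else:
        # moment seed: mean arrival ~ a1*tau1 + a2*tau2 for tau << window
        mean_t = float(np.dot(decay.time_bins, counts) / total)
        a2_0 = float(np.clip((mean_t - tau1_0) / max(tau2_0 - tau1_0, 1e-9), 0.05, 0.95))

    if fixed_lifetimes is not None:
        def residuals(x: np.ndarray) -> np.ndarray:
            amp, a2 = x
            return (_model_counts(amp, a2, tau1_0, tau2_0, edges) - counts) / weights

        x0 = np.array([total, a2_0])
        lb = np.array([1.0, 0.0])
        ub = np.array([np.inf, 1.0])
    else:
        def residuals(x: np.ndarray) -> np.ndarray:
            amp, a2, tau1, tau2 = x
            return (_model_counts(amp, a2, tau1, tau2, edges) - counts) / weights

        x0 = np.array([total, a2_0, tau1_0, tau2_0])
        lb = np.array([1.0, 0.0, tau1_bounds[0], tau2_bounds[0]])
        ub = np.array([np.inf, 1.0, tau1_bounds[1], tau2_bounds[1]])

    x0 = np.clip(x0, lb, np.minimum(ub, np.finfo(float).max))
    sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise FitFailureError(f"least-squares did not converge: {sol.message}")
    if fixed_lifetimes is not None:
        _, a2_hat = sol.x
        tau1_hat, tau2_hat = tau1_0, tau2_0
    else:
        _, a2_hat, tau1_hat, tau2_hat = sol.x
    if tau1_hat > tau2_hat:  # can only happen at the shared bound edge
        tau1_hat, tau2_hat = tau2_hat, tau1_hat
        a2_hat = 1.0 - a2_hat
    a1_hat = 1.0 - a2_hat
    return BiExpFit(
        a1=float(a1_hat),
        a2=float(a2_hat),
        tau1_ns=float(tau1_hat),
        tau2_ns=float(tau2_hat),
        tau_m_ns=float(a1_hat * tau1_hat + a2_hat * tau2_hat),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def build_a2_map(
    decays: np.ndarray | ImageField,
    time_bins: np.ndarray | None = None,
    min_photons: int = MIN_PHOTONS_PER_PIXEL,
    mode: str = "per_pixel",
) -> tuple[ImageField, np.ndarray]:
    """Per-pixel a2 map from a decay stack, or passthrough of an a2 image.

    Parameters
    ----------
    decays
        Either a 3-D ``(t, y, x)`` stack of binned photon counts (requires
        ``time_bins``) or an existing ``FLIM_A2`` :class:`ImageField`, which
        is passed through unchanged.
    mode
        ``"per_pixel"`` fits tau1/tau2 independently at every pixel;
        ``"global"`` fits the lifetimes once on the pooled field decay and
        then fits only a2 per pixel.

    Returns
    -------
    (field, background)
        ``field`` is a ``FLIM_A2`` image with a2 in [0, 1] (0 at background
        pixels); ``background`` is the boolean mask of pixels below the
        minimum-photon threshold.
    """
    if isinstance(decays, ImageField):
        if decays.modality != "FLIM_A2":
            raise ValueError("passthrough requires a FLIM_A2 field")
        pix = decays.pixels
        if pix.min() < 0.0 or pix.max() > 1.0:
            raise ValueError("a2 values must lie in [0, 1]")
        return decays, np.zeros(pix.shape, dtype=bool)

    stack = np.asarray(decays)
    if stack.ndim != 3:
        raise ValueError("decay stack must be 3-D (t, y, x)")
    if time_bins is None:
        raise ValueError("time_bins required for a decay stack")
    time_bins = np.asarray(time_bins, dtype=float)
    if len(time_bins) != stack.shape[0]:
        raise ValueError("time_bins length must match the stack's first axis")
    if mode not in ("per_pixel", "global"):
        raise ValueError("mode must be 'per_pixel' or 'global'")

    fixed = None
    if mode == "global":
        pooled = DecayCurve(time_bins=time_bins, counts=stack.sum(axis=(1, 2)))
        pooled_fit = fit_biexponential(pooled)
        fixed = (pooled_fit.tau1_ns, pooled_fit.tau2_ns)

    _, ny, nx = stack.shape
    a2_map = np.zeros((ny, nx), dtype=np.float32)
    background = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            counts = stack[:, iy, ix]
            if counts.sum() < min_photons:
                background[iy, ix] = True
                continue
            fit = fit_biexponential(
                DecayCurve(time_bins=time_bins, counts=counts),
                fixed_lifetimes=fixed,
            )
            a2_map[iy, ix] = fit.a2
    return ImageField(pixels=a2_map, modality="FLIM_A2"), background


def read_decay_stack(path) -> np.ndarray:
    """Read a 3-D (t, y, x) decay stack from TIFF."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3-D (t, y, x) stack, got shape {stack.shape}")
    return stack


def write_a2_map(field: ImageField, path, settings: dict | None = None) -> None:
    """Write an a2 map as TIFF plus a JSON sidecar with the fit settings."""
    import json
    from pathlib import Path

    if field.modality != "FLIM_A2":
        raise ValueError("write_a2_map expects a FLIM_A2 field")
    path = Path(path)
    field.save(path)
    sidecar = {"modality": field.modality, "settings": settings or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
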