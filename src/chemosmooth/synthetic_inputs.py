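"""Generators for every input the pipeline consumes.

The printed inocula of the experiments are emulated as a Gaussian ridge of
packed cells (FWHM 100 um, peak 0.95 cells/um^3) whose centerline position
oscillates sinusoidally along y with wavelength ``lambda_`` and amplitude
``A0``; the nutrient starts uniform (10 mM by default).  In addition this
module produces synthetic undulation-amplitude time series and
fluorescence-like image stacks so the analysis stages can be exercised in
isolation, with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams
from .numerics import FieldState, Grid

__all__ = [
    "InoculumSpec",
    "make_undulated_inoculum",
    "make_uniform_nutrient",
    "make_initial_state",
    "synth_amplitude_series",
    "render_image_stack",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Undulation wavelengths (um) used by the simulation sweep; 3.4 mm mirrors
#: the longest experimentally printed wavelength.
SWEEP_WAVELENGTHS = (800.0, 2000.0, 3200.0)
EXPERIMENT_LONG_WAVELENGTH = 3400.0


@dataclass(frozen=True)
class InoculumSpec:
    """Geometry of a printed inoculum ridge.

    ``x_center`` is the mean centerline position; with the default
    ``valley_at_0`` phase the centerline is ``x0(y) = x_center -
    A0*cos(2*pi*y/lambda_)``, so the undulation spans ``x_center +/- A0``
    (the extracted edge amplitude equals ``A0``), with valleys on the
    y boundaries and the peak at ``y = lambda_/2``.
    """

    lambda_: float
    A0: float
    x_center: float
    fwhm: float = 100.0
    b_peak: float = 0.95
    phase: str = "valley_at_0"

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValueError("A0 must be nonnegative")
        if self.fwhm <= 0 or self.lambda_ <= 0 or self.b_peak <= 0:
            raise ValueError("fwhm, lambda_ and b_peak must be positive")
        if self.phase not in ("valley_at_0", "peak_at_0"):
            raise ValueError("phase must be 'valley_at_0' or 'peak_at_0'")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    def centerline(self, y: np.ndarray) -> np.ndarray:
        """Centerline position x0(y) in um."""
        osc = np.cos(2.0 * np.pi * np.asarray(y) / self.lambda_)
        sign = -1.0 if self.phase == "valley_at_0" else 1.0
        return self.x_center + sign * self.A0 * osc


def make_undulated_inoculum(spec: InoculumSpec, grid: Grid) -> np.ndarray:
    """Cell-density field of a printed undulated ridge on ``grid``.

    ``b(x, y) = b_peak * exp(-(x - x0(y))^2 / (2 sigma^2))``; ``A0 = 0``
    yields a flat ridge (used for chi calibration).  Raises if the ridge
    (centerline excursion plus three Gaussian widths) does not fit in x.
    """
    margin = 3.0 * spec.fwhm
    if spec.x_center - spec.A0 - margin < 0 or spec.x_center + spec.A0 + margin > grid.Lx:
        raise ValueError("inoculum does not fit inside the grid in x")
    if abs(grid.Ly - spec.lambda_) > 1e-9 * spec.lambda_:
        raise ValueError(
            f"grid Ly={grid.Ly} must equal one undulation wavelength {spec.lambda_}")
    x0 = spec.centerline(grid.y)[None, :]
    x = grid.x[:, None]
    return spec.b_peak * np.exp(-((x - x0) ** 2) / (2.0 * spec.sigma**2))


def make_uniform_nutrient(c0: float, grid: Grid) -> np.ndarray:
    """Uniform nutrient field at concentration ``c0`` (uM)."""
    if c0 < 0:
        raise ValueError("c0 must be nonnegative")
    return np.full(grid.shape, float(c0))


def make_initial_state(spec: InoculumSpec, grid: Grid,
                       params: ModelParams) -> FieldState:
    """Initial condition: undulated inoculum plus uniform nutrient at params.c0."""
    return FieldState(0.0, make_undulated_inoculum(spec, grid),
                      make_uniform_nutrient(params.c0, grid))


def synth_amplitude_series(A0: float, tau: float, t0: float, duration: float,
                           sampling: float, noise_sd: float = 0.0,
                           seed: int | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic undulation-amplitude trace with known decay constants.

    ``A(t) = A0`` for ``t < t0`` and ``A0*exp(-(t-t0)/tau)`` after, with
    optional seeded Gaussian noise of standard deviation ``noise_sd``.
    ``tau = inf`` encodes a non-smoothing (flat) trace.  All units as
    given (the analysis stages are unit-agnostic as long as t and tau
    match).  Bit-reproducible for a fixed seed.
    """
    if sampling <= 0 or duration <= 0:
        raise ValueError("sampling and duration must be positive")
    if not (tau > 0):
        raise ValueError("tau must be positive (may be inf)")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required for a noisy series")
    t = np.arange(0.0, duration + 0.5 * sampling, sampling)
    A = np.where(t < t0, A0, A0 * np.exp(-np.maximum(t - t0, 0.0) / tau))
    if noise_sd > 0:
        A = A + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return t, A


def render_image_stack(snapshots, signal_floor: float = 1e-6,
                       b_max: float | None = None,
                       path=None) -> np.ndarray:
    """Map cell-density (or starvation-signal) snapshots to a log-scaled
    16-bit grayscale stack, emulating maximum-intensity fluorescence
    projections displayed on a log scale.

    Intensity transform (documented, invertible up to quantization):
    ``I = round(65535 * (log10(max(b, floor)) - log10(floor)) /
    (log10(b_max) - log10(floor)))`` with ``floor = signal_floor`` and
    ``b_max`` the stack-wide maximum by default.  Returns the (n, ny, nx)
    array; if ``path`` is given, also writes a multi-page TIFF.
    """
    snaps = [np.asarray(s, dtype=float) for s in snapshots]
    if not snaps:
        raise ValueError("empty snapshot list")
    if b_max is None:
        b_max = max(float(s.max()) for s in snaps)
    if b_max <= signal_floor:
        raise ValueError("b_max must exceed signal_floor")
    lo = math.log10(signal_floor)
    hi = math.log10(b_max)
    frames = []
    for s in snaps:
        z = (np.log10(np.maximum(s, signal_floor)) - lo) / (hi - lo)
        # transpose so the image rows are y and columns are x
        frames.append(np.round(np.clip(z, 0.0, 1.0) * 65535).astype(np.uint16).T)
    stack = np.stack(frames)
    if path is not None:
        import tifffile

        tifffile.imwrite(path, stack, photometric="minisblack")
    return stack


def invert_image_stack(stack: np.ndarray, signal_floor: float,
                       b_max: float) -> np.ndarray:
    """Inverse of the :func:`render_image_stack` transform (up to
    quantization and the floor)."""
    lo = math.log10(signal_floor)
    hi = math.log10(b_max)
    z = stack.astype(float) / 65535.0
    out = 10 ** (lo + z * (hi - lo))
    return np.transpose(out, (0, 2, 1))
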