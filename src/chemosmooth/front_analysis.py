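"""Leading-edge extraction and smoothing-time analysis.

The leading edge of a migrating front is the locus where the cell density
falls below a threshold while scanning inward from the +x boundary.  From
the per-row edge positions we obtain the undulation amplitude ``A`` (half
the peak-to-valley excursion) and the front position ``Rf``; the decay of
``A(t)`` after smoothing initiates at ``t0`` is fitted with
``A = A0 * exp(-(t - t0)/tau)`` to obtain the smoothing time ``tau``.

``t0`` itself is found as the earliest time at which the error of the
exponential fit is (nearly) minimal: the fit RMSE generically has a flat
basin in ``t0``, so "earliest minimal" is operationalized as the earliest
candidate whose RMSE is within a small tolerance (default 5%) of the
global minimum, and the extent of that basin is reported as the ``t0``
uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import ModelParams
from .numerics import Grid

__all__ = [
    "EdgeProfile",
    "FrontTrace",
    "SmoothingFit",
    "extract_leading_edge",
    "amplitude_and_position",
    "fit_smoothing_time",
    "depletion_times",
    "apply_starvation_signal",
]

#: Default edge threshold for migration traces, as a fraction of the
#: maximum initial cell density.
MIGRATION_THRESHOLD_FRACTION = 1e-4

#: Edge thresholds (cells/um^3) used for the velocity-decomposition
#: analysis, specific to each (pore size, wavelength) condition.
DECOMPOSITION_THRESHOLDS = {
    (1.7, 800.0): 0.003,
    (2.2, None): 0.003,   # all wavelengths in the loosest medium
    (1.7, 2000.0): 0.002,
    (1.7, 3200.0): 0.002,
    (1.2, 800.0): 0.001,
}


def decomposition_threshold(xi: float, lambda_: float) -> float:
    """Per-condition edge threshold for the decomposition analysis."""
    key = (float(xi), float(lambda_))
    if key in DECOMPOSITION_THRESHOLDS:
        return DECOMPOSITION_THRESHOLDS[key]
    if (float(xi), None) in DECOMPOSITION_THRESHOLDS:
        return DECOMPOSITION_THRESHOLDS[(float(xi), None)]
    return 0.003


@dataclass
class EdgeProfile:
    """Leading-edge x-position per y-row at one time.

    Rows whose density never reaches the threshold hold NaN and are
    reported by :attr:`invalid_rows` rather than silently filled.
    """

    t: float
    x_edge: np.ndarray          # um, length ny, NaN where no crossing
    threshold_used: float       # cells/um^3

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.x_edge)

    @property
    def invalid_rows(self) -> np.ndarray:
        return np.flatnonzero(~self.valid)

    @property
    def has_front(self) -> bool:
        return bool(self.valid.all())


@dataclass
class SmoothingFit:
    """Result of the exponential amplitude-decay fit."""

    t0: float                  # s, smoothing initiation time
    A0: float                  # um, amplitude at t0
    tau: float                 # s, smoothing time constant
    rmse: float                # um, fit residual RMSE over t >= t0
    t0_range: tuple[float, float]  # s, basin of near-minimal-RMSE t0 values
    n_points: int              # points entering the selected fit
    smoothing: bool = True     # False for a structured non-smoothing result

    @property
    def t0_uncertainty(self) -> float:
        return self.t0_range[1] - self.t0_range[0]


@dataclass
class FrontTrace:
    """Time series of undulation amplitude and front position, with fit."""

    times: np.ndarray          # s
    A: np.ndarray              # um
    Rf: np.ndarray             # um, measured from the inoculum centerline
    fit: SmoothingFit | None = None


def extract_leading_edge(b: np.ndarray, threshold: float, grid: Grid,
                         t: float = 0.0) -> EdgeProfile:
    """Locate the +x leading edge of the density field at ``threshold``.

    Each y-row is scanned inward from the +x boundary to the first node
    with ``b >= threshold``; the sub-grid crossing position is linearly
    interpolated between that node and its outward neighbor.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    b = np.asarray(b, dtype=float)
    if b.shape != grid.shape:
        raise ValueError("snapshot shape does not match grid")
    nx, ny = b.shape
    x_edge = np.full(ny, np.nan)
    # vectorized: index of last node >= threshold per row
    above = b >= threshold
    any_above = above.any(axis=0)
    last = nx - 1 - np.argmax(above[::-1, :], axis=0)
    for j in np.flatnonzero(any_above):
        i = last[j]
        if i == nx - 1:
            x_edge[j] = grid.x[i]
        else:
            hi, lo = b[i, j], b[i + 1, j]
            x_edge[j] = grid.x[i] + grid.dx * (hi - threshold) / (hi - lo)
    return EdgeProfile(t=t, x_edge=x_edge, threshold_used=threshold)


def amplitude_and_position(edge: EdgeProfile, x_center: float = 0.0,
                           ) -> tuple[float, float]:
    """Undulation amplitude and front position of one edge profile.

    ``A`` is half the peak-to-valley excursion of the edge; ``Rf`` is the
    leading-most edge position measured from the inoculum centerline
    ``x_center``.
    """
    xe = edge.x_edge[edge.valid]
    if xe.size < 2:
        raise ValueError("edge profile has fewer than 2 valid rows")
    return float((xe.max() - xe.min()) / 2.0), float(xe.max() - x_center)


def _fit_tau_fixed_t0(dt_: np.ndarray, A: np.ndarray, A0: float,
                      tau_max: float) -> tuple[float, float]:
    """Least-squares tau for A0*exp(-dt/tau); returns (tau, rmse)."""

    def cost(log_tau: float) -> float:
        r = A0 * np.exp(-dt_ / math.exp(log_tau)) - A
        return float(r @ r)

    span = max(dt_[-1], dt_[1] - dt_[0])
    res = minimize_scalar(cost, bounds=(math.log(span * 1e-3), math.log(tau_max)),
                          method="bounded", options={"xatol": 1e-10})
    tau = math.exp(res.x)
    rmse = math.sqrt(res.fun / dt_.size)
    return tau, rmse


def fit_smoothing_time(times: Sequence[float], A: Sequence[float], *,
                       rmse_tol: float = 0.05, min_points_after: int = 4,
                       flat_tau_factor: float = 20.0,
                       amp_floor_frac: float = 0.04,
                       t0_amp_frac: float = 0.3) -> SmoothingFit:
    """Fit the exponential smoothing law to an amplitude trace.

    For every candidate ``t0`` on the sampling grid, ``A0`` is pinned to
    ``A(t0)`` and ``tau`` is fitted by least squares to the points with
    ``t >= t0``.  The reported ``t0`` is the earliest candidate whose RMSE
    lies within ``rmse_tol`` of the global minimum; the basin of such
    candidates gives the ``t0`` uncertainty.

    Two guards keep the search on the physically meaningful part of the
    trace: samples below ``amp_floor_frac`` of the amplitude maximum are
    excluded (on simulated traces sub-grid amplitudes are resolution
    noise), and ``t0`` candidates are required to retain at least
    ``t0_amp_frac`` of the maximum (smoothing *initiation* means the
    amplitude is still near ``A0``; without this the RMSE minimum can
    drift into the low-amplitude tail, where residuals are trivially
    small).

    A structured non-smoothing result (``smoothing=False``, ``tau=inf``) is
    returned when the trace never decays: amplitude non-decreasing
    throughout, or best-fit ``tau`` beyond ``flat_tau_factor`` times the
    fitted window (indistinguishable from flat).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(A, dtype=float)
    keep = np.isfinite(t) & np.isfinite(a)
    t, a = t[keep], a[keep]
    if t.size < 6:
        raise ValueError("need at least 6 amplitude samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    scale = float(np.max(np.abs(a)))
    if scale <= 0 or np.all(np.diff(a) >= -1e-9 * scale):
        return SmoothingFit(t0=float(t[0]), A0=float(a[0]), tau=math.inf,
                            rmse=math.nan, t0_range=(float(t[0]), float(t[-1])),
                            n_points=t.size, smoothing=False)

    keep = a >= amp_floor_frac * scale
    # never drop leading samples (pre-decay plateau) -- only the tail
    first_low = np.argmin(keep) if not keep.all() else keep.size
    t, a = t[:max(first_low, 6)], a[:max(first_low, 6)]
    if t.size < 6:
        raise ValueError("fewer than 6 samples above the amplitude floor")

    window = t[-1] - t[0]
    tau_max = flat_tau_factor * window * 10.0
    candidates = []
    for k in range(t.size - min_points_after):
        A0 = a[k]
        if A0 < t0_amp_frac * scale:
            continue
        dt_ = t[k:] - t[k]
        tau, rmse = _fit_tau_fixed_t0(dt_, a[k:], A0, tau_max)
        candidates.append((t[k], A0, tau, rmse, t.size - k))
    if not candidates:
        raise ValueError("no valid t0 candidate above the amplitude guard")

    rmses = np.array([c[3] for c in candidates])
    tol = rmses.min() * (1.0 + rmse_tol) + 1e-6 * scale
    in_basin = [c for c, r in zip(candidates, rmses) if r <= tol]
    t0, A0, tau, rmse, n_pts = in_basin[0]
    t0_range = (in_basin[0][0], in_basin[-1][0])
    if not (tau < flat_tau_factor * (t[-1] - t0 + 1e-300)):
        return SmoothingFit(t0=float(t0), A0=float(A0), tau=math.inf,
                            rmse=float(rmse), t0_range=t0_range,
                            n_points=int(n_pts), smoothing=False)
    return SmoothingFit(t0=float(t0), A0=float(A0), tau=float(tau),
                        rmse=float(rmse), t0_range=t0_range,
                        n_points=int(n_pts), smoothing=True)


def trace_from_snapshots(times, b_snapshots, grid: Grid, threshold: float,
                         x_center: float, fit: bool = True) -> FrontTrace:
    """Build a :class:`FrontTrace` (with optional tau fit) from snapshots.

    Snapshots where no row reaches the threshold yield NaN amplitude (no
    front yet / no front at all); these are excluded from the fit.
    """
    A = np.full(len(b_snapshots), np.nan)
    Rf = np.full(len(b_snapshots), np.nan)
    for k, b in enumerate(b_snapshots):
        edge = extract_leading_edge(np.asarray(b, dtype=float), threshold, grid,
                                    t=float(times[k]))
        if edge.valid.sum() >= 2:
            A[k], Rf[k] = amplitude_and_position(edge, x_center)
    trace = FrontTrace(times=np.asarray(times, dtype=float), A=A, Rf=Rf)
    if fit and np.isfinite(A).sum() >= 6:
        trace.fit = fit_smoothing_time(trace.times[np.isfinite(A)],
                                       A[np.isfinite(A)])
    return trace


# ---------------------------------------------------------------------------
# starvation / fluorescence-signal model
# ---------------------------------------------------------------------------

def depletion_times(times, c_snapshots, c_star: float) -> np.ndarray:
    """First time each node's nutrient drops below ``c_star``.

    Computed from snapshot history (the integrator also records this
    per time step; use that when available).  Returns -1 for nodes never
    depleted.
    """
    tprime = np.full(np.asarray(c_snapshots[0]).shape, -1.0)
    for t, c in zip(times, c_snapshots):
        mask = (tprime < 0) & (np.asarray(c) < c_star)
        tprime[mask] = t
    return tprime


def apply_starvation_signal(times, b_snapshots, tprime: np.ndarray,
                            params: ModelParams) -> list[np.ndarray]:
    """Convert cell density to the fluorescence-like cellular signal.

    Wherever the nutrient first fell below the threshold at time ``t'``,
    the signal at times ``t > t' + tau_delay`` is ``b * exp(-(t - t')/
    tau_starve)`` (note the decay clock starts at depletion, not at the end
    of the delay, so the signal drops discontinuously when the delay
    elapses); elsewhere the signal equals ``b``.
    """
    times = np.asarray(times, dtype=float)
    if len(times) != len(b_snapshots):
        raise ValueError("times and snapshots are misaligned")
    out = []
    depleted = tprime >= 0
    for t, b in zip(times, b_snapshots):
        b = np.asarray(b, dtype=float)
        if b.shape != tprime.shape:
            raise ValueError("snapshot and tprime shapes differ")
        factor = np.ones_like(b)
        active = depleted & (t > tprime + params.tau_delay)
        factor[active] = np.exp(-(t - tprime[active]) / params.tau_starve)
        out.append(b * factor)
    return out
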