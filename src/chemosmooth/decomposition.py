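"""Decomposition of the chemotactic velocity along the leading edge.

The chemotactic drift can be written as a response to a driving force,

    v_c = chi * f'(c) * grad(c),

with the nutrient gradient as the forcing and ``chi f'(c)`` as the
response function.  Along an undulated leading edge the forcing is larger
at convex peaks (nutrient contours bunch there), which would amplify the
undulation -- but the response is smaller at peaks because the higher
nutrient saturates the receptors.  With saturating (logarithmic) sensing
the response wins: valleys outrun peaks and the front smooths.  This
module evaluates both factors and their product at the extracted edge,
their valley-minus-peak gap ``dv = v_cx(valley) - v_cx(peak)``, and the
catch-up time ``tau'`` at which the integrated gap equals the initial
amplitude ``A0``.

The motility correction is unity at the edge (the edge threshold sits far
below crowding densities), so ``chi`` enters at its uncorrected preset
value; this is asserted rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .front_analysis import EdgeProfile
from .model_core import (
    ModelParams,
    PorousMediumParams,
    motility_correction,
    sensing_fprime,
)
from .numerics import Grid

__all__ = [
    "DecompositionProfile",
    "decompose_at_edge",
    "velocity_gap",
    "catch_up_time",
    "nutrient_contours",
    "contour_spacing_at_rows",
]


@dataclass
class DecompositionProfile:
    """Forcing, response and chemotactic velocity along one edge profile."""

    t: float
    y: np.ndarray             # valid row positions, um
    x_edge: np.ndarray        # matching edge positions, um
    c_edge: np.ndarray        # nutrient at the edge, uM
    dcdx_edge: np.ndarray     # forcing: d(c)/dx at the edge, uM/um
    fprime_edge: np.ndarray   # response function f'(c), 1/uM
    vcx_edge: np.ndarray      # chi * f' * dc/dx with the constant chi, um/s
    correction_edge: np.ndarray  # crowding correction at the edge
    j_peak: int               # index (into the valid arrays) of the peak row
    j_valley: int             # index of the valley row

    @property
    def vcx_cell_edge(self) -> np.ndarray:
        """Drift velocity of the cells at the edge: the crowding
        correction multiplies chi exactly as it does in the transport
        equation.  This is the velocity whose valley-peak gap integrates
        to the actual amplitude decay."""
        return self.correction_edge * self.vcx_edge

    @property
    def flat(self) -> bool:
        return self.j_peak == self.j_valley


def _interp_along_x(field: np.ndarray, x: np.ndarray, xq: float, j: int) -> float:
    """Linear interpolation of a node field along x within row j."""
    return float(np.interp(xq, x, field[:, j]))


def decompose_at_edge(b: np.ndarray, c: np.ndarray, edge: EdgeProfile,
                      grid: Grid, params: ModelParams,
                      medium: PorousMediumParams,
                      require_dilute: bool = False) -> DecompositionProfile:
    """Evaluate the velocity decomposition at each valid edge row.

    The node-centered central-difference gradient of ``c`` and ``c``
    itself are linearly interpolated to the off-node edge positions; rows
    without a valid edge are omitted (their indices remain available on
    the ``edge``).

    ``v_cx`` uses the uncorrected per-medium ``chi`` (the definition of
    the chemotactic velocity).  The crowding correction at each edge point
    is recorded for inspection: it is exactly 1 for the low migration
    threshold, but the condition-specific decomposition thresholds sit
    slightly above the crowding onset, where the correction is < 1 for
    both peaks and valleys alike.  Pass ``require_dilute=True`` to demand
    a strictly dilute edge (raises otherwise).
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if b.shape != grid.shape or c.shape != grid.shape:
        raise ValueError("snapshot shapes do not match grid")
    valid = np.flatnonzero(edge.valid)
    if valid.size < 2:
        raise ValueError("edge has fewer than 2 valid rows")
    dcdx = np.gradient(c, grid.dx, axis=0)  # central differences, one-sided at walls
    x = grid.x
    ys, xs, cs, gs, fps, vs, corrs = [], [], [], [], [], [], []
    for j in valid:
        xq = edge.x_edge[j]
        c_e = _interp_along_x(c, x, xq, j)
        g_e = _interp_along_x(dcdx, x, xq, j)
        b_e = _interp_along_x(b, x, xq, j)
        corr = float(motility_correction(b_e, medium, params))
        if require_dilute and corr < 1.0 - 1e-9:
            raise ValueError(
                f"motility correction {corr:.4f} != 1 at edge row {j}: "
                "edge threshold too high for a strictly dilute edge")
        fp_e = float(sensing_fprime(max(c_e, 0.0), params))
        ys.append(grid.y[j]); xs.append(xq); cs.append(c_e)
        gs.append(g_e); fps.append(fp_e); corrs.append(corr)
        vs.append(medium.chi0 * fp_e * g_e)
    xs = np.asarray(xs)
    return DecompositionProfile(
        t=edge.t, y=np.asarray(ys), x_edge=xs, c_edge=np.asarray(cs),
        dcdx_edge=np.asarray(gs), fprime_edge=np.asarray(fps),
        vcx_edge=np.asarray(vs), correction_edge=np.asarray(corrs),
        j_peak=int(np.argmax(xs)), j_valley=int(np.argmin(xs)))


def velocity_gap(profile: DecompositionProfile, cell: bool = False) -> float:
    """Valley-minus-peak gap of the x chemotactic velocity, um/s.

    Positive values mean valleys outrun peaks (smoothing); a degenerate
    flat edge returns exactly 0 (``profile.flat`` is set).  With
    ``cell=True`` the gap is taken on the crowding-corrected cell
    velocity -- the variant whose time integral is commensurate with the
    measured amplitude decay and therefore the one used for the catch-up
    time.  The sign is the same for both variants.
    """
    if profile.flat:
        return 0.0
    v = profile.vcx_cell_edge if cell else profile.vcx_edge
    return float(v[profile.j_valley] - v[profile.j_peak])


def catch_up_time(dts: np.ndarray, gaps: np.ndarray, A0: float,
                  ) -> tuple[float, float]:
    """Time tau' for valleys to catch up to peaks.

    Trapezoidal cumulative integral of the velocity gap over time elapsed
    since smoothing initiation; tau' is the (interpolated) first time the
    integral reaches ``A0``.  Returns ``(tau_prime, integral_end)`` with
    ``tau_prime = inf`` if the distance ``A0`` is never covered.
    """
    dts = np.asarray(dts, dtype=float)
    gaps = np.asarray(gaps, dtype=float)
    if dts.size == 0:
        raise ValueError("empty gap series")
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if abs(dts[0]) > 1e-9:
        raise ValueError("gap series must start at elapsed time 0")
    integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (gaps[1:] + gaps[:-1]) * np.diff(dts))))
    reached = np.flatnonzero(integral >= A0)
    if reached.size == 0:
        return math.inf, float(integral[-1])
    k = reached[0]
    if k == 0:
        return float(dts[0]), float(integral[-1])
    frac = (A0 - integral[k - 1]) / (integral[k] - integral[k - 1])
    return float(dts[k - 1] + frac * (dts[k] - dts[k - 1])), float(integral[-1])


def nutrient_contours(c: np.ndarray, levels, grid: Grid) -> dict[float, list]:
    """Iso-concentration contours (marching squares) in physical units.

    Returns, per level, a list of (n, 2) arrays of (x, y) polyline
    vertices in um.  Levels outside the field range yield an empty list
    for that level.
    """
    from skimage import measure

    c = np.asarray(c, dtype=float)
    if c.shape != grid.shape:
        raise ValueError("snapshot shape does not match grid")
    out: dict[float, list] = {}
    for level in np.atleast_1d(levels):
        level = float(level)
        if not (c.min() < level < c.max()):
            out[level] = []
            continue
        segs = measure.find_contours(c, level)
        out[level] = [seg * grid.dx for seg in segs]  # rows are (x, y) indices
    return out


def contour_spacing_at_rows(c: np.ndarray, grid: Grid, params: ModelParams,
                            rows) -> dict[int, float]:
    """x-distance between the outermost c_minus and c_plus crossings per row.

    The spacing between the two sensing-limit contours measures the local
    steepness of the nutrient profile at the leading edge: smaller spacing
    means stronger forcing.  Rows where either level is not crossed map
    to NaN.
    """
    c = np.asarray(c, dtype=float)
    out: dict[int, float] = {}
    for j in rows:
        col = c[:, j]
        xm = _outermost_crossing(col, grid.x, params.c_minus)
        xp = _outermost_crossing(col, grid.x, params.c_plus)
        out[j] = (xp - xm) if (np.isfinite(xm) and np.isfinite(xp)) else np.nan
    return out


def _outermost_crossing(col: np.ndarray, x: np.ndarray, level: float) -> float:
    below = col < level
    if not below.any() or below.all():
        return math.nan
    i = int(np.flatnonzero(below)[-1])  # outermost upward crossing
    if i == col.size - 1:
        return math.nan
    lo, hi = col[i], col[i + 1]
    return float(x[i] + (level - lo) / (hi - lo) * (x[i + 1] - x[i]))
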