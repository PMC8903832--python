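"""Finite-difference operators and the multistep time integrator.

The PDE system is solved on a node-centered rectangular grid spanning
``x in [0, Lx]`` and one undulation wavelength ``y in [0, Ly]``, with
zero-flux boundaries on all four walls.  Spatial derivatives use central
differences; the bacterial flux is discretized in conservative face-flux
form so that, with proliferation switched off, total cell number is
conserved to round-off.

Time integration is an Adams-Bashforth-Moulton predictor-corrector
(order-3 predictor, trapezoidal corrector) started with two classical
RK4 steps.  The production path runs through the numba kernels in
:mod:`chemosmooth._kernels`; the NumPy implementations here are the
readable reference and are cross-checked against the kernels in the
test suite.

Negative undershoots of either field are projected to zero.  For the
nutrient this happens by design: consumption at packed cell density is
fast compared to any explicit time step, so depleted nodes chatter about
zero at the magnitude of one step's diffusive resupply, and projection
yields the correct diffusion-limited consumption.  For the cell density
the projected amount is accounted and the run aborts if a single node
undershoots beyond ``IntegratorConfig.b_negative_tol``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .model_core import (
    ModelParams,
    PorousMediumParams,
    motility_correction,
    reaction_terms,
    sensing_f,
)

__all__ = [
    "Grid",
    "FieldState",
    "IntegratorConfig",
    "SimulationResult",
    "laplacian",
    "flux_divergence",
    "rhs",
    "field_total",
    "start_history",
    "abm_step",
    "integrate",
    "ode_integrate",
]


class NumericsError(RuntimeError):
    """Raised when the integrator detects instability or invalid state."""


def _count_nodes(extent: float, dx: float, name: str) -> int:
    n = extent / dx
    if abs(n - round(n)) > 1e-8:
        raise ValueError(f"{name}={extent} must be an integer multiple of dx={dx}")
    return int(round(n)) + 1


@dataclass(frozen=True)
class Grid:
    """Node-centered rectangular grid with equal spacing in x and y.

    ``x`` spans ``[0, Lx]`` (propagation direction), ``y`` spans one
    undulation wavelength ``[0, Ly]``.
    """

    dx: float
    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.ny < 4:
            raise ValueError("ny >= 4 required for the transverse stencil")

    @property
    def nx(self) -> int:
        return _count_nodes(self.Lx, self.dx, "Lx")

    @property
    def ny(self) -> int:
        return _count_nodes(self.Ly, self.dx, "Ly")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        return np.arange(self.ny) * self.dx


@dataclass
class FieldState:
    """Bacterial density ``b`` (cells/um^3) and nutrient ``c`` (uM) at time ``t`` (s)."""

    t: float
    b: np.ndarray
    c: np.ndarray

    def validate(self, grid: Grid) -> None:
        if self.b.shape != grid.shape or self.c.shape != grid.shape:
            raise ValueError(
                f"field shapes {self.b.shape}/{self.c.shape} do not match grid {grid.shape}"
            )

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.b.copy(), self.c.copy())


@dataclass(frozen=True)
class IntegratorConfig:
    """Time-integration settings.

    ``dt`` (s) must satisfy the explicit-diffusion stability bound
    ``Dc*dt/dx^2 < 0.5``; a warning is issued above 0.25.  ``mode`` selects
    P(EC)E (tendencies refreshed at the corrected state, two evaluations
    per step) or PEC (one evaluation).  ``b_negative_tol`` (cells/um^3) is
    the largest single-node undershoot of ``b`` that is projected to zero
    rather than treated as an instability.
    """

    dt: float
    output_interval: float
    max_time: float
    starter: str = "rk4"
    mode: str = "pece"
    b_negative_tol: float = 2e-4
    window_threshold: float = 1e-14
    window_margin: float = 1000.0  # um
    snapshot_dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.output_interval <= 0:
            raise ValueError("dt and output_interval must be positive")
        if self.max_time < 0:
            raise ValueError("max_time must be nonnegative")
        if self.starter != "rk4":
            raise ValueError("available starter: 'rk4' (classical order 4)")
        if self.mode not in ("pece", "pec"):
            raise ValueError("mode must be 'pece' or 'pec'")

    def check_stability(self, grid: Grid, params: ModelParams) -> float:
        ratio = params.Dc * self.dt / grid.dx**2
        if ratio >= 0.5:
            raise ValueError(
                f"explicit diffusion unstable: Dc*dt/dx^2 = {ratio:.3f} >= 0.5"
            )
        if ratio > 0.25:
            warnings.warn(
                f"Dc*dt/dx^2 = {ratio:.3f} > 0.25: close to the stability bound",
                stacklevel=2,
            )
        return ratio


# ---------------------------------------------------------------------------
# reference spatial operators (NumPy)
# ---------------------------------------------------------------------------

def laplacian(field: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point Laplacian with zero-flux closures.

    x walls use the half-gradient finite-volume closure, y walls (symmetry
    planes of the undulation) use mirrored ghosts.
    """
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    f = field
    out = np.empty_like(f, dtype=float)
    # x part
    out[1:-1, :] = f[2:, :] - 2.0 * f[1:-1, :] + f[:-2, :]
    out[0, :] = f[1, :] - f[0, :]
    out[-1, :] = f[-2, :] - f[-1, :]
    # y part
    out[:, 1:-1] += f[:, 2:] - 2.0 * f[:, 1:-1] + f[:, :-2]
    out[:, 0] += 2.0 * (f[:, 1] - f[:, 0])
    out[:, -1] += 2.0 * (f[:, -1 - 1] - f[:, -1])
    out /= grid.dx**2
    return out


def _face_mean(a: np.ndarray, axis: int) -> np.ndarray:
    if axis == 0:
        return 0.5 * (a[:-1, :] + a[1:, :])
    return 0.5 * (a[:, :-1] + a[:, 1:])


def flux_divergence(b: np.ndarray, c: np.ndarray, grid: Grid,
                    params: ModelParams, medium: PorousMediumParams) -> np.ndarray:
    """Transport tendency ``-div(Jb)`` with ``Jb = -Db(b) grad b + b chi(b) grad f(c)``.

    Conservative face-flux discretization; all face coefficients are
    arithmetic means of the adjacent node values.  The sensed-signal
    gradient is the central difference of ``f(c)`` itself: averaging the
    convex ``f'(c)`` across a face where ``c`` spans orders of magnitude
    (the thin depletion zone) would grossly overestimate ``grad f``.
    Wall faces carry no flux, so the area-weighted total of the returned
    field vanishes to round-off.
    """
    if b.shape != grid.shape or c.shape != grid.shape:
        raise ValueError("field shapes do not match grid")
    if not (np.isfinite(b).all() and np.isfinite(c).all()):
        idx = np.argwhere(~(np.isfinite(b) & np.isfinite(c)))[0]
        raise NumericsError(f"non-finite input field at node {tuple(idx)}")
    dx = grid.dx
    phi = np.asarray(motility_correction(b, medium, params), dtype=float)
    Dbn = medium.Db0 * phi
    chin = medium.chi0 * phi
    fsig = np.asarray(sensing_f(np.maximum(c, 0.0), params), dtype=float)

    out = np.zeros_like(b, dtype=float)
    # x faces
    Jx = (-_face_mean(Dbn, 0) * np.diff(b, axis=0)
          + _face_mean(b, 0) * _face_mean(chin, 0)
          * np.diff(fsig, axis=0)) / dx
    out[1:-1, :] -= np.diff(Jx, axis=0) / dx
    out[0, :] -= Jx[0, :] / dx
    out[-1, :] += Jx[-1, :] / dx
    # y faces (half cells at the symmetry walls)
    Jy = (-_face_mean(Dbn, 1) * np.diff(b, axis=1)
          + _face_mean(b, 1) * _face_mean(chin, 1)
          * np.diff(fsig, axis=1)) / dx
    out[:, 1:-1] -= np.diff(Jy, axis=1) / dx
    out[:, 0] -= Jy[:, 0] * 2.0 / dx
    out[:, -1] += Jy[:, -1] * 2.0 / dx
    return out


def rhs(state: FieldState, grid: Grid, params: ModelParams,
        medium: PorousMediumParams) -> tuple[np.ndarray, np.ndarray]:
    """Reference tendencies ``(db/dt, dc/dt)`` including knockout flags."""
    state.validate(grid)
    med = params.effective_medium(medium)
    consumption, growth = reaction_terms(
        (state.b, np.maximum(state.c, 0.0)), params)
    dcdt = params.Dc * laplacian(state.c, grid) + consumption
    dbdt = flux_divergence(state.b, state.c, grid, params, med) + growth
    return dbdt, dcdt


def field_total(field: np.ndarray, grid: Grid) -> float:
    """Area-weighted total of a field (trapezoidal in y to match the
    half-cell boundary rows)."""
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    w = np.ones(grid.ny)
    w[0] = w[-1] = 0.5
    return float((field * w).sum() * grid.dx**2)


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------

class _KernelContext:
    """Holds the resolved constants and scratch arrays for the numba path."""

    def __init__(self, grid: Grid, params: ModelParams, medium: PorousMediumParams):
        med = params.effective_medium(medium)
        self.grid = grid
        self.params = params
        self.medium = med
        # density above which the crowding correction deviates from 1
        self.b_phi_min = 3.0 * med.f_pore / (
            4.0 * math.pi * (med.l_c + params.d_cell) ** 3)
        shape = grid.shape
        self.scratch = tuple(np.zeros(shape) for _ in range(7))
        self.const = (
            grid.dx, params.Dc, params.kappa, params.c_half, params.gamma_eff,
            params.c_minus, params.c_plus, params.sensing_mode == "linear",
            params.c_lin, med.Db0, med.chi0, med.f_pore, params.d_cell,
            med.l_c, self.b_phi_min,
        )

    def rhs_into(self, b, c, dbdt, dcdt, i0: int, i1: int) -> None:
        (dx, Dc, kappa, c_half, gamma, c_minus, c_plus, linear, c_lin,
         Db0, chi0, f_pore, d_cell, l_c, b_phi_min) = self.const
        fsig, Dbn, chin = self.scratch[4:]
        _kernels.rhs_kernel(b, c, dbdt, dcdt, i0, i1, dx, Dc, kappa, c_half,
                            gamma, c_minus, c_plus, linear, c_lin, Db0, chi0,
                            f_pore, d_cell, l_c, b_phi_min, fsig, Dbn, chin)

    def advance(self, b, c, fb, fc, head, t, nsteps, dt, i0, i1,
                b_negative_tol, c_star, tprime, final_eval):
        (dx, Dc, kappa, c_half, gamma, c_minus, c_plus, linear, c_lin,
         Db0, chi0, f_pore, d_cell, l_c, b_phi_min) = self.const
        bp, cp, fbs, fcs, fsig, Dbn, chin = self.scratch
        return _kernels.advance(
            b, c, fb, fc, head, t, nsteps, dt, i0, i1, dx, Dc, kappa, c_half,
            gamma, c_minus, c_plus, linear, c_lin, Db0, chi0, f_pore, d_cell,
            l_c, b_phi_min, b_negative_tol, c_star, tprime, final_eval,
            bp, cp, fbs, fcs, fsig, Dbn, chin)


def _active_window(b: np.ndarray, grid: Grid, cfg: IntegratorConfig) -> tuple[int, int]:
    cols = np.flatnonzero(b.max(axis=1) > cfg.window_threshold)
    margin = int(math.ceil(cfg.window_margin / grid.dx))
    if cols.size == 0:
        return 0, grid.nx - 1
    return max(int(cols[0]) - margin, 0), min(int(cols[-1]) + margin, grid.nx - 1)


# ---------------------------------------------------------------------------
# multistep scheme, reference (NumPy) path
# ---------------------------------------------------------------------------

@dataclass
class History:
    """Rolling state/tendency history for the order-3 predictor."""

    states: list  # three FieldState, oldest first
    fb: list      # matching db/dt evaluations
    fc: list      # matching dc/dt evaluations


def _rk4_pde_step(state: FieldState, grid: Grid, params: ModelParams,
                  medium: PorousMediumParams, dt: float) -> FieldState:
    def deriv(b, c):
        s = FieldState(state.t, b, c)
        return rhs(s, grid, params, medium)

    b, c = state.b, state.c
    kb1, kc1 = deriv(b, c)
    kb2, kc2 = deriv(np.maximum(b + 0.5 * dt * kb1, 0.0), np.maximum(c + 0.5 * dt * kc1, 0.0))
    kb3, kc3 = deriv(np.maximum(b + 0.5 * dt * kb2, 0.0), np.maximum(c + 0.5 * dt * kc2, 0.0))
    kb4, kc4 = deriv(np.maximum(b + dt * kb3, 0.0), np.maximum(c + dt * kc3, 0.0))
    bn = b + dt / 6.0 * (kb1 + 2 * kb2 + 2 * kb3 + kb4)
    cn = c + dt / 6.0 * (kc1 + 2 * kc2 + 2 * kc3 + kc4)
    return FieldState(state.t + dt, np.maximum(bn, 0.0), np.maximum(cn, 0.0))


def start_history(state0: FieldState, grid: Grid, params: ModelParams,
                  medium: PorousMediumParams, cfg: IntegratorConfig) -> History:
    """Generate the two back values for the order-3 predictor with RK4.

    A classical fourth-order single step exceeds the order of the
    predictor, so the multistep scheme starts at its full accuracy.
    """
    state0.validate(grid)
    states = [state0.copy()]
    for _ in range(2):
        states.append(_rk4_pde_step(states[-1], grid, params, medium, cfg.dt))
    evals = [rhs(s, grid, params, medium) for s in states]
    if not all(np.isfinite(e).all() for pair in evals for e in pair):
        raise NumericsError("non-finite tendencies during startup")
    return History(states=states,
                   fb=[e[0] for e in evals],
                   fc=[e[1] for e in evals])


def abm_step(history: History, grid: Grid, params: ModelParams,
             medium: PorousMediumParams, cfg: IntegratorConfig) -> FieldState:
    """One predictor-corrector step of the reference path; updates ``history``.

    Adams-Bashforth order-3 predictor, one trapezoidal (Adams-Moulton
    order-2) correction, and -- in ``pece`` mode -- a final tendency
    evaluation at the corrected state.
    """
    if len(history.states) != 3:
        raise ValueError("history must hold exactly 3 states")
    dt = cfg.dt
    s = history.states[-1]
    fb2, fb1, fb0 = history.fb  # oldest ... newest
    fc2, fc1, fc0 = history.fc
    bp = np.maximum(s.b + dt / 12.0 * (23 * fb0 - 16 * fb1 + 5 * fb2), 0.0)
    cp = np.maximum(s.c + dt / 12.0 * (23 * fc0 - 16 * fc1 + 5 * fc2), 0.0)
    pred = FieldState(s.t + dt, bp, cp)
    fbp, fcp = rhs(pred, grid, params, medium)
    bn = np.maximum(s.b + dt / 2.0 * (fbp + fb0), 0.0)
    cn = np.maximum(s.c + dt / 2.0 * (fcp + fc0), 0.0)
    new = FieldState(s.t + dt, bn, cn)
    if cfg.mode == "pece":
        fbn, fcn = rhs(new, grid, params, medium)
    else:
        fbn, fcn = fbp, fcp
    history.states = history.states[1:] + [new]
    history.fb = [fb1, fb0, fbn]
    history.fc = [fc1, fc0, fcn]
    return new


# ---------------------------------------------------------------------------
# production integrator (numba path)
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Snapshots and diagnostics of one PDE integration."""

    times: np.ndarray              # snapshot times, s
    b: list                        # snapshots of cell density
    c: list                        # snapshots of nutrient
    final: FieldState              # full-precision final state
    tprime: np.ndarray             # first nutrient-depletion time per node, -1 if never
    stop_reason: str               # "max_time" | "callback" | name of abort
    clipped_b: float               # accumulated projected b undershoot (field units)
    clipped_c: float
    min_b_seen: float

    @property
    def n_snapshots(self) -> int:
        return len(self.b)


def integrate(state0: FieldState, grid: Grid, params: ModelParams,
              medium: PorousMediumParams, cfg: IntegratorConfig,
              callbacks: Sequence[Callable[[float, np.ndarray, np.ndarray], bool]] = (),
              ) -> SimulationResult:
    """Integrate the model from ``state0`` to ``cfg.max_time``.

    Snapshots are emitted every ``cfg.output_interval`` (and at t=0).  Each
    callback is invoked at snapshot times with ``(t, b, c)``; returning a
    truthy value stops the run cleanly ("callback" stop reason).  The
    solver is fully deterministic.
    """
    state0.validate(grid)
    cfg.check_stability(grid, params)
    if np.min(state0.b) < 0 or np.min(state0.c) < 0:
        raise ValueError("initial fields must be nonnegative")

    ctx = _KernelContext(grid, params, medium)
    dt = cfg.dt
    steps_per_out = max(int(round(cfg.output_interval / dt)), 1)
    n_steps_total = int(round(cfg.max_time / dt))

    snap_dtype = np.dtype(cfg.snapshot_dtype)
    times = [0.0]
    b_snaps = [state0.b.astype(snap_dtype)]
    c_snaps = [state0.c.astype(snap_dtype)]
    tprime = np.full(grid.shape, -1.0)
    tprime[state0.c < params.c_star] = 0.0

    if n_steps_total == 0:
        return SimulationResult(np.asarray(times), b_snaps, c_snaps,
                                state0.copy(), tprime, "max_time", 0.0, 0.0, 0.0)

    b = state0.b.astype(float).copy()
    c = state0.c.astype(float).copy()
    fb = np.zeros((3,) + grid.shape)
    fc = np.zeros((3,) + grid.shape)

    # starter: two RK4 steps on the kernel RHS, evaluated on the full window
    i0, i1 = _active_window(b, grid, cfg)
    kb = [np.zeros(grid.shape) for _ in range(4)]
    kc = [np.zeros(grid.shape) for _ in range(4)]
    ctx.rhs_into(b, c, fb[0], fc[0], i0, i1)
    t = 0.0
    for m in range(2):
        ctx.rhs_into(b, c, kb[0], kc[0], i0, i1)
        ctx.rhs_into(np.maximum(b + 0.5 * dt * kb[0], 0.0),
                     np.maximum(c + 0.5 * dt * kc[0], 0.0), kb[1], kc[1], i0, i1)
        ctx.rhs_into(np.maximum(b + 0.5 * dt * kb[1], 0.0),
                     np.maximum(c + 0.5 * dt * kc[1], 0.0), kb[2], kc[2], i0, i1)
        ctx.rhs_into(np.maximum(b + dt * kb[2], 0.0),
                     np.maximum(c + dt * kc[2], 0.0), kb[3], kc[3], i0, i1)
        b += dt / 6.0 * (kb[0] + 2 * kb[1] + 2 * kb[2] + kb[3])
        c += dt / 6.0 * (kc[0] + 2 * kc[1] + 2 * kc[2] + kc[3])
        np.maximum(b, 0.0, out=b)
        np.maximum(c, 0.0, out=c)
        t += dt
        ctx.rhs_into(b, c, fb[m + 1], fc[m + 1], i0, i1)
    if not (np.isfinite(b).all() and np.isfinite(c).all()):
        raise NumericsError("non-finite fields during startup")
    tprime[(tprime < 0) & (c < params.c_star)] = t

    head = 2
    steps_done = 2
    clip_b_total = 0.0
    clip_c_total = 0.0
    min_b_global = 0.0
    stop_reason = "max_time"
    final_eval = cfg.mode == "pece"
    next_output = steps_per_out

    while steps_done < n_steps_total:
        while next_output <= steps_done:
            next_output += steps_per_out
        n_chunk = min(next_output, n_steps_total) - steps_done
        i0, i1 = _active_window(b, grid, cfg)
        head, t, status, min_b, clip_b, clip_c = ctx.advance(
            b, c, fb, fc, head, t, n_chunk, dt, i0, i1,
            cfg.b_negative_tol, params.c_star, tprime, final_eval)
        steps_done += n_chunk
        clip_b_total += clip_b
        clip_c_total += clip_c
        min_b_global = min(min_b_global, min_b)
        if status == _kernels.ABORT_NEGATIVE_B:
            raise NumericsError(
                f"cell density undershot {min_b:.3e} (< -{cfg.b_negative_tol:g}) "
                f"at t={t:.1f} s")
        if not (np.isfinite(b).all() and np.isfinite(c).all()):
            raise NumericsError(f"non-finite fields at t={t:.1f} s")
        # snapshot + callbacks at output boundaries (and at the final step)
        if steps_done % steps_per_out == 0 or steps_done == n_steps_total:
            times.append(t)
            b_snaps.append(b.astype(snap_dtype))
            c_snaps.append(c.astype(snap_dtype))
            if any(cb(t, b, c) for cb in callbacks):
                stop_reason = "callback"
                break

    return SimulationResult(np.asarray(times), b_snaps, c_snaps,
                            FieldState(t, b.copy(), c.copy()), tprime,
                            stop_reason, clip_b_total, clip_c_total,
                            min_b_global)


# ---------------------------------------------------------------------------
# scalar embodiment of the same scheme (for convergence/validation studies)
# ---------------------------------------------------------------------------

def ode_integrate(f: Callable, y0, t0: float, dt: float, nsteps: int,
                  mode: str = "pece"):
    """Integrate ``dy/dt = f(t, y)`` with the RK4-started AB3/AM2 scheme.

    Same coefficients and sequencing as the PDE path, applied to a scalar
    or array state without projection; used to validate the order and
    accuracy of the multistep scheme against closed-form solutions.
    Returns the state at ``t0 + nsteps*dt``.
    """
    if nsteps < 0:
        raise ValueError("nsteps must be nonnegative")
    y = np.asarray(y0, dtype=float)
    ts = [t0]
    ys = [y]
    fs = [np.asarray(f(t0, y), dtype=float)]
    for _ in range(min(2, nsteps)):
        t, y = ts[-1], ys[-1]
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append(t + dt)
        ys.append(y)
        fs.append(np.asarray(f(t + dt, y)))
    for n in range(2, nsteps):
        t, y = ts[-1], ys[-1]
        yp = y + dt / 12.0 * (23 * fs[-1] - 16 * fs[-2] + 5 * fs[-3])
        fp_ = np.asarray(f(t + dt, yp))
        yn = y + dt / 2.0 * (fp_ + fs[-1])
        fn = np.asarray(f(t + dt, yn)) if mode == "pece" else fp_
        ts.append(t + dt)
        ys.append(yn)
        fs.append(fn)
        ts, ys, fs = ts[-3:], ys[-3:], fs[-3:]
    return ys[-1]
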