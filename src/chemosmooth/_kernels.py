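"""Numba-compiled inner loops of the PDE integrator.

The readable reference implementations live in :mod:`chemosmooth.numerics`;
these kernels compute the same right-hand side and multistep update, fused
and loop-based for speed, and are cross-checked against the reference in the
test suite.

Spatial scheme (node-centered grid, spacing ``dx`` in both directions):

* nutrient diffusion: 5-point Laplacian; zero-flux closures use a copied
  ghost at the x walls (finite-volume style) and a mirrored ghost at the
  y walls (symmetry planes of the undulation), i.e. the boundary rows get
  the factor-2 half-cell divergence in y.
* bacterial transport: conservative face-flux form of
  ``-div(-Db(b) grad b + b chi(b) grad f(c))`` with arithmetic-mean face
  coefficients.  The sensed-signal gradient is the central difference of
  ``f(c)`` itself, never the chain-rule form ``f'(c) grad c``: ``f'`` is
  strongly convex, so averaging it across a face where ``c`` jumps orders
  of magnitude (as it does across the thin depletion zone) would
  overestimate ``grad f`` by orders of magnitude and produce spurious
  chemotactic velocities.  Wall faces carry zero flux, so cell mass
  changes only through growth.

Transport is evaluated only on a window of x-columns that contains the
support of ``b`` (plus a generous margin); outside the window ``b`` is zero
to round-off and its tendencies are exactly zero.

Time scheme: Adams-Bashforth order-3 predictor with an Adams-Moulton
order-2 (trapezoidal) corrector in P(EC)E mode (``final_eval=True``) or
PEC mode (``final_eval=False``).  Negative undershoots are projected to
zero and accounted for; the caller decides whether the accounted amount is
tolerable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by _advance
OK = 0
ABORT_NEGATIVE_B = 1
ABORT_NONFINITE = 2


@njit(cache=True, fastmath=True)
def rhs_kernel(b, c, dbdt, dcdt, i0, i1, dx,
               Dc, kappa, c_half, gamma,
               c_minus, c_plus, linear_sensing, c_lin,
               Db0, chi0, f_pore, d_cell, l_c, b_phi_min,
               fsig, Dbn, chin):
    """Fill dbdt/dcdt with the model tendencies.

    ``i0:i1+1`` is the active x-window for bacterial terms.  ``fsig``,
    ``Dbn``, ``chin`` are caller-allocated scratch arrays (node sensed
    signal and corrected motility coefficients).
    """
    nx, ny = b.shape
    inv_dx = 1.0 / dx
    inv_dx2 = inv_dx * inv_dx
    three_f_over_4pi = 3.0 * f_pore / (4.0 * np.pi)
    inv_lc = 1.0 / l_c

    # --- nutrient: diffusion everywhere, consumption in the window;
    #     bacterial growth shares the Monod factor so it is filled here too.
    for i in range(nx):
        iW = i - 1 if i > 0 else 0          # copied ghost at x walls
        iE = i + 1 if i < nx - 1 else nx - 1
        in_window = i0 <= i <= i1
        for j in range(ny):
            jS = j - 1 if j > 0 else 1       # mirrored ghost at y walls
            jN = j + 1 if j < ny - 1 else ny - 2
            lap = (c[iW, j] + c[iE, j] + c[i, jS] + c[i, jN]
                   - 4.0 * c[i, j]) * inv_dx2
            react_c = 0.0
            react_b = 0.0
            if in_window:
                bij = b[i, j]
                cij = c[i, j]
                if bij > 0.0 and cij > 0.0:
                    g = cij / (cij + c_half)
                    react_c = -kappa * bij * g
                    react_b = gamma * bij * g
            dcdt[i, j] = Dc * lap + react_c
            dbdt[i, j] = react_b

    if i1 < i0:
        return

    # --- node coefficients on the window (with one halo column each side);
    #     fsig holds the sensed signal f(c) whose face differences drive
    #     the chemotactic flux
    ih0 = i0 - 1 if i0 > 0 else 0
    ih1 = i1 + 1 if i1 < nx - 1 else nx - 1
    for i in range(ih0, ih1 + 1):
        for j in range(ny):
            cij = c[i, j]
            if cij < 0.0:
                cij = 0.0
            if linear_sensing:
                fsig[i, j] = cij / c_lin
            else:
                fsig[i, j] = np.log((1.0 + cij / c_minus) / (1.0 + cij / c_plus))
            bij = b[i, j]
            if bij <= b_phi_min:
                phi = 1.0
            else:
                lcell = (three_f_over_4pi / bij) ** (1.0 / 3.0) - d_cell
                if lcell <= 0.0:
                    phi = 0.0
                else:
                    r = lcell * inv_lc
                    phi = r * r if r < 1.0 else 1.0
            Dbn[i, j] = Db0 * phi
            chin[i, j] = chi0 * phi

    # --- x-direction face fluxes (zero at walls and window edges)
    for j in range(ny):
        Jl = 0.0
        for i in range(i0, i1 + 1):
            if i < i1:
                D_f = 0.5 * (Dbn[i, j] + Dbn[i + 1, j])
                chi_f = 0.5 * (chin[i, j] + chin[i + 1, j])
                b_f = 0.5 * (b[i, j] + b[i + 1, j])
                Jr = (-D_f * (b[i + 1, j] - b[i, j])
                      + b_f * chi_f * (fsig[i + 1, j] - fsig[i, j])) * inv_dx
            else:
                Jr = 0.0
            dbdt[i, j] -= (Jr - Jl) * inv_dx
            Jl = Jr

    # --- y-direction face fluxes; boundary rows are half cells (factor 2)
    for i in range(i0, i1 + 1):
        Jb = 0.0
        for j in range(ny):
            if j < ny - 1:
                D_f = 0.5 * (Dbn[i, j] + Dbn[i, j + 1])
                chi_f = 0.5 * (chin[i, j] + chin[i, j + 1])
                b_f = 0.5 * (b[i, j] + b[i, j + 1])
                Jt = (-D_f * (b[i, j + 1] - b[i, j])
                      + b_f * chi_f * (fsig[i, j + 1] - fsig[i, j])) * inv_dx
            else:
                Jt = 0.0
            if j == 0 or j == ny - 1:
                dbdt[i, j] -= (Jt - Jb) * 2.0 * inv_dx
            else:
                dbdt[i, j] -= (Jt - Jb) * inv_dx
            Jb = Jt
    return


@njit(cache=True, fastmath=True)
def advance(b, c, fb, fc, head, t, nsteps, dt, i0, i1, dx,
            Dc, kappa, c_half, gamma,
            c_minus, c_plus, linear_sensing, c_lin,
            Db0, chi0, f_pore, d_cell, l_c, b_phi_min,
            b_negative_tol, c_star, tprime, final_eval,
            bp, cp, fbs, fcs, fsig, Dbn, chin):
    """Advance ``nsteps`` ABM steps in place.

    ``fb``/``fc`` are (3, nx, ny) tendency histories with the newest slice at
    index ``head``.  Returns ``(head, t, status, min_b_seen, clipped_b,
    clipped_c)`` where the clipped totals are sums of projected negative
    undershoot magnitudes (field units, not yet weighted by cell area).
    """
    nx, ny = b.shape
    a0 = dt * 23.0 / 12.0
    a1 = -dt * 16.0 / 12.0
    a2 = dt * 5.0 / 12.0
    h2 = 0.5 * dt
    min_b = 0.0
    clip_b = 0.0
    clip_c = 0.0
    status = OK

    for _ in range(nsteps):
        n = head
        n1 = (head + 2) % 3
        n2 = (head + 1) % 3

        # predict (clip negatives: predicted values only feed the evaluate)
        for i in range(nx):
            bwin = i0 <= i <= i1
            for j in range(ny):
                cv = c[i, j] + a0 * fc[n, i, j] + a1 * fc[n1, i, j] + a2 * fc[n2, i, j]
                cp[i, j] = cv if cv > 0.0 else 0.0
                if bwin:
                    bv = b[i, j] + a0 * fb[n, i, j] + a1 * fb[n1, i, j] + a2 * fb[n2, i, j]
                    bp[i, j] = bv if bv > 0.0 else 0.0
                else:
                    bp[i, j] = b[i, j]

        rhs_kernel(bp, cp, fbs, fcs, i0, i1, dx, Dc, kappa, c_half, gamma,
                   c_minus, c_plus, linear_sensing, c_lin,
                   Db0, chi0, f_pore, d_cell, l_c, b_phi_min, fsig, Dbn, chin)

        # correct
        t = t + dt
        for i in range(nx):
            bwin = i0 <= i <= i1
            for j in range(ny):
                cv = c[i, j] + h2 * (fcs[i, j] + fc[n, i, j])
                if cv < 0.0:
                    clip_c -= cv
                    cv = 0.0
                c[i, j] = cv
                if bwin:
                    bv = b[i, j] + h2 * (fbs[i, j] + fb[n, i, j])
                    if bv < 0.0:
                        if bv < min_b:
                            min_b = bv
                        clip_b -= bv
                        bv = 0.0
                    b[i, j] = bv
                    if tprime[i, j] < 0.0 and cv < c_star:
                        tprime[i, j] = t

        if min_b < -b_negative_tol:
            status = ABORT_NEGATIVE_B
            return head, t, status, min_b, clip_b, clip_c
        if not (np.isfinite(b[i0, 0]) and np.isfinite(c[i0, 0])):
            status = ABORT_NONFINITE
            return head, t, status, min_b, clip_b, clip_c

        nxt = (head + 1) % 3
        if final_eval:
            # P(EC)E: refresh the stored tendency at the corrected state
            rhs_kernel(b, c, fb[nxt], fc[nxt], i0, i1, dx, Dc, kappa, c_half,
                       gamma, c_minus, c_plus, linear_sensing, c_lin,
                       Db0, chi0, f_pore, d_cell, l_c, b_phi_min, fsig, Dbn, chin)
        else:
            for i in range(nx):
                for j in range(ny):
                    fb[nxt, i, j] = fbs[i, j]
                    fc[nxt, i, j] = fcs[i, j]
        head = nxt

    return head, t, status, min_b, clip_b, clip_c
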