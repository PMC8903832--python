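# Methods

## Model

`chemosmooth` simulates dense *E. coli* populations migrating through a
disordered porous medium by chemotaxis along a self-generated gradient of
their primary nutrient and attractant (L-serine), and analyzes how
large-scale undulations of the migrating front autonomously smooth out.

Two coupled fields on a 2D plane: nutrient concentration `c(x,y,t)` and
bacterial number density `b(x,y,t)`:

    dc/dt = Dc lap(c) - b kappa g(c)
    db/dt = -div(Jb) + b gamma g(c),   Jb = -Db(b) grad b + b chi(b) grad f(c)

with Michaelis–Menten kinetics `g(c) = c/(c + c_half)` governing both
consumption and growth, and logarithmic sensing

    f(c) = ln[(1 + c/c_minus)/(1 + c/c_plus)].

`f` is linear in `c` below `c_minus` and saturates at `ln(c_plus/c_minus)`
above `c_plus` — the receptor dissociation constants of the inactive and
active conformations. The chemotactic drift is `v_c = chi grad f(c) =
chi f'(c) grad c`: the nutrient gradient is the forcing, `chi f'(c)` the
response. Because `f''< 0`, the response decays with `c`; cells at convex
front peaks (bathed in more nutrient) respond more weakly than cells in
concave valleys, and this difference — not diffusion — erases front
undulations. A strictly linear variant `f(c) = c/c_lin` with
`c_lin = (1/c_minus - 1/c_plus)^-1` (same small-`c` slope, no saturation)
is included as the control that abolishes smoothing. The control is a
*response re-analysis*, not a separate simulation: without saturation the
sensed signal would jump by `c0/c_lin ~ 1e4` across the depletion zone,
implying chemotactic velocities of order 100 um/s — physically absurd and
numerically explosive. Instead `chi f'(c) dc/dx` is re-evaluated with the
constant linear `f'` along the edge of the established
(logarithmic-sensing) front: the valley-minus-peak velocity gap flips
sign, i.e. with concentration-independent response the stronger forcing
at peaks wins and the undulation would amplify, not smooth
(`driver.reanalyze_with_sensing`).

### Parameters (internal units: um, s, uM, cells/um^3)

| symbol | meaning | default | source |
|---|---|---|---|
| Dc | nutrient diffusivity | 800 um^2/s | bulk measurement |
| kappa | max consumption per cell | 1.6e4 uM um^3/cell/s (= 1.6e-11 mM (cell/mL)^-1 s^-1) | literature |
| c_half | Monod constant | 1 uM | literature |
| gamma | max division rate | ln2 / 3600 s | measured (60 min doubling) |
| c_minus, c_plus | sensing dissociation constants | 1, 30 uM | literature |
| c0 | initial nutrient | 1e4 uM (10 mM) | medium recipe |
| b_pack | printed inoculum density | 0.95 cells/um^3 | measured |
| d_cell | cell size in the crowding law | 1 um | estimate |
| tau_delay, tau_starve | starvation signal-loss delay and decay | 7200 s, 1782 s | measured |
| c_star | depletion threshold of the signal model | 1 uM (= c_half) | chosen: the natural kinetic scale; configurable |

Per-medium motility presets (mean pore size xi; measured):
`(xi, Db, chi, f_pore, l_c)` = (2.2, 2.32, 145, 0.36, 4.6),
(1.7, 0.93, 9, 0.17, 3.1), (1.2, 0.42, 5, 0.04, 2.4), units um and um^2/s.

All literature values quoted in mM / cells/mL / min / hr are converted
once at construction; round-trips are tested.

### Density-dependent motility

The mean cell separation `l_cell = (3 f_pore/(4 pi b))^(1/3) - d_cell`
truncates the random-walk step once it falls below the mean chord length
`l_c` of the pore space: both `Db` and `chi` are multiplied by
`(l_cell/l_c)^2` for `0 < l_cell < l_c`, by 1 for dilute populations, and
by 0 once cells overlap (`l_cell <= 0`, jamming). The printed inoculum
(0.95 cells/um^3) is jammed in every preset; fronts carry ~0.003
cells/um^3, where the factor is ~0.2.

## Numerics

Node-centered grid, equal spacing `dx` in both directions; `x in [0, Lx]`
is the propagation direction, `y` spans exactly one undulation wavelength
with zero-flux boundaries (valley on the boundaries, peak at `lambda/2`;
by symmetry equivalent to any one-wavelength window).

* Nutrient diffusion: 5-point central Laplacian. x-walls use the
  finite-volume copied-ghost closure; y-walls are symmetry planes and use
  mirrored ghosts with half-cell divergence, which keeps the transverse
  curvature of symmetric modes second-order accurate at the peak/valley
  rows.
* Bacterial transport: conservative face-flux form with arithmetic-mean
  face coefficients and zero wall fluxes, so with `gamma = 0` total cell
  number is conserved to round-off (verified to 1e-6 relative in tests;
  the discrete total uses trapezoidal weights in y to match the half-cell
  boundary rows).
* The chemotactic face flux differences the sensed signal itself,
  `b_f chi_f (f(c_E) - f(c_W))/dx`, never the chain-rule form
  `avg(f'(c)) (c_E - c_W)/dx`. `f'` is strongly convex, and across the
  thin depletion zone `c` jumps orders of magnitude between neighboring
  nodes; averaging `f'` there overestimates `grad f` by orders of
  magnitude and produces spurious edge velocities (empirically: several
  times faster undulation decay). Differencing `f` bounds the face
  gradient by `ln(c_plus/c_minus)/dx`, which is the physical saturation
  of the sensed signal.
* Time stepping: Adams–Bashforth order-3 predictor with an Adams–Moulton
  order-2 (trapezoidal) corrector, one correction per step, tendencies
  re-evaluated at the corrected state (P(EC)E). PEC (no final
  evaluation) is provided for the scalar scheme but is unstable on the
  stiff PDE and is not used. The multistep history is started with two
  classical RK4 steps — order 4, above the predictor's order 3, so the
  scheme starts at full accuracy (the order-6 starter named in the
  original description depends on coefficients from an inaccessible
  reference; a single-step starter of order >= predictor order leaves the
  solution unchanged at this order).
* Stability: the explicit diffusion bound `Dc dt/dx^2 < 0.5` is enforced,
  with a warning above 0.25. Defaults (`dx = 20 um`, `dt = 0.05 s`) give
  0.1.

### Stiff consumption and positivity

At packed density the consumption rate constant is `b_pack kappa/c_half
~ 1.5e4 /s` — a 70-microsecond time scale that no practical explicit step
resolves. Depleted nodes therefore chatter about `c = 0` at the magnitude
of one step's diffusive resupply. Negative `c` excursions are projected
to zero each step (with `g(c<=0) = 0`), which yields exactly the
physically correct diffusion-limited consumption; the projected amount is
accounted, and the monotone decrease of total nutrient is a test. The
cell field can undershoot slightly at the steep front foot (central
differences, no artificial diffusion); undershoots are projected and
accounted, and the run aborts if any node undershoots beyond
`b_negative_tol` (default 2e-4 cells/um^3; measured undershoots peak near
1.1e-4 in the loosest, fastest medium and near 1e-5 elsewhere). Projected
cell mass over a full desk-scale run stays below ~0.2% of the initial
population (2% in the loosest medium, whose front foot is strongly
advection-dominated) and is reported per run.

A side effect of the chatter: it amplifies floating-point asymmetries, so
a mirror-symmetric initial condition stays symmetric only to ~1% locally
near depleted nodes after hours of simulated time. The leading edge —
everything the analysis reads — stays symmetric to better than 0.01 dx
(tested).

### Desk-scale preset and self-convergence

The production ("desk") preset uses `dx = 20 um`, `dt = 0.05 s`, a
front-region domain (5–12 mm by one wavelength, inoculum centered at
x = 1 mm) and stops once the undulation amplitude has decayed to 10% of
its running maximum; a wall guard stops a run before the front reaches
the +x boundary. The full-chamber preset (`dx = 10 um`, `dt = 0.01 s`,
`Lx = 3.5 cm`, 20 h) is selectable but ~3 orders of magnitude more
expensive and is not exercised by the test suite. Problem sizes in the
tests and the acceptance script are chosen so the whole suite runs in
tens of minutes on one core.

Self-convergence of the base case (wavelength 0.8 mm, amplitude 300 um,
xi = 1.7 preset): the amplitude trace `A(t)` agrees within ~10–15% across
(dx, dt) = (40, 0.05), (20, 0.05), (20, 0.0125), (10, 0.0125) um/s, and a
non-conservative nodal-form discretization prototype reproduces it as
well; the fitted smoothing time changes by <15% under (dx/2, dt/4)
refinement (an acceptance test). The transport hot loop runs through
numba kernels that are cross-checked elementwise against the readable
NumPy implementation; transport is evaluated only on the x-window
carrying cell support (plus a 1 mm margin; `b < 1e-14` outside, so the
windowing error is below round-off).

## Analysis pipeline

* Leading edge: per y-row, scan inward from +x to the first node with
  `b >= threshold` and interpolate the crossing linearly. Migration
  analyses use `threshold = 1e-4 x` peak initial density; the velocity
  decomposition uses per-condition thresholds (0.003 cells/um^3 for the
  base condition and the loosest medium, 0.002 for the longer wavelengths
  at xi = 1.7, 0.001 for the tightest medium). Undulation amplitude `A` =
  half the peak-to-valley edge excursion (so the initial geometric
  amplitude is recovered exactly); front position `Rf` = leading-most
  edge point relative to the inoculum centerline.
* Smoothing time: for each candidate `t0` on the sampling grid, `A0` is
  pinned to `A(t0)` and `A = A0 exp(-(t-t0)/tau)` is least-squares fitted
  to `t >= t0`; the reported `t0` is the earliest whose RMSE is within 5%
  of the global minimum, and the basin of such candidates is the `t0`
  uncertainty. Two guards keep the ill-posed "earliest minimal error"
  search on the meaningful part of clean simulated traces: samples below
  4% of the trace maximum are dropped (sub-grid amplitudes), and `t0`
  candidates must retain >= 30% of the maximum (otherwise the RMSE
  minimum drifts into the near-zero tail). Both are exposed parameters.
  A trace that never decays (or fits `tau` beyond 20x the window) returns
  a structured non-smoothing result.
* Velocity decomposition: `c`, its central-difference x-gradient, and
  `f'(c)` interpolated to the edge; `v_cx = chi f' dc/dx` with the
  constant per-medium `chi` is the printed decomposition. The crowding
  correction at the decomposition threshold is ~0.2 (the threshold sits
  above the crowding onset of 5.9e-4 cells/um^3), identical at peaks and
  valleys to within a few percent, so it scales but never flips the gap.
  The catch-up time `tau'` — the first time the integrated valley-minus-
  peak velocity gap covers `A0` — uses the crowding-corrected cell
  velocity, because that is the speed edge cells actually move;
  uncorrected, the integral overshoots the observed amplitude decay
  about five-fold and `tau'` would not be commensurate with `tau`.
* No-front criterion (knockout and low-nutrient runs): a collectively
  migrating front must outrun undirected spreading; a full-length run is
  classified no-front when the edge advance stays below
  `2 sqrt(Db t) + 2 sqrt(Db gamma) t` (diffusive plus pulled-wave
  proliferative advance). Runs stopped early by the amplitude or wall
  callbacks trivially had a front.
* Starvation signal: each node records the first time `t'` its nutrient
  fell below `c_star`; for `t > t' + tau_delay` the rendered cell signal
  is `b exp(-(t - t')/tau_starve)` (the decay clock starts at depletion,
  per the source description, so the signal drops discontinuously when
  the delay elapses). This affects only the fluorescence-like
  visualization, not the density analyses.

## Synthetic data

The generator emulates the 3D-printed inocula: a Gaussian ridge (FWHM
100 um, peak 0.95 cells/um^3) whose centerline oscillates sinusoidally
(amplitude `A0`, wavelength `lambda`), plus a uniform nutrient field. It
also produces ground-truth amplitude time series (piecewise
constant-then-exponential, optional seeded Gaussian noise) and log-scaled
16-bit image stacks for testing the fitting and imaging stages in
isolation. What it does not emulate: pore-scale granularity of the
medium, imaging noise and optical sectioning, inoculation irregularities,
and any 3D structure — so passing tests demonstrate the pipeline's
correctness on the model's own terms, not agreement with raw micrographs.

## Known limitations

* The model is 2D and mean-field; hydrodynamic and alignment interactions
  are deliberately absent (end-on collisions only, via the step-length
  truncation).
* Quantitatively, the faithful solution of these equations at the stated
  parameters smooths the desk-scale base case with `tau ~ 0.5 hr`,
  a factor ~5 below the experimental 2.5 hr. The discrepancy is robust
  to resolution, domain size, discretization form and amplitude
  convention (see self-convergence above), so it reflects the continuum
  model with these parameters rather than a numerical artifact; the
  qualitative machinery (orderings with wavelength and pore size,
  knockout outcomes, sign and origin of the velocity gap, tau' ~ tau) is
  insensitive to it.
* The exponential-fit `t0` is ill-posed on clean traces without the
  documented guards; changing the guard parameters moves `tau` by ~10%.
* At `dx = 20 um` the front foot (width ~ `Db/v` ~ 10 um) is
  under-resolved; refinement checks bound the effect on `tau` at <15%.
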