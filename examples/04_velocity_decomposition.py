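"""Why valleys catch up: forcing versus response along the leading edge.

Runs a shortened base case, extracts the leading edge mid-smoothing, and
splits the chemotactic velocity v_cx = chi * f'(c) * dc/dx into its two
factors at the peak and valley rows.  The nutrient gradient (forcing) is
stronger at the peak, but receptor saturation makes the response f' so
much weaker there that the valley wins -- the signature of chemotactic
smoothing.
"""

import numpy as np

from chemosmooth import (
    RunConfig,
    decompose_at_edge,
    extract_leading_edge,
    run_case,
    velocity_gap,
)
from chemosmooth.decomposition import contour_spacing_at_rows

cfg = RunConfig(max_time=2 * 3600.0, stop_amplitude_frac=None)
res = run_case(cfg)
grid = cfg.grid()

k = np.argmin(np.abs(res.sim.times - 2700.0))  # ~45 min, mid-smoothing
b = np.asarray(res.sim.b[k], dtype=float)
c = np.asarray(res.sim.c[k], dtype=float)
edge = extract_leading_edge(b, 0.003, grid, t=res.sim.times[k])
prof = decompose_at_edge(b, c, edge, grid, cfg.params, cfg.medium)

for label, j in (("peak  ", prof.j_peak), ("valley", prof.j_valley)):
    print(f"{label}: y = {prof.y[j]:5.0f} um  edge x = {prof.x_edge[j]:6.0f} um  "
          f"c = {prof.c_edge[j]:8.1f} uM  dc/dx = {prof.dcdx_edge[j]:6.2f} uM/um  "
          f"f' = {prof.fprime_edge[j]:.4f} /uM  v_cx = {prof.vcx_edge[j]:.4f} um/s")

gap = velocity_gap(prof)
print(f"\nvalley - peak velocity gap: {gap:+.4f} um/s "
      f"({'smoothing' if gap > 0 else 'amplifying'})")

spacing = contour_spacing_at_rows(c, grid, cfg.params,
                                  [0, grid.ny // 2])
print(f"c- to c+ contour spacing: valley {spacing[0]:.0f} um, "
      f"peak {spacing[grid.ny // 2]:.0f} um")
print("-> contours bunch at the peak (stronger forcing there), yet the"
      "\n   saturated response still hands the valley the larger velocity.")
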