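"""Run output: HDF5 snapshot container, CSV traces, JSON summaries."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .front_analysis import apply_starvation_signal
from .synthetic_inputs import render_image_stack

__all__ = ["write_run", "write_snapshots_h5", "load_snapshots_h5"]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_snapshots_h5(path, sim, grid) -> None:
    """Datasets /b/<k>, /c/<k>, /t, /tprime with grid attributes."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("t", data=np.asarray(sim.times))
        h5.create_dataset("tprime", data=sim.tprime)
        gb = h5.create_group("b")
        gc = h5.create_group("c")
        for k, (b, c) in enumerate(zip(sim.b, sim.c)):
            gb.create_dataset(f"{k:04d}", data=b)
            gc.create_dataset(f"{k:04d}", data=c)
        h5.attrs.update(dx=grid.dx, Lx=grid.Lx, Ly=grid.Ly,
                        nx=grid.nx, ny=grid.ny)


def load_snapshots_h5(path):
    """Inverse of :func:`write_snapshots_h5`; returns (times, b, c, tprime, attrs)."""
    import h5py

    with h5py.File(path, "r") as h5:
        times = h5["t"][...]
        tprime = h5["tprime"][...]
        keys = sorted(h5["b"])
        b = [h5["b"][k][...] for k in keys]
        c = [h5["c"][k][...] for k in keys]
        attrs = dict(h5.attrs)
    return times, b, c, tprime, attrs


def write_run(result, out_dir, *, fields: bool = True,
              images: bool = False) -> Path:
    """Persist a :class:`~chemosmooth.driver.RunResult` to a directory.

    Writes ``summary.json``, ``front_trace.csv`` (t_s, A_um, Rf_um),
    ``velocity_gap.csv`` (dt_s, dvcx_um_per_s), optionally the full
    snapshot container ``snapshots.h5`` and a fluorescence-like
    ``signal.tif`` stack.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    summary = result.summary()
    fit = result.fit
    if fit is not None:
        summary["fit"] = {k: _jsonable(v) for k, v in
                          dataclasses.asdict(fit).items()}
    (out / "summary.json").write_text(
        json.dumps({k: _jsonable(v) for k, v in summary.items()}, indent=2,
                   default=_jsonable) + "\n")

    pd.DataFrame({"t_s": result.trace.times, "A_um": result.trace.A,
                  "Rf_um": result.trace.Rf}).to_csv(
        out / "front_trace.csv", index=False)
    pd.DataFrame({"dt_s": result.gap_times,
                  "dvcx_um_per_s": result.gap_values,
                  "dvcx_cell_um_per_s": result.gap_values_cell}).to_csv(
        out / "velocity_gap.csv", index=False)

    if fields:
        write_snapshots_h5(out / "snapshots.h5", result.sim, cfg.grid())
    if images:
        snaps = result.sim.b
        if cfg.apply_signal_loss:
            snaps = apply_starvation_signal(result.sim.times, snaps,
                                            result.sim.tprime, cfg.params)
        render_image_stack(snaps, path=out / "signal.tif")
    return out
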