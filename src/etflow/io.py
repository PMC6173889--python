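"""Plain-text output writers: legacy-ASCII VTK rectilinear grids for field
snapshots and CSV tables for trajectories and summaries."""

from __future__ import annotations

import os

import numpy as np

from .metrics import summary_frame, trajectories_frame


def write_vtk_rectilinear(path, mesh, cell_fields: dict) -> None:
    """Write cell-centred fields on the tensor mesh as legacy ASCII VTK."""
    nx1, ny1 = mesh.xf.size, mesh.yf.size
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\netflow snapshot\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx1} {ny1} 1\n")
        fh.write(f"X_COORDINATES {nx1} double\n")
        fh.write(" ".join(f"{x:.8g}" for x in mesh.xf) + "\n")
        fh.write(f"Y_COORDINATES {ny1} double\n")
        fh.write(" ".join(f"{y:.8g}" for y in mesh.yf) + "\n")
        fh.write("Z_COORDINATES 1 double\n0\n")
        fh.write(f"CELL_DATA {(nx1 - 1) * (ny1 - 1)}\n")
        for name, arr in cell_fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.asarray(arr, float).ravel().tofile(fh, sep="\n", format="%.8g")
            fh.write("\n")


def write_run(result, outdir: str) -> None:
    """Persist one run: config copy, CSV tables and a VTK series."""
    os.makedirs(outdir, exist_ok=True)
    result.config.to_yaml(os.path.join(outdir, "config.yaml"))
    trajectories_frame(result.trajectories).to_csv(
        os.path.join(outdir, "trajectories.csv"), index=False)
    result.force_series.to_csv(os.path.join(outdir, "force.csv"), index=False)
    result.budget_log.to_csv(os.path.join(outdir, "budget.csv"), index=False)
    summary_frame([result.summary]).to_csv(
        os.path.join(outdir, "summary.csv"), index=False)
    vtkdir = os.path.join(outdir, "vtk")
    os.makedirs(vtkdir, exist_ok=True)
    for k, snap in enumerate(result.snapshots):
        write_vtk_rectilinear(
            os.path.join(vtkdir, f"flow_{k:04d}.vtk"), result.mesh,
            dict(u=snap.u, v=snap.v, p=snap.p, alpha=snap.alpha,
                 fluid=snap.is_fluid.astype(float)))
    with open(os.path.join(outdir, "contour.csv"), "w") as fh:
        fh.write("contour,x_mm,y_mm\n")
        for k, poly in enumerate(result.pattern.contours):
            for x, y in poly:
                fh.write(f"{k},{x:.6g},{y:.6g}\n")
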