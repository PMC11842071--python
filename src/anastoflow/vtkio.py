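"""Legacy-VTK (ASCII structured points) field export and CSV table writers.

Legacy ASCII was chosen over XML-VTK so round-trips are testable without a
VTK dependency; files open directly in ParaView-class viewers. Velocities
are interpolated from the staggered faces to cell centres; the fluid mask
rides along as an integer array. All writers emit deterministic bytes for
deterministic inputs (%.6g formatting, fixed column and row order).
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .geometry import AnastomosisGeometry
from .units import MM_TO_M

__all__ = ["frame_point_data", "write_vtk_frame", "read_vtk_frame",
           "write_waveform_csv", "write_table"]


def frame_point_data(frame, geom: AnastomosisGeometry) -> dict:
    """Cell-centred point arrays (u, v, speed, p, mask) for one frame."""
    u = 0.5 * (frame.u[:, :-1] + frame.u[:, 1:])
    v = 0.5 * (frame.v[:-1, :] + frame.v[1:, :])
    mask = geom.fluid_mask
    u = np.where(mask, u, 0.0)
    v = np.where(mask, v, 0.0)
    p = np.where(mask, frame.p, 0.0)
    return {"u": u, "v": v, "speed": np.hypot(u, v), "p": p,
            "mask": mask.astype(np.int8)}


def write_vtk_frame(frame, geom: AnastomosisGeometry, path) -> None:
    """One legacy-VTK STRUCTURED_POINTS file with point data arrays."""
    data = frame_point_data(frame, geom)
    ny, nx = geom.fluid_mask.shape
    x0, y0 = geom.origin
    h_m = geom.h * MM_TO_M
    lines = [
        "# vtk DataFile Version 3.0",
        f"anastoflow frame t={frame.t:.6g}s",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {(x0 + 0.5 * geom.h) * MM_TO_M:.9g} "
        f"{(y0 + 0.5 * geom.h) * MM_TO_M:.9g} 0",
        f"SPACING {h_m:.9g} {h_m:.9g} {h_m:.9g}",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in data.items():
        dtype = "int" if arr.dtype.kind in "iu" else "double"
        lines.append(f"SCALARS {name} {dtype} 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.ravel(order="C")
        fmt = (lambda x: str(int(x))) if dtype == "int" else (lambda x: f"{x:.9g}")
        for k in range(0, flat.size, 9):
            lines.append(" ".join(fmt(x) for x in flat[k:k + 9]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_frame(path) -> dict:
    """Parse a file written by :func:`write_vtk_frame` back into arrays."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    dims = None
    arrays = {}
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("DIMENSIONS"):
            nx, ny, _ = (int(x) for x in ln.split()[1:])
            dims = (ny, nx)
        elif ln.startswith("SCALARS"):
            _, name, dtype, _ = ln.split()
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while i < len(lines) and lines[i] and not lines[i].startswith("SCALARS"):
                vals.extend(lines[i].split())
                i += 1
            arr = np.array(vals, dtype=float if dtype == "double" else int)
            arrays[name] = arr.reshape(dims)
            continue
        i += 1
    return arrays


def write_waveform_csv(waveform, path) -> None:
    """Waveform export: (t_s, value, unit) rows."""
    df = pd.DataFrame({"t_s": waveform.times, "value": waveform.values,
                       "unit": waveform.unit})
    write_table(df, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV: %.6g numeric formatting, fixed column order."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
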