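"""Readers and writers for the package's on-disk formats.

Surface meshes go out as ASCII STL (geometry only) and legacy ASCII VTK
PolyData (geometry + integer region labels + optional point data); WSS time
series as a VTK file-per-step collection with a ``.series`` index, or as one
wide CSV; centerlines, plane series, diameter tables and cohort tables as
plain CSV with documented headers. Only the formats written here are read
back; these are simple line-oriented text formats and no general-purpose
parser is attempted.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Centerline,
    DiameterTable,
    LabeledSurfaceMesh,
    PlaneSeries,
    WSSSeries,
)

__all__ = [
    "write_stl",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_wss_vtk_series",
    "write_wss_csv",
    "read_wss_csv",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_plane_series_csv",
    "write_diameter_table_csv",
    "read_diameter_table_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_stl(mesh: LabeledSurfaceMesh, path) -> None:
    """ASCII STL of the triangulated surface (labels are not representable)."""
    v = mesh.vertices[mesh.triangles]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1)
    n = n / np.where(norm > 0, norm, 1.0)[:, None]
    with open(path, "w") as f:
        f.write("solid dissectwall\n")
        for tri, nn in zip(v, n):
            f.write(f"  facet normal {nn[0]:.6e} {nn[1]:.6e} {nn[2]:.6e}\n")
            f.write("    outer loop\n")
            for p in tri:
                f.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            f.write("    endloop\n  endfacet\n")
        f.write("endsolid dissectwall\n")


def write_vtk_polydata(mesh: LabeledSurfaceMesh, path, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK PolyData with region labels and optional point data.

    Scalars go out as one-component FLOAT arrays, vectors as VECTORS; the
    region label is always written as the integer array ``region``.
    """
    pd_arrays = {"region": mesh.vertex_region}
    pd_arrays.update(point_data or {})
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ndissectwall surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} float\n")
        np.savetxt(f, mesh.vertices, fmt="%.6e")
        m = len(mesh.triangles)
        f.write(f"POLYGONS {m} {4 * m}\n")
        np.savetxt(f, np.column_stack([np.full(m, 3), mesh.triangles]), fmt="%d")
        f.write(f"POINT_DATA {mesh.n_vertices}\n")
        for name, arr in pd_arrays.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%d" if kind == "int" else "%.6e")
            else:
                f.write(f"VECTORS {name} float\n")
                np.savetxt(f, arr, fmt="%.6e")


def read_vtk_polydata(path) -> tuple[LabeledSurfaceMesh, dict[str, np.ndarray]]:
    """Read back a PolyData file written by :func:`write_vtk_polydata`."""
    lines = Path(path).read_text().splitlines()
    i = 0
    points = tris = None
    arrays: dict[str, np.ndarray] = {}
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "POINTS":
            n = int(tok[1])
            points = np.loadtxt(lines[i + 1 : i + 1 + n])
            i += 1 + n
        elif key == "POLYGONS":
            m = int(tok[1])
            raw = np.loadtxt(lines[i + 1 : i + 1 + m], dtype=int)
            tris = raw[:, 1:4]
            i += 1 + m
        elif key == "SCALARS":
            name, kind = tok[1], tok[2]
            n = len(points)
            arrays[name] = np.loadtxt(
                lines[i + 2 : i + 2 + n], dtype=int if kind == "int" else float
            )
            i += 2 + n
        elif key == "VECTORS":
            name = tok[1]
            n = len(points)
            arrays[name] = np.loadtxt(lines[i + 1 : i + 1 + n])
            i += 1 + n
        else:
            i += 1
    region = arrays.pop("region", np.zeros(len(points), dtype=int)).astype(int)
    mesh = LabeledSurfaceMesh(vertices=points, triangles=tris, vertex_region=region)
    return mesh, arrays


def write_wss_vtk_series(mesh: LabeledSurfaceMesh, wss: WSSSeries, out_dir) -> Path:
    """One VTK PolyData per time step (vector point data ``wss_pa``) plus a
    ``wss.series`` JSON index; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, t in enumerate(wss.times):
        name = f"wss_{k:04d}.vtk"
        write_vtk_polydata(mesh, out / name, point_data={"wss_pa": wss.values[:, k, :]})
        entries.append({"name": name, "time": float(t)})
    index = out / "wss.series"
    index.write_text(json.dumps({"file-series-version": "1.0", "files": entries}, indent=1))
    return index


def write_wss_csv(wss: WSSSeries, path) -> None:
    """Wide CSV: vertex, t_s, tau_x_pa, tau_y_pa, tau_z_pa."""
    n_v, n_t, _ = wss.values.shape
    vert = np.repeat(np.arange(n_v), n_t)
    t = np.tile(wss.times, n_v)
    flat = wss.values.reshape(n_v * n_t, 3)
    df = pd.DataFrame(
        {"vertex": vert, "t_s": t, "tau_x_pa": flat[:, 0], "tau_y_pa": flat[:, 1], "tau_z_pa": flat[:, 2]}
    )
    df.to_csv(path, index=False)


def read_wss_csv(path, period: float) -> WSSSeries:
    df = pd.read_csv(path)
    times = np.unique(df["t_s"].to_numpy())
    n_v = df["vertex"].nunique()
    vals = (
        df.sort_values(["vertex", "t_s"])[["tau_x_pa", "tau_y_pa", "tau_z_pa"]]
        .to_numpy()
        .reshape(n_v, len(times), 3)
    )
    return WSSSeries(times=times, values=vals, period=period)


def write_centerline_csv(centerline: Centerline, path) -> None:
    pd.DataFrame(centerline.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    df = pd.read_csv(path)
    return Centerline(points=df[["x_mm", "y_mm", "z_mm"]].to_numpy())


def write_plane_series_csv(planes: PlaneSeries, path) -> None:
    """Long CSV: s_mm, t_s, p_tl_pa, p_fl_pa, q_tl_m3s, q_fl_m3s."""
    rows = []
    for i, s in enumerate(planes.s_mm):
        for k, t in enumerate(planes.times):
            rows.append(
                (s, t, planes.p_tl[i, k], planes.p_fl[i, k], planes.q_tl[i, k], planes.q_fl[i, k])
            )
    pd.DataFrame(
        rows, columns=["s_mm", "t_s", "p_tl_pa", "p_fl_pa", "q_tl_m3s", "q_fl_m3s"]
    ).to_csv(path, index=False)


def write_diameter_table_csv(table: DiameterTable, path) -> None:
    df = pd.DataFrame(table.diameters_mm, columns=["d_prox_mm", "d_mid_mm", "d_dist_mm"])
    df.insert(0, "t_years", table.times_years)
    df.to_csv(path, index=False)


def read_diameter_table_csv(path) -> DiameterTable:
    df = pd.read_csv(path)
    return DiameterTable(
        times_years=df["t_years"].to_numpy(),
        diameters_mm=df[["d_prox_mm", "d_mid_mm", "d_dist_mm"]].to_numpy(),
    )


def write_cohort_csv(records, path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_cohort_csv(path):
    from .synthetic_cohort import CohortRecord

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kw = row.to_dict()
        kw["reintervention"] = bool(kw["reintervention"])
        kw["death"] = bool(kw["death"])
        kw["n_reentry_tears"] = int(kw["n_reentry_tears"])
        records.append(CohortRecord(**kw))
    return records
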