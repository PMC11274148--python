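"""WSS-based hemodynamic wall descriptors and their regional summaries.

Standard literature definitions, frozen here:

    TAWSS = (1/T) int_0^T |tau| dt
    OSI   = 0.5 * (1 - |int_0^T tau dt| / int_0^T |tau| dt)
    RRT   = 1 / ((1 - 2 OSI) * TAWSS)

Time integrals are composite trapezoids on the periodic grid (equivalent to
the sample mean times T on a uniform grid that wraps around). Vertices whose
shear magnitude integrates to zero get OSI = 0 and an undefined (infinite)
RRT: the residence-time surrogate diverges where there is no shear at all,
and where the cycle-mean shear vector vanishes (OSI = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ID_TO_REGION, REGION_TO_ID, LabeledSurfaceMesh, TearGeometry, WSSSeries

__all__ = ["HWDMap", "compute_hwd", "region_summary", "tear_margin_tawss"]


@dataclass
class HWDMap:
    """Per-vertex TAWSS (Pa), OSI (dimensionless) and RRT (1/Pa)."""

    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray


def compute_hwd(series: WSSSeries, on_nonuniform: str = "error") -> HWDMap:
    """Compute TAWSS/OSI/RRT from one cycle of WSS vectors.

    Requires >= 8 samples on a uniform grid spanning the period; non-uniform
    grids are periodically resampled if ``on_nonuniform="resample"``.
    """
    times, values, period = series.times, series.values, series.period
    if len(times) < 8:
        raise ValueError("need at least 8 time samples over the cycle")
    bad = np.argwhere(~np.isfinite(values))
    if len(bad):
        raise ValueError(f"non-finite WSS at vertex {int(bad[0][0])}, sample {int(bad[0][1])}")
    dt = np.diff(np.concatenate([times, [period]]))
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        if on_nonuniform != "resample":
            raise ValueError("non-uniform WSS time grid; pass on_nonuniform='resample'")
        tu = np.linspace(0.0, period, len(times), endpoint=False)
        tp = np.concatenate([times, [period]])
        vp = np.concatenate([values, values[:, :1]], axis=1)
        values = np.stack(
            [
                np.stack([np.interp(tu, tp, vp[v, :, k]) for k in range(3)], axis=-1)
                for v in range(values.shape[0])
            ]
        )
        times = tu

    # periodic trapezoid: append the wrap-around sample
    vp = np.concatenate([values, values[:, :1]], axis=1)
    tp = np.concatenate([times, [period]])
    mag = np.linalg.norm(vp, axis=2)
    int_mag = np.trapezoid(mag, tp, axis=1)
    int_vec = np.trapezoid(vp, tp[None, :, None], axis=1)
    mean_vec_mag = np.linalg.norm(int_vec, axis=1)

    tawss = int_mag / period
    with np.errstate(invalid="ignore", divide="ignore"):
        osi = np.where(int_mag > 0, 0.5 * (1.0 - mean_vec_mag / int_mag), 0.0)
    osi = np.clip(osi, 0.0, 0.5)
    denom = (1.0 - 2.0 * osi) * tawss
    # denominators at round-off scale mean full reversal: infinite residence
    tiny = 1e-12 * np.maximum(tawss, 1.0)
    rrt = np.where(denom > tiny, 1.0 / np.where(denom > tiny, denom, 1.0), np.inf)
    return HWDMap(tawss=tawss, osi=osi, rrt=rrt)


def region_summary(
    hwd: HWDMap,
    mesh: LabeledSurfaceMesh,
    extra_groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Area-weighted per-region descriptor summary.

    Vertex weights are one third of the incident triangle areas. Beyond the
    raw labels, a combined ``descending`` row (TL + FL wall) is always
    reported; further label groupings can be supplied via ``extra_groups``.
    Regions with no vertices are simply absent from the table.
    """
    weights = mesh.vertex_areas()
    groups: dict[str, np.ndarray] = {}
    for rid in np.unique(mesh.vertex_region):
        groups[ID_TO_REGION[int(rid)]] = mesh.vertex_region == rid
    groups["descending"] = mesh.region_mask("TL", "FL")
    for name, labels in (extra_groups or {}).items():
        groups[name] = mesh.region_mask(*labels)

    rows = []
    for name, mask in groups.items():
        if not mask.any():
            continue
        w = weights[mask]
        wsum = w.sum()
        finite_rrt = hwd.rrt[mask][np.isfinite(hwd.rrt[mask])]
        w_rrt = w[np.isfinite(hwd.rrt[mask])]
        rows.append(
            {
                "region": name,
                "area_mm2": wsum,
                "mean_tawss_pa": float(np.sum(w * hwd.tawss[mask]) / wsum),
                "peak_tawss_pa": float(hwd.tawss[mask].max()),
                "mean_osi": float(np.sum(w * hwd.osi[mask]) / wsum),
                "mean_rrt_inv_pa": (
                    float(np.sum(w_rrt * finite_rrt) / w_rrt.sum())
                    if len(finite_rrt)
                    else float("inf")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def tear_margin_tawss(
    hwd: HWDMap,
    tear: TearGeometry,
    mesh: LabeledSurfaceMesh,
    method: str = "peak_times_perimeter",
) -> float:
    """Entry-tear TAWSS distributed over the tear margins, Pa mm.

    Default: (peak TAWSS over tear_margin vertices) x (tear perimeter).
    ``method="line_integral"`` instead integrates TAWSS along the margin rim
    polyline (trapezoid over the closed loop).
    """
    if tear.perimeter_mm <= 0:
        raise ValueError("tear perimeter must be positive")
    mask = mesh.vertex_region == REGION_TO_ID["tear_margin"]
    if not mask.any():
        raise ValueError("mesh has no tear_margin vertices")
    if method == "peak_times_perimeter":
        return float(hwd.tawss[mask].max() * tear.perimeter_mm)
    if method == "line_integral":
        idx = np.flatnonzero(mask)
        pts = mesh.vertices[idx]
        order = _order_loop(pts)
        pts, vals = pts[order], hwd.tawss[idx][order]
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        return float(np.sum(0.5 * (vals + np.roll(vals, -1)) * seg))
    raise ValueError(f"unknown method {method!r}")


def _order_loop(points: np.ndarray) -> np.ndarray:
    """Order rim points into a closed loop by angle around their best-fit plane."""
    c = points.mean(axis=0)
    q = points - c
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    ang = np.arctan2(q @ vt[1], q @ vt[0])
    return np.argsort(ang)
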