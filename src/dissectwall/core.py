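"""Shared containers for dissected-aorta surfaces, centerlines and field samples.

Every spatial quantity is carried in millimetres unless the attribute name says
otherwise; wall shear stress is in Pa, pressure in Pa, volumetric flux in m^3/s,
time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Region labels, in the order used for integer encoding in VTK output.
REGIONS: tuple[str, ...] = (
    "ascending",
    "arch",
    "branch1",
    "branch2",
    "branch3",
    "TL",
    "FL",
    "flap",
    "tear_margin",
)

REGION_TO_ID: dict[str, int] = {name: i for i, name in enumerate(REGIONS)}
ID_TO_REGION: dict[int, str] = {i: name for i, name in enumerate(REGIONS)}


@dataclass
class LabeledSurfaceMesh:
    """Triangulated aortic lumen wall with per-vertex region labels.

    The descending aorta is split by a zero-thickness intimal flap into a true
    lumen (TL) and a false lumen (FL); the flap sheet carries the ``flap``
    label and the rim of the entry tear carries ``tear_margin``.
    """

    vertices: np.ndarray  # (n, 3) float, mm
    triangles: np.ndarray  # (m, 3) int
    vertex_region: np.ndarray  # (n,) int, indexes REGIONS
    outlet_caps: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)
    #: unit axial (streamwise) direction per vertex, filled by the generator
    vertex_axial: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def region_mask(self, *names: str) -> np.ndarray:
        ids = [REGION_TO_ID[n] for n in names]
        return np.isin(self.vertex_region, ids)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Lumped vertex areas: one third of each incident triangle."""
        tri_area = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.triangles.ravel(), np.repeat(tri_area / 3.0, 3))
        return out

    def vertex_normals(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.triangles[:, k], cross)
        norm = np.linalg.norm(out, axis=1)
        norm[norm == 0] = 1.0
        return out / norm[:, None]

    def edge_incidence(self) -> dict[tuple[int, int], int]:
        """Count of incident triangles per undirected edge."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return {tuple(edge): int(c) for edge, c in zip(uniq, counts)}


@dataclass
class Centerline:
    """Ordered vessel centerline polyline with cumulative arclength (mm).

    ``markers`` maps anatomical segment names to (start, end) arclength spans;
    the generator fills ``ascending``, ``arch``, ``descending`` and
    ``dissected`` (the axial extent of the flap).
    """

    points: np.ndarray  # (n, 3) mm
    markers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least two points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arclength must be strictly increasing")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        return np.array(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.arclength, s) - 1, 0, len(self.points) - 2))
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)


@dataclass
class WSSSeries:
    """Per-vertex wall shear stress vectors over one cardiac cycle.

    ``times`` is a uniform open grid on [0, T): times[0] = 0, times[-1] < T.
    ``values`` has shape (n_vertices, n_times, 3), Pa.
    """

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0.0 or self.times[-1] >= self.period:
            raise ValueError("times must start at 0 and stay below the period")
        if self.values.ndim != 3 or self.values.shape[1] != len(self.times):
            raise ValueError("values must have shape (n_vertices, n_times, 3)")


@dataclass
class PlaneSeries:
    """Per-plane lumen-averaged pressure and volumetric flux time series.

    Planes are normal to the centerline at arclengths ``s_mm`` (measured along
    the descending aorta). Pressures are Pa; fluxes m^3/s. Arrays are
    (n_planes, n_times); FL columns are NaN where no dissection exists.
    """

    s_mm: np.ndarray
    times: np.ndarray
    p_tl: np.ndarray
    p_fl: np.ndarray
    q_tl: np.ndarray
    q_fl: np.ndarray

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        if len(self.s_mm) < 3:
            raise ValueError("need at least three analysis planes")
        for name in ("p_tl", "p_fl", "q_tl", "q_fl"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.s_mm), len(self.times)):
                raise ValueError(f"{name} must be (n_planes, n_times)")
            setattr(self, name, arr)

    def total_flux(self) -> np.ndarray:
        """TL + FL flux per plane and time (FL NaN treated as zero)."""
        return self.q_tl + np.nan_to_num(self.q_fl)


@dataclass
class DiameterTable:
    """Longitudinal aortic diameters at the three surveillance planes.

    ``times_years`` are scan times from baseline; ``diameters_mm`` is
    (n_scans, 3) for the proximal, mid and distal descending planes.
    """

    times_years: np.ndarray
    diameters_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times_years = np.asarray(self.times_years, dtype=float)
        self.diameters_mm = np.atleast_2d(np.asarray(self.diameters_mm, dtype=float))
        if len(self.times_years) < 2:
            raise ValueError("need at least two scans to assess growth")
        if self.diameters_mm.shape[0] != len(self.times_years):
            raise ValueError("one diameter row per scan required")
        if np.any(self.diameters_mm <= 0):
            raise ValueError("diameters must be positive")


@dataclass
class TearGeometry:
    """Entry tear dimensions and derived circle-equivalent area/perimeter."""

    height_mm: float
    width_mm: float
    area_mm2: float
    perimeter_mm: float
    arclength_mm: float = float("nan")
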