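"""Geometric characterization of a dissected aorta.

Tortuosity (arc-chord ratio of the centerline), cross-sectional lumen areas by
plane slicing of the labeled surface, the TL/DA area ratio averaged over the
three surveillance planes, circle-equivalent entry-tear metrics, and the
growth-rate classification separating stable from rapidly growing aortas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import REGION_TO_ID, Centerline, DiameterTable, LabeledSurfaceMesh, TearGeometry

__all__ = [
    "SectionAreas",
    "GrowthResult",
    "tortuosity",
    "section_areas",
    "tl_da_ratio",
    "tear_metrics",
    "classify_growth",
    "default_plane_arclengths",
]

#: anatomical surveillance planes as fractions of the dissected descending span
DEFAULT_PLANE_FRACTIONS = (0.15, 0.5, 0.85)

RAPID_GROWTH_THRESHOLD_MM_YR = 3.0


@dataclass(frozen=True)
class SectionAreas:
    """Cross-sectional lumen areas (mm^2) at one analysis plane."""

    tl_area: float
    fl_area: float
    total_area: float
    equivalent_diameter: float


@dataclass(frozen=True)
class GrowthResult:
    """Per-plane diameter growth rates (mm/yr) and the rapid/stable label."""

    rates: tuple[float, ...]
    max_rate: float
    label: str


def tortuosity(centerline: Centerline) -> float:
    """Centerline arclength over the inlet-to-outlet straight distance (>= 1)."""
    chord = np.linalg.norm(centerline.points[-1] - centerline.points[0])
    if chord <= 1e-9 * centerline.length:
        raise ValueError("tortuosity undefined: coincident centerline endpoints")
    return float(centerline.length / chord)


def tear_metrics(
    height_mm: float,
    width_mm: float,
    arclength_mm: float = float("nan"),
    method: str = "mean_diameter",
) -> TearGeometry:
    """Circle-equivalent tear area and perimeter from height and width.

    Default treats the tear as a circle of diameter d = (h + w)/2 (exact when
    h = w). ``method="ellipse"`` uses the ellipse area pi h w / 4 with the
    Ramanujan perimeter approximation instead.
    """
    if height_mm <= 0 or width_mm <= 0:
        raise ValueError("tear height and width must be positive")
    if method == "mean_diameter":
        d = 0.5 * (height_mm + width_mm)
        area = np.pi * d**2 / 4.0
        perim = np.pi * d
    elif method == "ellipse":
        a, b = height_mm / 2.0, width_mm / 2.0
        area = np.pi * a * b
        h = (a - b) ** 2 / (a + b) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TearGeometry(
        height_mm=height_mm,
        width_mm=width_mm,
        area_mm2=float(area),
        perimeter_mm=float(perim),
        arclength_mm=arclength_mm,
    )


def classify_growth(
    table: DiameterTable, threshold_mm_yr: float = RAPID_GROWTH_THRESHOLD_MM_YR
) -> GrowthResult:
    """Endpoint growth rate per plane; rapid iff any rate >= threshold.

    The rate is the diameter change between first and last scan over the
    surveillance interval (two-point slope, mirroring clinical reading of the
    baseline and latest scan).
    """
    dt = table.times_years[-1] - table.times_years[0]
    if dt <= 0:
        raise ValueError("scans must span a positive surveillance interval")
    rates = (table.diameters_mm[-1] - table.diameters_mm[0]) / dt
    max_rate = float(np.max(rates))
    label = "rapid" if max_rate >= threshold_mm_yr else "stable"
    return GrowthResult(rates=tuple(float(r) for r in rates), max_rate=max_rate, label=label)


def default_plane_arclengths(centerline: Centerline) -> np.ndarray:
    """Surveillance plane arclengths (mm) at the default fractions of the
    dissected descending span."""
    s0, s1 = centerline.markers.get(
        "dissected", centerline.markers.get("descending", (0.0, centerline.length))
    )
    return s0 + np.asarray(DEFAULT_PLANE_FRACTIONS) * (s1 - s0)


def tl_da_ratio(
    mesh: LabeledSurfaceMesh,
    centerline: Centerline,
    plane_arclengths=None,
) -> float:
    """TL/(TL+FL) area ratio averaged over the three surveillance planes."""
    if plane_arclengths is None:
        plane_arclengths = default_plane_arclengths(centerline)
    ratios = []
    for s in plane_arclengths:
        sec = section_areas(mesh, centerline, s)
        ratios.append(sec.tl_area / sec.total_area)
    return float(np.mean(ratios))


def section_areas(
    mesh: LabeledSurfaceMesh, centerline: Centerline, s: float
) -> SectionAreas:
    """Slice the lumen wall with the plane normal to the centerline at s (mm).

    The outer-wall intersection is chained into a closed polygon (shoelace
    area); the flap intersection, if present, is a chord polyline splitting
    the polygon into the TL and FL sub-areas, which therefore sum exactly to
    the total. Without a flap crossing the whole section is assigned to TL.
    """
    if not 0 <= s <= centerline.length:
        raise ValueError("plane arclength outside the centerline span")
    p0 = centerline.point_at(s)
    normal = centerline.tangent_at(s)

    flap_ids = {REGION_TO_ID["flap"], REGION_TO_ID["tear_margin"]}
    tri_labels = mesh.vertex_region[mesh.triangles]
    is_flap_tri = np.isin(tri_labels, list(flap_ids)).all(axis=1)

    wall_segs = _slice_triangles(mesh, ~is_flap_tri, p0, normal)
    if not wall_segs:
        raise ValueError(f"plane at s={s} mm does not intersect the wall")
    loops = _chain_segments(wall_segs)
    closed = [lp for lp, is_closed in loops if is_closed and len(lp) >= 3]
    if not closed:
        raise ValueError(f"open wall contour after slicing at s={s} mm")
    # keep the loop nearest the centerline point (the plane may graze other limbs)
    pts_of = lambda lp: np.array([p for p, _ in lp])
    loop = min(closed, key=lambda lp: np.linalg.norm(pts_of(lp).mean(axis=0) - p0))

    e1 = _any_perpendicular(normal)
    e2 = np.cross(normal, e1)
    to2d = lambda pts: np.column_stack([(pts - p0) @ e1, (pts - p0) @ e2])
    poly = to2d(pts_of(loop))
    total = abs(_shoelace(poly))
    eq_diam = 2.0 * np.sqrt(total / np.pi)

    flap_segs = _slice_triangles(mesh, is_flap_tri, p0, normal)
    if not flap_segs:
        return SectionAreas(total, 0.0, total, eq_diam)

    # the flap trace is a straight chord (possibly interrupted by the tear
    # hole): its extreme intersection points define the lumen divider
    fpts = np.array([p for seg in flap_segs for p in (seg[0][1], seg[1][1])])
    f2d = to2d(fpts)
    d2 = np.sum((f2d[:, None, :] - f2d[None, :, :]) ** 2, axis=2)
    i_a, i_b = np.unravel_index(np.argmax(d2), d2.shape)
    chord = np.array([f2d[i_a], f2d[i_b]])
    labels = np.array([lab for _, lab in loop])
    tl_area, fl_area = _split_by_chord(poly, labels, chord, mesh)
    return SectionAreas(tl_area, fl_area, total, eq_diam)


# ---------------------------------------------------------------- helpers


def _slice_triangles(mesh, tri_mask, p0, normal):
    """Plane-triangle intersection segments as ((pt, label), (pt, label)) pairs.

    Each endpoint lies on a mesh edge and is tagged with the region label of
    its nearer edge vertex, so contour arcs inherit wall labels.
    """
    d = (mesh.vertices - p0) @ normal
    # nudge vertices lying exactly on the plane so every crossing is strict
    span = np.ptp(d) or 1.0
    d = np.where(d == 0.0, 1e-9 * span, d)
    tris = mesh.triangles[tri_mask]
    dv = d[tris]
    crossing = (dv.max(axis=1) > 0) & (dv.min(axis=1) < 0)
    segs = []
    for tri, dd in zip(tris[crossing], dv[crossing]):
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dd[a], dd[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                p = mesh.vertices[tri[a]] + t * (mesh.vertices[tri[b]] - mesh.vertices[tri[a]])
                lab = mesh.vertex_region[tri[a] if t < 0.5 else tri[b]]
                key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
                pts.append((key, p, int(lab)))
        if len(pts) == 2:
            segs.append(tuple(pts))
    return segs


def _chain_segments(segs):
    """Chain edge-keyed segments into polylines; returns [(points, closed)].

    Points are (xyz, label) tuples; matching uses the shared-edge key so
    adjacent triangles connect exactly.
    """
    from collections import defaultdict

    adj = defaultdict(list)
    for i, (a, b) in enumerate(segs):
        adj[a[0]].append(i)
        adj[b[0]].append(i)
    used = [False] * len(segs)
    chains = []
    for start in range(len(segs)):
        if used[start]:
            continue
        used[start] = True
        a, b = segs[start]
        chain = [a, b]
        for head in (1, 0):  # extend forward then backward
            while True:
                key = chain[-1][0] if head else chain[0][0]
                nxt = [i for i in adj[key] if not used[i]]
                if not nxt:
                    break
                i = nxt[0]
                used[i] = True
                c, d_ = segs[i]
                new = d_ if c[0] == key else c
                chain.append(new) if head else chain.insert(0, new)
        closed = chain[0][0] == chain[-1][0] and len(chain) > 3
        pts = chain[:-1] if closed else chain
        chains.append(([(p, lab) for _, p, lab in pts], closed))
    return chains


def _any_perpendicular(n):
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(n, ref)
    return v / np.linalg.norm(v)


def _shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def _project_on_polygon(poly, p):
    """(edge index, projected point) of the closest point on the polygon."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    k = int(np.argmin(d))
    return k, proj[k]


def _split_by_chord(poly, labels, chord, mesh):
    """Split the outer polygon by the flap chord; return (TL, FL) areas.

    The chord endpoints are projected onto the nearest polygon edges and
    inserted as new vertices, so the two arc+chord polygons partition the
    total area without angular quantization. TL is the side whose wall arc
    carries the majority of TL labels.
    """
    ends = (chord[0], chord[-1])
    hits = [_project_on_polygon(poly, e) for e in ends]
    # insert projected points after their edges (careful with shared indexing)
    order = np.argsort([h[0] for h in hits])
    pts = list(map(tuple, poly))
    labs = list(labels)
    inserted = []
    shift = 0
    for oi in order:
        k, proj = hits[oi]
        pos = k + 1 + shift
        pts.insert(pos, tuple(proj))
        labs.insert(pos, -1)
        inserted.append(pos)
        shift += 1
    poly = np.asarray(pts)
    labels = np.asarray(labs)
    n = len(poly)
    i, j = sorted(inserted)
    if i == j:
        return (abs(_shoelace(poly)), 0.0)
    arc1 = list(range(i, j + 1))
    arc2 = list(range(j, n)) + list(range(0, i + 1))
    a1 = abs(_shoelace(poly[arc1]))
    a2 = abs(_shoelace(poly[arc2]))
    tl_id = REGION_TO_ID["TL"]
    tl_votes1 = np.mean(labels[arc1] == tl_id)
    tl_votes2 = np.mean(labels[arc2] == tl_id)
    if tl_votes1 >= tl_votes2:
        return (a1, a2)
    return (a2, a1)
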