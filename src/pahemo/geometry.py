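"""Quantification of vascular surface meshes.

Centerlines with maximal-inscribed-sphere radii, per-segment lengths and
mean diameters, the LPA/RPA bifurcation angle and regional surface areas —
the geometric parameters summarised for each animal in the cohort tables.

The centerline is computed as a shortest path on a wall-distance-weighted
graph over interior voxels (heavily penalising proximity to the wall, which
drives the path onto the medial axis), followed by a local medial-ascent
refinement of every path point against the exact triangulated surface.  The
accuracy contract, not the algorithm, is the interface: on a straight tube
the result is the axis and the radii are the tube radius.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy import ndimage

from .errors import ConnectivityError, DegeneracyError, DomainError
from .mesh import CAP_REGIONS, SurfaceMesh, surface_area
from .spatial import TriangleDistance, grid_for_bounds, parity_inside

#: Arc-length spacing (mm) at which inscribed diameters are sampled.
DIAMETER_SAMPLING_MM = 0.5

#: Default arc length (mm) over which branch take-off directions are fitted.
TAKEOFF_FIT_MM = 10.0


@dataclass
class Centerline:
    """Ordered polyline through a vessel with inscribed-sphere radii (mm)."""

    points: np.ndarray
    radii: np.ndarray
    branch: str = "VESSEL"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.points) < 2:
            raise DomainError("a centerline needs at least two points")
        if len(self.radii) != len(self.points):
            raise DomainError("one radius per centerline point required")
        if not (self.radii > 0).all():
            raise DomainError("centerline radii must be positive")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length (mm), zero at the first point."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def at(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Point(s) and radius(-i) at arc length ``s`` by linear interpolation."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        al = self.arc_length
        if (s < al[0] - 1e-9).any() or (s > al[-1] + 1e-9).any():
            raise DomainError("arc length outside centerline extent")
        s = np.clip(s, al[0], al[-1])
        pts = np.stack([np.interp(s, al, self.points[:, i]) for i in range(3)], axis=-1)
        rad = np.interp(s, al, self.radii)
        return pts, rad

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), self.radii[::-1].copy(), self.branch)

    def to_csv(self, path, branch: str | None = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["branch", "point_index", "x", "y", "z", "radius"])
            for i, (p, r) in enumerate(zip(self.points, self.radii)):
                w.writerow([branch or self.branch, i, *(f"{c:.9g}" for c in p), f"{r:.9g}"])


def centerlines_to_csv(centerlines, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["branch", "point_index", "x", "y", "z", "radius"])
        for cl in centerlines:
            for i, (p, r) in enumerate(zip(cl.points, cl.radii)):
                w.writerow([cl.branch, i, *(f"{c:.9g}" for c in p), f"{r:.9g}"])


def centerlines_from_csv(path) -> list[Centerline]:
    rows = list(csv.DictReader(open(path)))
    out = []
    for branch in dict.fromkeys(r["branch"] for r in rows):
        rr = [r for r in rows if r["branch"] == branch]
        pts = np.array([[float(r["x"]), float(r["y"]), float(r["z"])] for r in rr])
        rad = np.array([float(r["radius"]) for r in rr])
        out.append(Centerline(pts, rad, branch))
    return out


@dataclass
class VesselSegment:
    """Length, mean diameter and surface area of a labelled vessel segment."""

    label: str
    length_mm: float
    diameter_mm: float
    area_cm2: float
    side_branch_count: int = 0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.diameter_mm <= 0:
            raise DomainError("segment length and diameter must be positive")


@dataclass
class BifurcationMeasure:
    """Angle (degrees) between the LPA and RPA take-off directions."""

    angle_deg: float
    fit_length_mm: float = TAKEOFF_FIT_MM

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_deg < 180.0):
            raise DomainError(
                f"bifurcation angle {self.angle_deg:.3f} deg is degenerate "
                "(must lie strictly between 0 and 180)"
            )


# ---------------------------------------------------------------------------
# centerline extraction


def _interior_grid(mesh: SurfaceMesh, pitch: float):
    origin, shape = grid_for_bounds(mesh.tm.bounds, pitch, pad=2)
    inside = parity_inside(mesh, origin, pitch, shape)
    wall = ndimage.distance_transform_edt(inside) * pitch
    return origin, shape, inside, wall


def _medial_refine(points, tangents, tdist: TriangleDistance, step0: float, iters: int = 18):
    """Push each point toward the local medial axis.

    Moves each point away from its nearest surface point, restricted to the
    plane perpendicular to the local tangent, with a geometrically shrinking
    step; on a tube cross-section this converges to the inscribed-circle
    centre.
    """
    pts = points.copy()
    step = step0
    for _ in range(iters):
        d, cp, _ = tdist.query(pts)
        g = pts - cp
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        g = np.divide(g, norm, out=np.zeros_like(g), where=norm > 1e-12)
        g -= (g * tangents).sum(axis=1, keepdims=True) * tangents
        pts = pts + step * g
        step *= 0.7
    return pts


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    return t / np.where(n > 1e-12, n, 1.0)


def compute_centerline(
    mesh: SurfaceMesh,
    source: np.ndarray,
    targets,
    branch_labels=None,
    pitch: float | None = None,
) -> list[Centerline]:
    """Extract one centerline per target point.

    Parameters
    ----------
    mesh : watertight lumen surface.
    source : 3-vector on or inside the lumen (e.g. inlet centre).
    targets : iterable of 3-vectors (e.g. outlet centres).
    branch_labels : optional names, one per target.
    pitch : interior voxel pitch (mm); default adapts to the mesh extent.
    """
    mesh.audit()
    source = np.asarray(source, dtype=float)
    targets = [np.asarray(t, dtype=float) for t in np.atleast_2d(targets)]
    if branch_labels is None:
        branch_labels = [f"BRANCH_{i}" for i in range(len(targets))]

    extent = mesh.tm.bounds[1] - mesh.tm.bounds[0]
    if pitch is None:
        pitch = float(max(extent.max() / 140.0, extent.min() / 30.0))
    origin, shape, inside, wall = _interior_grid(mesh, pitch)
    if not inside.any():
        raise ConnectivityError("no interior voxels found (pitch too coarse?)")

    idx = np.argwhere(inside)
    node_of = -np.ones(shape, dtype=np.int64)
    node_of[tuple(idx.T)] = np.arange(len(idx))
    wall_d = wall[tuple(idx.T)]

    # 26-neighbourhood edges, weight = step / midpoint wall distance squared
    offsets = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) > (0, 0, 0)]
    )
    rows, cols, weights = [], [], []
    for off in offsets:
        nb = idx + off
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        nb_ok = nb[ok]
        j = node_of[tuple(nb_ok.T)]
        valid = j >= 0
        i_nodes = np.arange(len(idx))[ok][valid]
        j_nodes = j[valid]
        step = np.linalg.norm(off) * pitch
        dmid = 0.5 * (wall_d[i_nodes] + wall_d[j_nodes])
        rows.append(i_nodes)
        cols.append(j_nodes)
        weights.append(step / (dmid**2 + 1e-9))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(idx), len(idx)),
    )
    graph = graph + graph.T

    def nearest_node(p):
        cell = np.round((p - origin) / pitch).astype(int)
        cell = np.clip(cell, 0, np.asarray(shape) - 1)
        if node_of[tuple(cell)] >= 0:
            return node_of[tuple(cell)]
        # fall back to nearest interior voxel
        d2 = ((idx - (p - origin) / pitch) ** 2).sum(axis=1)
        return int(d2.argmin())

    src_node = nearest_node(source)
    dist, pred = dijkstra(graph, indices=src_node, return_predecessors=True)

    # radii measure the distance to the vessel *wall*: cap faces closing the
    # fluid domain are excluded (when labelled) so end radii stay physical
    wall_faces = np.asarray([l not in CAP_REGIONS for l in mesh.labels], dtype=bool)
    tris = np.asarray(mesh.tm.triangles)
    tdist = TriangleDistance(tris[wall_faces] if wall_faces.any() else tris)
    out = []
    for tgt, lab in zip(targets, branch_labels):
        node = nearest_node(tgt)
        if not np.isfinite(dist[node]):
            raise ConnectivityError(f"target {tgt} unreachable from source")
        chain = [node]
        while pred[chain[-1]] >= 0:
            chain.append(int(pred[chain[-1]]))
        chain = chain[::-1]  # source -> target
        pts = origin + pitch * idx[chain]
        pts = np.vstack([source, pts, tgt])
        # light smoothing before tangent estimation
        if len(pts) > 4:
            kernel = np.array([0.25, 0.5, 0.25])
            sm = pts.copy()
            for ax in range(3):
                sm[1:-1, ax] = np.convolve(pts[:, ax], kernel, mode="valid")
            pts = sm
        tang = _polyline_tangents(pts)
        pts = _medial_refine(pts, tang, tdist, step0=pitch)
        radii = tdist.query(pts)[0]
        keep = radii > 1e-6
        out.append(Centerline(pts[keep], radii[keep], branch=lab))
    return out


# ---------------------------------------------------------------------------
# measurements


def measure_segment(
    centerline: Centerline,
    bounds: tuple[float, float],
    mesh: SurfaceMesh | None = None,
    label: str | None = None,
    ostia=(),
) -> VesselSegment:
    """Measure a centerline interval: length, mean inscribed diameter, area.

    ``bounds`` is an arc-length interval (mm).  The mean diameter averages
    inscribed-sphere diameters sampled every 0.5 mm of arc length.  The
    surface area integrates the faces carrying the segment's label, and the
    side-branch count is the number of ostium loops whose centre projects
    into the interval.
    """
    s0, s1 = float(bounds[0]), float(bounds[1])
    if not (s1 > s0):
        raise DomainError("empty arc-length interval")
    al = centerline.arc_length
    if s0 < al[0] - 1e-9 or s1 > al[-1] + 1e-9:
        raise DomainError("interval outside centerline extent")
    n = max(2, int(np.floor((s1 - s0) / DIAMETER_SAMPLING_MM)) + 1)
    samples = np.linspace(s0, s1, n)
    _, radii = centerline.at(samples)
    lab = label or centerline.branch
    area = 0.0
    if mesh is not None:
        try:
            area = surface_area(mesh, lab)
        except DomainError:
            area = 0.0
    count = 0
    for ost in ostia:
        centre = np.asarray(getattr(ost, "center", ost), dtype=float)
        d2 = ((centerline.points - centre) ** 2).sum(axis=1)
        s_near = al[int(d2.argmin())]
        if s0 <= s_near <= s1:
            count += 1
    return VesselSegment(
        label=lab,
        length_mm=s1 - s0,
        diameter_mm=float(2.0 * radii.mean()),
        area_cm2=area,
        side_branch_count=count,
    )


def _takeoff_direction(cl: Centerline, junction: np.ndarray, fit_length: float) -> np.ndarray:
    """Least-squares take-off direction over ``fit_length`` mm of centerline
    leaving the junction.

    The centerline may extend upstream of the junction (e.g. a full
    inlet-to-outlet path); the fit starts at the point closest to the
    junction and runs toward the far end.
    """
    d = np.linalg.norm(cl.points - junction, axis=1)
    j_idx = int(d.argmin())
    # walk toward whichever end is farther from the junction
    if d[-1] >= d[0]:
        pts = cl.points[j_idx:]
    else:
        pts = cl.points[j_idx::-1]
    if len(pts) < 2:
        raise DegeneracyError("zero-length take-off arc")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    al = np.concatenate([[0.0], np.cumsum(seg)])
    span = min(fit_length, al[-1])
    if span <= 0:
        raise DegeneracyError("zero-length take-off arc")
    sel = pts[al <= span + 1e-9]
    if len(sel) < 2:
        sel = pts[:2]
    centred = sel - sel.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if np.linalg.norm(direction) < 1e-12:
        raise DegeneracyError("degenerate take-off direction")
    # orient away from the junction
    if np.dot(direction, sel[-1] - sel[0]) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def bifurcation_angle(
    left: Centerline,
    right: Centerline,
    junction: np.ndarray,
    fit_length: float = TAKEOFF_FIT_MM,
) -> BifurcationMeasure:
    """Angle between the two branch take-off directions at a junction.

    Symmetric in its arguments.  Degenerate (collinear, 0 or 180 degree)
    configurations are rejected by the :class:`BifurcationMeasure` invariant.
    """
    junction = np.asarray(junction, dtype=float)
    u = _takeoff_direction(left, junction, fit_length)
    v = _takeoff_direction(right, junction, fit_length)
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return BifurcationMeasure(angle_deg=angle, fit_length_mm=fit_length)
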