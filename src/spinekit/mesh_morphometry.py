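"""Per-spine morphological variables computed from triangle meshes.

Five features are extracted for each spine surface: volume, surface area,
length, maximum diameter and neck mean diameter, plus a three-way class
label (mushroom / stubby / thin).  Volume and area come straight from the
mesh; length and the two diameters require a notion of a *spine axis*,
which we build from the geodesic distance field over the mesh surface
seeded at the dendrite attachment point:

1. graph-geodesic distances from the attachment are computed on the edge
   graph (Dijkstra, edge weights = edge lengths);
2. vertices are binned by distance and the per-bin centroids, ordered by
   distance, form the axis polyline from attachment to the most distant
   point (the tip).  Spine length is the polyline arc length;
3. cross-sections perpendicular to the local axis direction are cut at
   equally spaced arc positions; each station's *equivalent diameter* is
   the diameter of the circle with the same area as the intersection loop
   containing the axis point.

The neck is defined as the contiguous run of proximal stations whose
equivalent diameter stays below ``neck_fraction`` (default 0.7) of the
maximum diameter; its mean diameter is the neck mean diameter.  A spine
with no such run has no neck (stubby); one with a neck but a maximum
diameter below the smallest plausible head (default 0.43 µm) is thin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import Point

from .errors import AttachmentError, NotWatertightError, ProfileError, SpinekitError
from .io_formats import TriangleMesh

__all__ = [
    "SpineMorphometry",
    "SpineAxis",
    "CrossSectionProfile",
    "surface_area",
    "enclosed_volume",
    "spine_axis",
    "cross_section_profile",
    "max_diameter",
    "neck_mean_diameter",
    "classify_spine",
    "morphometry",
    "DEFAULT_NECK_FRACTION",
    "DEFAULT_HEAD_THRESHOLD_UM",
]

#: Neck stations are those below this fraction of the maximum diameter.
DEFAULT_NECK_FRACTION = 0.7
#: Smallest head diameter (µm) still classified as a mushroom head.
DEFAULT_HEAD_THRESHOLD_UM = 0.43


@dataclass
class SpineMorphometry:
    """The five per-spine morphological features plus class label (µm units)."""

    volume: float
    area: float
    length: float
    max_diameter: float
    neck_mean_diameter: float | None
    spine_class: str

    def __post_init__(self):
        if not (self.volume > 0 and self.area > 0 and self.length > 0):
            raise SpinekitError("volume, area and length must be positive")
        if self.neck_mean_diameter is not None and not (
            self.max_diameter >= self.neck_mean_diameter
        ):
            raise SpinekitError(
                "neck mean diameter exceeds maximum diameter "
                f"({self.neck_mean_diameter} > {self.max_diameter})"
            )

    def as_features(self) -> dict[str, float]:
        out = {
            "Volume": self.volume,
            "Area": self.area,
            "Length": self.length,
            "MaxDiameter": self.max_diameter,
        }
        if self.neck_mean_diameter is not None:
            out["NeckMeanDiameter"] = self.neck_mean_diameter
        return out


@dataclass
class SpineAxis:
    """Polyline from attachment to tip with cumulative arc positions (µm)."""

    points: np.ndarray          # (k, 3)
    arc_positions: np.ndarray   # (k,), 0 at attachment
    length: float

    def point_at(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        return np.array(
            [np.interp(s, self.arc_positions, self.points[:, i]) for i in range(3)]
        )

    def tangent_at(self, s: float, window: float | None = None) -> np.ndarray:
        """Central-difference tangent; window defaults to length/16."""
        h = window if window is not None else self.length / 16.0
        a = self.point_at(s - h)
        b = self.point_at(s + h)
        d = b - a
        n = np.linalg.norm(d)
        if n == 0.0:  # degenerate: fall back to overall direction
            d = self.points[-1] - self.points[0]
            n = np.linalg.norm(d)
        return d / n


@dataclass
class CrossSectionProfile:
    """Equivalent diameters at ordered arc positions along the spine axis."""

    stations: list[tuple[float, float]]  # (arc position µm, equivalent diameter µm)
    attachment_end: float = 0.0
    tip_end: float = 0.0

    def __post_init__(self):
        pos = [s for s, _ in self.stations]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise SpinekitError("profile arc positions must be strictly increasing")
        if any(d < 0 for _, d in self.stations):
            raise SpinekitError("negative equivalent diameter")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([d for _, d in self.stations])


# ---------------------------------------------------------------------------
# Area / volume
# ---------------------------------------------------------------------------

def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area (µm²): sum of triangle areas, caps included."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _boundary_edge_count(mesh: TriangleMesh) -> int:
    f = mesh.faces
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts != 2).sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (µm³) by the divergence theorem.

    The mesh must be closed and consistently oriented; the signed sum of
    origin tetrahedra is translation invariant for such a surface.
    """
    n_boundary = _boundary_edge_count(mesh)
    if n_boundary:
        raise NotWatertightError(n_boundary)
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum(
        "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
    ).sum() / 6.0
    return float(abs(signed))


# ---------------------------------------------------------------------------
# Axis and cross-sections
# ---------------------------------------------------------------------------

def spine_axis(
    mesh: TriangleMesh,
    attachment,
    n_bins: int = 64,
) -> SpineAxis:
    """Spine axis from the attachment-seeded geodesic distance field.

    The attachment must lie within twice the median edge length of the mesh
    (checked against the nearest vertex).
    """
    attachment = np.asarray(attachment, dtype=float)
    v = mesh.vertices
    f = mesh.faces

    edges = np.unique(
        np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        ),
        axis=0,
    )
    lengths = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    median_edge = float(np.median(lengths))

    d_attach = np.linalg.norm(v - attachment, axis=1)
    seed = int(d_attach.argmin())
    if d_attach[seed] > 2.0 * median_edge:
        raise AttachmentError(
            f"attachment is {d_attach[seed]:.3g} µm from the mesh "
            f"(limit {2 * median_edge:.3g} µm = 2x median edge)"
        )

    n = len(v)
    graph = coo_matrix(
        (lengths, (edges[:, 0], edges[:, 1])), shape=(n, n)
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=seed)
    if not np.isfinite(dist).all():
        raise SpinekitError("mesh edge graph is disconnected")

    tip = int(dist.argmax())
    dmax = float(dist[tip])
    width = dmax / n_bins
    centroids = []
    for k in range(n_bins):
        lo, hi = k * width, (k + 1) * width
        sel = (dist >= lo) & (dist < hi) if k < n_bins - 1 else (dist >= lo)
        if sel.any():
            centroids.append(v[sel].mean(axis=0))

    pts = [attachment] + centroids + [v[tip]]
    points = np.array(pts)
    # drop consecutive duplicates so arc positions stay strictly increasing
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seglen > 1e-12])
    points = points[keep]
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(points, axis=0), axis=1)
    )])
    return SpineAxis(points=points, arc_positions=arc, length=float(arc[-1]))


def _section_equivalent_diameter(tm, origin, normal) -> float | None:
    """Equivalent diameter of the intersection loop containing ``origin``."""
    section = tm.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        return None
    try:
        planar, to_3d = section.to_2D()
    except Exception:
        return None
    polys = planar.polygons_full
    if len(polys) == 0:
        return None
    # map the axis point into section plane coordinates
    inv = np.linalg.inv(to_3d)
    p2 = (inv @ np.append(origin, 1.0))[:2]
    target = Point(p2)
    containing = [pg for pg in polys if pg.contains(target)]
    if containing:
        area = containing[0].area
    else:
        # numerical grazing: fall back to the loop whose boundary is nearest
        area = min(polys, key=lambda pg: pg.exterior.distance(target)).area
    if area <= 0.0:
        return None
    return float(2.0 * np.sqrt(area / np.pi))


def cross_section_profile(
    mesh: TriangleMesh,
    axis: SpineAxis,
    n_stations: int = 32,
    max_fail_fraction: float = 0.2,
) -> CrossSectionProfile:
    """Cut ``n_stations`` planes perpendicular to the axis, evenly spaced.

    Stations are placed at arc positions ``(i + 1/2) / n * length`` so the
    degenerate end planes (tangent to the caps) are never sampled.  Stations
    whose section is empty or has zero area are dropped; if more than
    ``max_fail_fraction`` of stations fail, a :class:`ProfileError` is raised.
    """
    if n_stations < 8:
        raise ValueError("n_stations must be >= 8")
    tm = mesh.to_trimesh()
    L = axis.length
    stations: list[tuple[float, float]] = []
    failed = 0
    for i in range(n_stations):
        s = (i + 0.5) / n_stations * L
        origin = axis.point_at(s)
        normal = axis.tangent_at(s)
        d = _section_equivalent_diameter(tm, origin, normal)
        if d is None:
            failed += 1
        else:
            stations.append((s, d))
    if failed > max_fail_fraction * n_stations:
        raise ProfileError(
            f"{failed}/{n_stations} stations produced no usable section"
        )
    return CrossSectionProfile(
        stations=stations, attachment_end=0.0, tip_end=L
    )


# ---------------------------------------------------------------------------
# Diameters and classification
# ---------------------------------------------------------------------------

def max_diameter(profile: CrossSectionProfile) -> float:
    if not profile.stations:
        raise SpinekitError("empty cross-section profile")
    return float(profile.diameters.max())


def neck_mean_diameter(
    profile: CrossSectionProfile, neck_fraction: float = DEFAULT_NECK_FRACTION
) -> float | None:
    """Mean diameter over the proximal sub-``neck_fraction``·max run.

    Returns ``None`` when the first station already reaches the threshold,
    i.e. the spine has no detectable neck (stubby).
    """
    if not profile.stations:
        raise SpinekitError("empty cross-section profile")
    d = profile.diameters
    threshold = neck_fraction * d.max()
    run = []
    for val in d:
        if val < threshold:
            run.append(val)
        else:
            break
    if not run:
        return None
    return float(np.mean(run))


def classify_spine(
    profile: CrossSectionProfile,
    morph_max_diameter: float | None = None,
    neck_fraction: float = DEFAULT_NECK_FRACTION,
    head_threshold: float = DEFAULT_HEAD_THRESHOLD_UM,
) -> str:
    """Three-way spine class from the diameter profile.

    No neck → stubby; a neck plus a head at least ``head_threshold`` across →
    mushroom; a neck with a smaller tip (no clear head) → thin.
    """
    md = morph_max_diameter if morph_max_diameter is not None else max_diameter(profile)
    if neck_mean_diameter(profile, neck_fraction) is None:
        return "stubby"
    return "mushroom" if md >= head_threshold else "thin"


def morphometry(
    mesh: TriangleMesh,
    attachment,
    n_stations: int = 32,
    neck_fraction: float = DEFAULT_NECK_FRACTION,
    head_threshold: float = DEFAULT_HEAD_THRESHOLD_UM,
) -> SpineMorphometry:
    """End-to-end morphometry of one closed spine mesh."""
    area = surface_area(mesh)
    volume = enclosed_volume(mesh)
    axis = spine_axis(mesh, attachment)
    profile = cross_section_profile(mesh, axis, n_stations=n_stations)
    md = max_diameter(profile)
    nmd = neck_mean_diameter(profile, neck_fraction)
    cls = classify_spine(profile, md, neck_fraction, head_threshold)
    return SpineMorphometry(
        volume=volume,
        area=area,
        length=axis.length,
        max_diameter=md,
        neck_mean_diameter=nmd,
        spine_class=cls,
    )
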