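"""Discrete geometry on closed triangulated vesicle surfaces.

The central container is :class:`TriangleMesh`: a closed, consistently
oriented genus-0 triangulation whose faces are labelled ``solid`` (the 2D
crystal domain) or ``fluid`` (the surrounding bilayer), with a planar rest
configuration attached to the solid faces.  All lengths are in reduced units
in which the equal-area sphere has radius R = 1.

Curvature fields follow the standard discrete-differential-geometry
discretizations: the cotangent Laplace-Beltrami operator with mixed Voronoi
vertex areas for the mean curvature H, and the angle deficit for the Gaussian
curvature K_G.  On any closed genus-0 triangulation the total angle deficit is
exactly 4*pi (discrete Gauss-Bonnet), independent of vertex positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

SOLID = "solid"
FLUID = "fluid"


class MeshError(ValueError):
    """Raised for meshes that violate the closed-surface contracts."""


@dataclass
class TriangleMesh:
    """Closed oriented genus-0 triangulation with per-face phase labels.

    Attributes
    ----------
    vertices : (V, 3) float array, reduced length units.
    faces : (F, 3) int array, outward-oriented vertex triples.
    face_region : (F,) array of {"solid", "fluid"} labels.
    rest_lengths : (S, 3) rest edge lengths of the solid faces (edge k is
        opposite vertex k), taken from the planar reference state; None for
        meshes with no solid phase.
    solid_face_index : (S,) indices into ``faces`` matching ``rest_lengths``.
    rigid_core : True when the solid patch is a rigid planar disk whose
        vertices are held fixed during minimization (effective-core model).
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_region: np.ndarray
    rest_lengths: np.ndarray | None = None
    solid_face_index: np.ndarray | None = None
    rigid_core: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.face_region = np.asarray(self.face_region)
        if self.solid_face_index is None and self.rest_lengths is not None:
            self.solid_face_index = np.flatnonzero(self.face_region == SOLID)

    # -- basic derived quantities -----------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def solid_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_region == SOLID)

    @property
    def fluid_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_region == FLUID)

    def copy(self, vertices: np.ndarray | None = None) -> "TriangleMesh":
        m = replace(self)
        m.vertices = (self.vertices if vertices is None else np.asarray(vertices, float)).copy()
        m.faces = self.faces.copy()
        m.face_region = self.face_region.copy()
        if self.rest_lengths is not None:
            m.rest_lengths = self.rest_lengths.copy()
        if self.solid_face_index is not None:
            m.solid_face_index = self.solid_face_index.copy()
        m.meta = dict(self.meta)
        return m

    def validate(self) -> None:
        """Check the closed-surface invariants; raise :class:`MeshError` if violated."""
        v, f = self.n_vertices, len(self.faces)
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise MeshError("surface is not closed: some edges bound != 2 faces")
        e = len(uniq)
        if v - e + f != 2:
            raise MeshError(f"Euler characteristic {v - e + f} != 2 (not genus 0)")
        if np.any(face_areas(self) <= 0):
            raise MeshError("degenerate (zero-area) face")
        if enclosed_volume(self, _validate=False) <= 0:
            raise MeshError("signed volume <= 0: orientation is not outward")
        # oriented closedness: each directed edge appears exactly once
        directed = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        keys = directed[:, 0] * (v + 1) + directed[:, 1]
        if len(np.unique(keys)) != len(keys):
            raise MeshError("inconsistent face orientation")


# ---------------------------------------------------------------------------
# areas, volume, reduced volume
# ---------------------------------------------------------------------------

def face_areas(mesh: TriangleMesh) -> np.ndarray:
    p = mesh.vertices[mesh.faces]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def surface_area(mesh: TriangleMesh, region: str | None = None) -> float:
    """Total area, optionally restricted to the ``solid`` or ``fluid`` region."""
    areas = face_areas(mesh)
    if region is None:
        return float(areas.sum())
    if region not in (SOLID, FLUID):
        raise ValueError(f"unknown region label {region!r}")
    return float(areas[mesh.face_region == region].sum())


def solid_area_fraction(mesh: TriangleMesh) -> float:
    return surface_area(mesh, SOLID) / surface_area(mesh)


def enclosed_volume(mesh: TriangleMesh, _validate: bool = True) -> float:
    """Signed enclosed volume by the divergence theorem (sum of tetrahedra)."""
    p = mesh.vertices[mesh.faces]
    vol = float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0)
    if _validate and vol <= 0:
        raise MeshError(f"enclosed volume {vol:.3g} <= 0: mesh is inverted or open")
    return vol


def reduced_volume(mesh: TriangleMesh) -> float:
    """v = sqrt(36 pi) V / A^(3/2): inflation relative to the equal-area sphere."""
    a = surface_area(mesh)
    if a <= 0:
        raise MeshError("degenerate mesh with zero area")
    return float(np.sqrt(36.0 * np.pi) * enclosed_volume(mesh) / a ** 1.5)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def _corner_angles(mesh: TriangleMesh) -> np.ndarray:
    """(F, 3) interior angles; angle k is at face vertex k."""
    p = mesh.vertices[mesh.faces]
    ang = np.empty((len(mesh.faces), 3))
    for k in range(3):
        u = p[:, (k + 1) % 3] - p[:, k]
        v = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        ang[:, k] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return ang


def mixed_voronoi_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex mixed Voronoi areas (Meyer et al. hybrid cell areas)."""
    n = mesh.n_vertices
    p = mesh.vertices[mesh.faces]
    ang = _corner_angles(mesh)
    areas = face_areas(mesh)
    obtuse = ang > np.pi / 2
    any_obtuse = obtuse.any(axis=1)
    out = np.zeros(n)
    cot = 1.0 / np.tan(ang)
    for k in range(3):
        i, j = (k + 1) % 3, (k + 2) % 3
        # Voronoi contribution at corners i and j from edge (i, j), using
        # the cotangent of the opposite angle (at corner k).
        le2 = np.einsum("ij,ij->i", p[:, i] - p[:, j], p[:, i] - p[:, j])
        w = np.where(any_obtuse, 0.0, le2 * cot[:, k] / 8.0)
        np.add.at(out, mesh.faces[:, i], w)
        np.add.at(out, mesh.faces[:, j], w)
    for k in range(3):
        share = np.where(any_obtuse, np.where(obtuse[:, k], areas / 2.0, areas / 4.0), 0.0)
        np.add.at(out, mesh.faces[:, k], share)
    return out


def cotan_laplacian_rows(mesh: TriangleMesh) -> np.ndarray:
    """(V, 3) rows of the cotangent Laplacian applied to the positions,
    (L x)_i = 1/2 sum_j (cot a_ij + cot b_ij) (x_i - x_j)."""
    n = mesh.n_vertices
    x = mesh.vertices
    ang = _corner_angles(mesh)
    cot = 1.0 / np.tan(ang)
    out = np.zeros((n, 3))
    for k in range(3):
        i, j = (k + 1) % 3, (k + 2) % 3
        w = 0.5 * cot[:, k]
        d = x[mesh.faces[:, i]] - x[mesh.faces[:, j]]
        np.add.at(out, mesh.faces[:, i], w[:, None] * d)
        np.add.at(out, mesh.faces[:, j], -w[:, None] * d)
    return out


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    p = mesh.vertices[mesh.faces]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # area-weighted
    out = np.zeros((mesh.n_vertices, 3))
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fn)
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def vertex_mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Signed per-vertex mean curvature H (positive for a sphere with
    outward orientation), cotangent discretization with mixed Voronoi areas."""
    areas = mixed_voronoi_areas(mesh)
    if np.any(areas <= 0):
        raise MeshError("zero mixed-Voronoi area at a vertex (degenerate star)")
    hvec = cotan_laplacian_rows(mesh) / (2.0 * areas[:, None])
    sign = np.sign(np.einsum("ij,ij->i", hvec, vertex_normals(mesh)))
    sign[sign == 0] = 1.0
    return sign * np.linalg.norm(hvec, axis=1)


def angle_deficits(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex angle deficit 2 pi - sum of incident angles (integrated K_G)."""
    ang = _corner_angles(mesh)
    total = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(total, mesh.faces[:, k], ang[:, k])
    return 2.0 * np.pi - total


def vertex_gaussian_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Pointwise K_G: angle deficit divided by the mixed Voronoi area."""
    return angle_deficits(mesh) / mixed_voronoi_areas(mesh)


def total_gaussian_curvature(mesh: TriangleMesh) -> float:
    """Integrated K_G; exactly 4 pi on closed genus-0 meshes (Gauss-Bonnet)."""
    return float(angle_deficits(mesh).sum())


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------

def boundary_loop(mesh: TriangleMesh) -> np.ndarray:
    """Ordered vertex indices of the solid-fluid boundary loop.

    Raises :class:`MeshError` unless the interface is a single closed loop.
    """
    region = mesh.face_region
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, tri in enumerate(mesh.faces):
        for k in range(3):
            key = tuple(sorted((tri[k], tri[(k + 1) % 3])))
            edge_faces.setdefault(key, []).append(fi)
    interface = [e for e, fs in edge_faces.items()
                 if len(fs) == 2 and region[fs[0]] != region[fs[1]]]
    if not interface:
        raise MeshError("no solid-fluid interface edges")
    nxt: dict[int, list[int]] = {}
    for a, b in interface:
        nxt.setdefault(a, []).append(b)
        nxt.setdefault(b, []).append(a)
    if any(len(v) != 2 for v in nxt.values()):
        raise MeshError("solid-fluid interface is not a simple loop")
    start = min(nxt)
    loop = [start, min(nxt[start])]
    while True:
        a, b = loop[-2], loop[-1]
        c = nxt[b][0] if nxt[b][0] != a else nxt[b][1]
        if c == start:
            break
        loop.append(c)
    if len(loop) != len(nxt):
        raise MeshError("solid-fluid interface has multiple loops")
    return np.asarray(loop, dtype=np.int64)


def interface_edges(mesh: TriangleMesh) -> np.ndarray:
    """(K, 2) vertex pairs of edges separating solid from fluid faces."""
    loop = boundary_loop(mesh)
    return np.column_stack([loop, np.roll(loop, -1)])


def region_vertex_masks(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (solid-only, fluid-only, interface) over vertices."""
    in_solid = np.zeros(mesh.n_vertices, bool)
    in_fluid = np.zeros(mesh.n_vertices, bool)
    in_solid[np.unique(mesh.faces[mesh.face_region == SOLID])] = True
    in_fluid[np.unique(mesh.faces[mesh.face_region == FLUID])] = True
    both = in_solid & in_fluid
    return in_solid & ~both, in_fluid & ~both, both


# ---------------------------------------------------------------------------
# Delaunay edge flips
# ---------------------------------------------------------------------------

def _angle_at(apex, p, q):
    u, v = p - apex, q - apex
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.arccos(np.clip(c, -1.0, 1.0))


def _min_angle(p0, p1, p2):
    return min(_angle_at(p0, p1, p2), _angle_at(p1, p2, p0), _angle_at(p2, p0, p1))


def delaunay_flips(faces: np.ndarray, positions: np.ndarray,
                   face_mask: np.ndarray, max_passes: int = 5) -> int:
    """Flip non-Delaunay edges whose two incident faces are both in ``face_mask``.

    ``positions`` may be planar (N, 2) or embedded (N, 3); flips are accepted
    only when they strictly increase the local minimum angle, so the pass
    terminates and never degrades quality.  ``faces`` is modified in place
    (orientation is preserved); returns the number of flips.
    """
    x = positions if positions.shape[1] == 3 else \
        np.column_stack([positions, np.zeros(len(positions))])
    flips = 0
    for _ in range(max_passes):
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for fi, tri in enumerate(faces):
            for k in range(3):
                key = (int(min(tri[k], tri[(k + 1) % 3])),
                       int(max(tri[k], tri[(k + 1) % 3])))
                edge_faces.setdefault(key, []).append(fi)
        all_edges = set(edge_faces)
        changed = 0
        for key in sorted(edge_faces):
            fs = edge_faces[key]
            if len(fs) != 2 or not (face_mask[fs[0]] and face_mask[fs[1]]):
                continue
            fa, fb = fs
            ta, tb = faces[fa], faces[fb]
            a = b = c = d = None
            for k in range(3):
                if {int(ta[k]), int(ta[(k + 1) % 3])} == set(key):
                    a, b = int(ta[k]), int(ta[(k + 1) % 3])
                    c = int(ta[(k + 2) % 3])
            for k in range(3):
                if int(tb[k]) == b and int(tb[(k + 1) % 3]) == a:
                    d = int(tb[(k + 2) % 3])
            if d is None:
                continue
            if (min(c, d), max(c, d)) in all_edges:
                continue
            if _angle_at(x[c], x[a], x[b]) + _angle_at(x[d], x[a], x[b]) \
                    <= np.pi + 1e-9:
                continue
            old = min(_min_angle(x[a], x[b], x[c]), _min_angle(x[b], x[a], x[d]))
            new = min(_min_angle(x[a], x[d], x[c]), _min_angle(x[d], x[b], x[c]))
            if new <= old:
                continue
            faces[fa] = (a, d, c)
            faces[fb] = (d, b, c)
            all_edges.discard(key)
            all_edges.add((min(c, d), max(c, d)))
            changed += 1
        flips += changed
        if changed == 0:
            break
    return flips


# ---------------------------------------------------------------------------
# primitive meshes
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int = 4, radius: float = 1.0,
              region: str = FLUID) -> TriangleMesh:
    """Uniform unit-ish sphere mesh; all faces labelled ``region``."""
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, np.int64),
        face_region=np.full(len(tm.faces), region, dtype=object),
    )
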