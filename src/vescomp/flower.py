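"""Synthetic vesicle construction: flower-shaped solid domains on spheres.

The 6-fold solid (crystal) domain is defined in a planar reference state by
the radial profile

    r(theta) = r0 * (1 + (a/2) cos 6 theta - (a/10) cos 12 theta),

whose petal-to-core ratio alpha = r(0)/r(pi/6) = (5 + 2a)/(5 - 3a) runs from
1 (disk) upward as the petal amplitude ``a`` grows.  The builder carves this
shape out of an icosphere through an inverse Lambert azimuthal equal-area
projection centred on the +z pole, so the solid area fraction equals the
planar flower area fraction by construction, and attaches the planar layout
to the solid faces as their strain-free rest configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import (FLUID, SOLID, MeshError, TriangleMesh, boundary_loop,
                   face_areas, icosphere, reduced_volume, solid_area_fraction,
                   surface_area)

A_MAX = 5.0 / 3.0  # inradius vanishes at a = 5/3


def _check_a(a: float) -> None:
    if not 0.0 <= a < A_MAX:
        raise ValueError(f"petal amplitude a={a} outside [0, 5/3)")


def alpha_of(a: float) -> float:
    """Circumradius/inradius ratio alpha = (5 + 2a)/(5 - 3a)."""
    _check_a(a)
    return (5.0 + 2.0 * a) / (5.0 - 3.0 * a)


def a_of_alpha(alpha: float) -> float:
    """Inverse of :func:`alpha_of`; alpha = 1 maps to a circular domain."""
    if alpha < 1.0:
        raise ValueError(f"alpha={alpha} < 1")
    return 5.0 * (alpha - 1.0) / (3.0 * alpha + 2.0)


@dataclass(frozen=True)
class FlowerBoundary:
    """Planar flower boundary with base radius ``r0`` and petal amplitude ``a``."""

    r0: float
    a: float

    def __post_init__(self):
        _check_a(self.a)
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")

    @property
    def alpha(self) -> float:
        return alpha_of(self.a)

    @property
    def area(self) -> float:
        return flower_area(self)

    def radius(self, theta) -> np.ndarray | float:
        return flower_radius(self, theta)


def flower_radius(boundary: FlowerBoundary, theta) -> np.ndarray | float:
    """r(theta) of the 6-fold flower profile."""
    t = np.asarray(theta, float)
    a, r0 = boundary.a, boundary.r0
    r = r0 * (1.0 + 0.5 * a * np.cos(6.0 * t) - 0.1 * a * np.cos(12.0 * t))
    return float(r) if np.isscalar(theta) else r


def flower_area(boundary: FlowerBoundary) -> float:
    """Closed-form enclosed area pi r0^2 (1 + a^2/8 + a^2/200)."""
    a = boundary.a
    return np.pi * boundary.r0 ** 2 * (1.0 + a * a / 8.0 + a * a / 200.0)


def flower_perimeter(boundary: FlowerBoundary) -> float:
    """Arc length of the boundary by adaptive quadrature."""
    a, r0 = boundary.a, boundary.r0

    def ds(t):
        r = 1.0 + 0.5 * a * np.cos(6 * t) - 0.1 * a * np.cos(12 * t)
        dr = -3.0 * a * np.sin(6 * t) + 1.2 * a * np.sin(12 * t)
        return np.sqrt(r * r + dr * dr)

    # integrand is pi/3-periodic
    val, _ = quad(ds, 0.0, np.pi / 3.0, limit=200)
    return 6.0 * r0 * val


def solve_r0(a: float, target_area: float) -> float:
    """Base radius giving the requested enclosed area (exact inversion)."""
    _check_a(a)
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    return float(np.sqrt(target_area / (np.pi * (1.0 + a * a / 8.0 + a * a / 200.0))))


@dataclass
class BuildSpec:
    """Recipe for a composite vesicle mesh.

    ``alpha`` (or equivalently ``a``) sets the flower shape, ``phi`` the solid
    area fraction, ``vbar_init`` the initial reduced volume, ``subdivisions``
    the icosphere refinement (level 4 is about 2562 vertices), ``seed`` the
    symmetry-breaking perturbation, and ``core_mode`` switches between the
    elastic flower and the rigid planar effective-core disk of area fraction
    ``phi_core``.
    """

    alpha: float = 1.0
    phi: float = 0.14
    vbar_init: float = 1.0
    subdivisions: int = 4
    seed: int = 0
    core_mode: str = "elastic_flower"
    phi_core: float | None = None
    perturb_amplitude: float = 1e-3
    init_mode: str = "projected"

    def __post_init__(self):
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if not 0.0 < self.vbar_init <= 1.0:
            raise ValueError("vbar_init must lie in (0, 1]")
        if self.core_mode not in ("elastic_flower", "rigid_disk"):
            raise ValueError(f"unknown core_mode {self.core_mode!r}")
        if self.init_mode not in ("projected", "flat_solid"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.core_mode == "rigid_disk":
            if self.phi_core is None:
                raise ValueError("rigid_disk mode requires phi_core")
            if not 0.0 < self.phi_core < 1.0:
                raise ValueError("phi_core must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Lambert azimuthal equal-area projection about the +z pole of the unit sphere
# ---------------------------------------------------------------------------

def _to_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sphere points -> planar polar coordinates (rho, phi); area preserving."""
    z = np.clip(points[:, 2] / np.linalg.norm(points, axis=1), -1.0, 1.0)
    polar = np.arccos(z)
    rho = 2.0 * np.sin(polar / 2.0)
    phi = np.arctan2(points[:, 1], points[:, 0])
    return rho, phi


def _to_sphere(rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    polar = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
    return np.column_stack([np.sin(polar) * np.cos(phi),
                            np.sin(polar) * np.sin(phi),
                            np.cos(polar)])


def _nearest_on_curve(flower: FlowerBoundary, rho: np.ndarray,
                      phi: np.ndarray, samples: int = 4096
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on the flower curve for each planar point (rho, phi).

    Snapping to the nearest curve point (rather than radially) keeps the
    displacement bounded by the distance to the curve, so boundary vertices
    never jump across a petal notch and fold their incident triangles.
    """
    t = np.linspace(0.0, 2.0 * np.pi, samples, endpoint=False)
    rc = flower.radius(t)
    cx, cy = rc * np.cos(t), rc * np.sin(t)
    px, py = rho * np.cos(phi), rho * np.sin(phi)
    d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
    j = np.argmin(d2, axis=1)
    nx, ny = cx[j], cy[j]
    return np.hypot(nx, ny), np.arctan2(ny, nx)


def _redistribute_loop(flower: FlowerBoundary, pts: np.ndarray,
                       samples: int = 8192) -> np.ndarray:
    """Respace an ordered planar loop uniformly by arclength along the curve.

    The loop's winding direction is preserved; output points lie exactly on
    the flower boundary.  Equal spacing removes the sliver triangles that
    nearest-point snapping alone leaves behind.
    """
    t = np.linspace(0.0, 2.0 * np.pi, samples, endpoint=False)
    rc = flower.radius(t)
    c = np.column_stack([rc * np.cos(t), rc * np.sin(t)])
    seg = np.linalg.norm(np.diff(np.vstack([c, c[:1]]), axis=0), axis=1)
    s_grid = np.concatenate([[0.0], np.cumsum(seg)])  # length samples+1
    total = s_grid[-1]
    d2 = ((pts[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    s = s_grid[np.argmin(d2, axis=1)]
    ds = np.diff(np.concatenate([s, s[:1]]))
    ds = (ds + total / 2.0) % total - total / 2.0  # wrapped increments
    direction = 1.0 if np.median(ds) >= 0 else -1.0
    n = len(pts)
    new_s = (s[0] + direction * total * np.arange(n) / n) % total
    idx = np.minimum(np.searchsorted(s_grid, new_s), samples - 1)
    return c[idx]


def _smooth(planar: np.ndarray, verts: np.ndarray, faces: np.ndarray,
            solid_interior: np.ndarray, fluid_only: np.ndarray,
            iterations: int = 12, relax: float = 0.7
            ) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian smoothing: solid interior in the rest plane, fluid on the sphere.

    Boundary-loop vertices are kept fixed.  Returns updated (planar, verts).
    """
    nv = len(verts)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    deg = np.bincount(e.ravel(), minlength=nv).astype(float)
    planar = planar.copy()
    verts = verts.copy()
    for _ in range(iterations):
        acc2 = np.zeros((nv, 2))
        np.add.at(acc2, e[:, 0], planar[e[:, 1]])
        np.add.at(acc2, e[:, 1], planar[e[:, 0]])
        mean2 = acc2 / deg[:, None]
        planar[solid_interior] += relax * (mean2[solid_interior] - planar[solid_interior])
        acc3 = np.zeros((nv, 3))
        np.add.at(acc3, e[:, 0], verts[e[:, 1]])
        np.add.at(acc3, e[:, 1], verts[e[:, 0]])
        mean3 = acc3 / deg[:, None]
        moved = verts[fluid_only] + relax * (mean3[fluid_only] - verts[fluid_only])
        verts[fluid_only] = moved / np.linalg.norm(moved, axis=1)[:, None]
    return planar, verts


def _face_adjacency(faces: np.ndarray) -> np.ndarray:
    """(M, 2) pairs of faces sharing an edge."""
    f = len(faces)
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    fid = np.repeat(np.arange(f), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    e, fi = edges[order], fid[order]
    same = np.all(e[:-1] == e[1:], axis=1)
    return np.column_stack([fi[:-1][same], fi[1:][same]])


def _clean_labels(faces: np.ndarray, areas: np.ndarray,
                  solid: np.ndarray) -> np.ndarray:
    """Keep the largest solid component; absorb enclosed fluid islands."""
    adj = _face_adjacency(faces)
    nf = len(faces)

    def biggest(mask: np.ndarray) -> np.ndarray:
        keep = adj[mask[adj[:, 0]] & mask[adj[:, 1]]]
        g = coo_matrix((np.ones(len(keep)), (keep[:, 0], keep[:, 1])), shape=(nf, nf))
        _, lab = connected_components(g, directed=False)
        ids = np.unique(lab[mask])
        weights = np.array([areas[mask & (lab == i)].sum() for i in ids])
        return mask & (lab == ids[np.argmax(weights)])

    solid = biggest(solid.copy())
    fluid = biggest(~solid)
    return ~fluid  # fluid islands inside the solid become solid


def _rest_lengths(faces: np.ndarray, planar: np.ndarray,
                  solid_faces: np.ndarray) -> np.ndarray:
    """Per-solid-face rest edge lengths from the planar layout.

    Edge k is opposite corner k, i.e. connects corners k+1 and k+2.
    """
    tri = planar[faces[solid_faces]]
    out = np.empty((len(solid_faces), 3))
    for k in range(3):
        out[:, k] = np.linalg.norm(tri[:, (k + 1) % 3] - tri[:, (k + 2) % 3], axis=1)
    return out


def _squash_to_vbar(verts: np.ndarray, faces: np.ndarray,
                    region: np.ndarray, vbar: float) -> np.ndarray:
    """Oblate z-scaling of a unit-sphere mesh to the requested reduced volume."""
    if vbar >= 1.0:
        return verts

    def vb(c):
        v = verts.copy()
        v[:, 2] *= c
        return reduced_volume(TriangleMesh(v, faces, region))

    c = brentq(lambda s: vb(s) - vbar, 0.2, 1.0, xtol=1e-10)
    out = verts.copy()
    out[:, 2] *= c
    return out


def build_vesicle(spec: BuildSpec) -> TriangleMesh:
    """Closed genus-0 composite vesicle mesh per the build recipe.

    The solid patch is the image of the planar flower under the inverse
    Lambert equal-area projection; its planar layout is stored as the
    strain-free rest state.  A seeded normal perturbation of amplitude
    ``perturb_amplitude`` breaks the 6-fold symmetry reproducibly.
    """
    if spec.core_mode == "rigid_disk":
        return build_core_vesicle(spec)
    a = a_of_alpha(spec.alpha)
    base = icosphere(spec.subdivisions)
    target_area = spec.phi * 4.0 * np.pi
    r0 = solve_r0(a, target_area)

    mesh = planar = None
    for _ in range(4):  # fixed-point adjustment of r0 onto the measured phi
        flower = FlowerBoundary(r0, a)
        verts = base.vertices.copy()
        faces = base.faces
        cent = verts[faces].mean(axis=1)
        rho_c, phi_c = _to_plane(cent)
        solid = rho_c <= flower.radius(phi_c)
        if solid.sum() < 6:
            raise MeshError("resolution too coarse: solid patch unresolved")
        solid = _clean_labels(faces, face_areas(TriangleMesh(verts, faces,
                              np.full(len(faces), FLUID, object))), solid)
        region = np.where(solid, SOLID, FLUID).astype(object)
        mesh = TriangleMesh(verts, faces, region)
        loop = boundary_loop(mesh)
        needed = 48 if a > 0.05 else 12
        if len(loop) < needed:
            raise MeshError(
                f"resolution too coarse: {len(loop)} boundary vertices "
                f"(need >= {needed} to resolve the petals)")
        rho_all, phi_all = _to_plane(verts)
        planar = np.column_stack([rho_all * np.cos(phi_all),
                                  rho_all * np.sin(phi_all)])
        planar[loop] = _redistribute_loop(flower, planar[loop])
        verts[loop] = _to_sphere(np.hypot(*planar[loop].T),
                                 np.arctan2(planar[loop][:, 1], planar[loop][:, 0]))
        svert = np.unique(faces[solid])
        interior = np.setdiff1d(svert, loop)
        fluid_only = np.setdiff1d(np.unique(faces[~solid]), svert)
        faces = faces.copy()

        def _project_interior(planar, verts):
            verts[interior] = _to_sphere(np.hypot(*planar[interior].T),
                                         np.arctan2(planar[interior][:, 1],
                                                    planar[interior][:, 0]))

        from .mesh import delaunay_flips
        for _ in range(2):  # smooth / flip rounds
            planar, verts = _smooth(planar, verts, faces, interior, fluid_only)
            _project_interior(planar, verts)
            delaunay_flips(faces, planar, solid)
            delaunay_flips(faces, verts, ~solid)
        planar, verts = _smooth(planar, verts, faces, interior, fluid_only)
        _project_interior(planar, verts)
        mesh = TriangleMesh(verts, faces, region)
        measured = solid_area_fraction(mesh)
        if abs(measured - spec.phi) < 2e-4:
            break
        r0 *= np.sqrt(spec.phi / measured)

    # planar rest layout of the solid patch (strain-free reference)
    sidx = mesh.solid_faces
    rest = _rest_lengths(mesh.faces, planar, sidx)

    rng = np.random.default_rng(spec.seed)
    from .mesh import vertex_normals
    if spec.init_mode == "flat_solid":
        # start the crystal exactly in its planar rest state (zero strain),
        # sitting on the plane of its mean rim height; only the fluid is
        # perturbed.  vbar_init is ignored: the configuration's own reduced
        # volume (recorded in meta) is the natural starting inflation.
        verts = mesh.vertices.copy()
        sv = np.unique(mesh.faces[sidx])
        verts[sv, :2] = planar[sv]
        verts[sv, 2] = 1.0 - np.mean(np.hypot(*planar[sv].T) ** 2) / 2.0
        normals = vertex_normals(TriangleMesh(verts, mesh.faces,
                                              mesh.face_region))
        fluid_only = np.setdiff1d(np.arange(mesh.n_vertices), sv)
        amp = np.zeros((len(verts), 1))
        amp[fluid_only] = spec.perturb_amplitude * \
            rng.uniform(-1.0, 1.0, size=(len(fluid_only), 1))
        verts = verts + amp * normals
    else:
        verts = _squash_to_vbar(mesh.vertices, mesh.faces, mesh.face_region,
                                spec.vbar_init)
        normals = vertex_normals(TriangleMesh(verts, mesh.faces,
                                              mesh.face_region))
        verts = verts + spec.perturb_amplitude * \
            rng.uniform(-1.0, 1.0, size=(len(verts), 1)) * normals

    out = TriangleMesh(verts, mesh.faces, mesh.face_region,
                       rest_lengths=rest, solid_face_index=sidx)
    out.meta.update(alpha=spec.alpha, a=a, phi=spec.phi, r0=r0,
                    seed=spec.seed, subdivisions=spec.subdivisions,
                    planar_rest=planar, core_mode=spec.core_mode,
                    init_mode=spec.init_mode)
    out.validate()
    return out


def build_core_vesicle(spec: BuildSpec) -> TriangleMesh:
    """Vesicle with a rigid planar disk (area fraction ``phi_core``) at the pole.

    The disk vertices carry their Lambert planar coordinates, so the flat
    patch has exactly the equal-area disk layout; the fluid starts on the
    sphere and relaxes during minimization.  The mesh is flagged
    ``rigid_core`` so the minimizer holds the disk fixed.
    """
    if spec.phi_core is None:
        raise ValueError("phi_core required")
    base = icosphere(spec.subdivisions)
    verts = base.vertices.copy()
    faces = base.faces
    rho_rim = 2.0 * np.sqrt(spec.phi_core)

    cent = verts[faces].mean(axis=1)
    rho_c, _ = _to_plane(cent)
    solid = rho_c <= rho_rim
    if solid.sum() < 6:
        raise MeshError("resolution too coarse for the requested phi_core")
    solid = _clean_labels(faces, face_areas(TriangleMesh(verts, faces,
                          np.full(len(faces), FLUID, object))), solid)
    region = np.where(solid, SOLID, FLUID).astype(object)
    mesh = TriangleMesh(verts, faces, region)
    loop = boundary_loop(mesh)
    if len(loop) < 12:
        raise MeshError("resolution too coarse: rim under-resolved")

    # place the disk flat at the rim height, with equal-area planar coords
    svert = np.unique(faces[solid])
    rho_s, phi_s = _to_plane(verts[svert])
    rho_s = np.where(np.isin(svert, loop), rho_rim, rho_s)
    z_plane = 1.0 - rho_rim ** 2 / 2.0  # cos of the rim polar angle
    verts[svert, 0] = rho_s * np.cos(phi_s)
    verts[svert, 1] = rho_s * np.sin(phi_s)
    verts[svert, 2] = z_plane

    # remap the fluid onto the maximal-inflation bulb: the spherical cap
    # that meets the flat disk along its rim (closed-form geometry).  This
    # starts the relaxation from a consistent, nearly equilibrated shape.
    cospsi = (1.0 - 3.0 * spec.phi_core) / (1.0 - spec.phi_core)
    if abs(cospsi) < 1.0:
        psi = np.arccos(cospsi)
        rs = rho_rim / np.sin(psi)
        zc = z_plane - rs * cospsi
        theta_rim = 2.0 * np.arcsin(min(rho_rim / 2.0, 1.0))
        fl = np.setdiff1d(np.arange(len(verts)), svert)
        zsph = np.clip(verts[fl, 2], -1.0, 1.0)
        frac = (np.cos(theta_rim) - zsph) / (np.cos(theta_rim) + 1.0)
        frac = np.clip(frac, 0.0, 1.0)
        a = np.arccos(np.clip(cospsi - frac * (1.0 + cospsi), -1.0, 1.0))
        phi_az = np.arctan2(verts[fl, 1], verts[fl, 0])
        verts[fl, 0] = rs * np.sin(a) * np.cos(phi_az)
        verts[fl, 1] = rs * np.sin(a) * np.sin(phi_az)
        verts[fl, 2] = zc + rs * np.cos(a)

    # restore local mesh quality before handing the mesh to the minimizer
    from .mesh import delaunay_flips
    faces = faces.copy()
    delaunay_flips(faces, verts, ~solid)

    rng = np.random.default_rng(spec.seed)
    fluid_only = np.setdiff1d(np.unique(faces[~solid]), svert)
    from .mesh import vertex_normals
    normals = vertex_normals(TriangleMesh(verts, faces, region))
    verts[fluid_only] += spec.perturb_amplitude * \
        rng.uniform(-1.0, 1.0, size=(len(fluid_only), 1)) * normals[fluid_only]

    out = TriangleMesh(verts, faces, region, rigid_core=True)
    out.meta.update(phi_core=spec.phi_core, seed=spec.seed,
                    subdivisions=spec.subdivisions, core_mode="rigid_disk",
                    rim_vertices=loop, core_vertices=svert)
    out.validate()
    return out
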