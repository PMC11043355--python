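"""Membrane energy functionals for fluid-solid composite vesicles.

The fluid phase carries the Helfrich bending energy (B/2) * integral (2H)^2 dA.
The solid (crystal) phase adds, on top of the same bending term, an isotropic
2D elastic-plate stretching energy evaluated per constant-strain triangle
against its planar rest configuration:

    E_stretch = Y / (2 (1 + nu)) * integral dA [ Tr eps^2 + nu/(1-nu) (Tr eps)^2 ]

with eps the (Green-Lagrange) 2D strain.  A configuration toggle
(``eq2_as_printed``) swaps the two trace terms to the transposed arrangement;
at the near-inextensible conditions studied here (t/R ~ 1e-4) the choice is
immaterial because the strain energy is negligible compared with bending.

Bending is discretized with the cotangent Laplacian and barycentric vertex
areas, E_bend = (B/2) sum_v |(L x)_v|^2 / A_v, which converges to the Helfrich
energy (8 pi B for a sphere) under refinement and is shared verbatim by the
shape optimizer so that reported and minimized energies coincide.  The
Gaussian-curvature bending term is omitted: on a closed vesicle with
developable solid domains its integral is topologically fixed and shape
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (FLUID, SOLID, TriangleMesh, boundary_loop, face_areas,
                   cotan_laplacian_rows)

KBT_J = 4.114e-21  # thermal energy at 25 C, joules
DEFAULT_T_OVER_R = 8.3e-5  # elastic thickness over vesicle radius


def line_length_scale_nm(B_kBT: float = 25.0,
                         sigma_kBT_per_nm: float = 1.0) -> float:
    """B/sigma: the length above which line energy outweighs bending.

    With the fluid-phase stiffness B = 25 k_BT and a solid-fluid line
    tension of 1 k_BT/nm this calibrates the state-map size axis to 25 nm.
    """
    return B_kBT / sigma_kBT_per_nm


@dataclass(frozen=True)
class MaterialParams:
    """Material constants in reduced units (R = 1, B = 1 by default).

    ``t_over_R`` fixes the 2D Young's modulus through Y = B / t^2, i.e. the
    elastic thickness t = sqrt(B/Y); the default 8.3e-5 corresponds to a
    nanometric bilayer on a multi-micron vesicle (nearly inextensible).
    ``sigma`` is the solid-fluid line tension used only in the state-map
    comparison.
    """

    B: float = 1.0
    t_over_R: float = DEFAULT_T_OVER_R
    nu: float = 0.4
    sigma: float = 0.0
    eq2_as_printed: bool = False

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not -1.0 < self.nu < 1.0:
            raise ValueError("nu must lie in (-1, 1)")
        if self.t_over_R <= 0:
            raise ValueError("t_over_R must be positive")

    @property
    def Y(self) -> float:
        return self.B / self.t_over_R ** 2


@dataclass
class EnergyBreakdown:
    """Energy components of a composite vesicle configuration."""

    E_bend_fluid: float
    E_bend_solid: float
    E_stretch: float
    E_line: float
    perimeter: float
    B: float
    extras: dict = field(default_factory=dict)

    @property
    def E_elastic(self) -> float:
        return self.E_bend_fluid + self.E_bend_solid + self.E_stretch

    @property
    def E_total(self) -> float:
        return self.E_elastic + self.E_line

    @property
    def Ebar(self) -> float:
        """Reduced elastic energy (E_solid + E_fluid)/(8 pi B); excludes line energy."""
        return self.E_elastic / (8.0 * np.pi * self.B)


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------

def _vertex_bending_density(mesh: TriangleMesh, B: float) -> np.ndarray:
    """Per-vertex bending energies e_v with sum e_v = (B/2) int (2H)^2 dA."""
    areas = face_areas(mesh)
    av = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(av, mesh.faces[:, k], areas / 3.0)
    lx = cotan_laplacian_rows(mesh)
    return 0.5 * B * np.einsum("ij,ij->i", lx, lx) / av


def _region_vertex_weights(mesh: TriangleMesh, region: str) -> np.ndarray:
    """Fraction of each vertex's barycentric area lying in ``region``."""
    areas = face_areas(mesh)
    tot = np.zeros(mesh.n_vertices)
    reg = np.zeros(mesh.n_vertices)
    sel = mesh.face_region == region
    for k in range(3):
        np.add.at(tot, mesh.faces[:, k], areas / 3.0)
        np.add.at(reg, mesh.faces[:, k], np.where(sel, areas, 0.0) / 3.0)
    return reg / tot


def bending_energy(mesh: TriangleMesh, B: float = 1.0,
                   region: str | None = None) -> float:
    """Helfrich bending energy, optionally restricted to one phase.

    Vertices on the solid-fluid interface split their contribution between
    the phases in proportion to incident face areas; with a common bending
    modulus the split leaves the total unchanged.
    """
    e = _vertex_bending_density(mesh, B)
    if region is None:
        return float(e.sum())
    if region not in (SOLID, FLUID):
        raise ValueError(f"unknown region label {region!r}")
    return float((e * _region_vertex_weights(mesh, region)).sum())


# ---------------------------------------------------------------------------
# stretching
# ---------------------------------------------------------------------------

def _rest_metric_inverse(rest_lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-face inverse rest-shape matrices M = S^-1 and rest areas.

    The rest triangle is laid out in 2D from its three edge lengths
    (l0 opposite corner 0, etc.); S has the two rest edge vectors from corner
    0 as columns.
    """
    l0, l1, l2 = rest_lengths[:, 0], rest_lengths[:, 1], rest_lengths[:, 2]
    # corner 0 at origin, corner 1 at (l2, 0); corner 2 from the two lengths
    x2 = (l1 ** 2 + l2 ** 2 - l0 ** 2) / (2.0 * l2)
    y2sq = l1 ** 2 - x2 ** 2
    if np.any(y2sq <= 0):
        raise ValueError("degenerate rest triangle")
    y2 = np.sqrt(y2sq)
    det = l2 * y2  # = 2 * rest area
    m = np.empty((len(l0), 2, 2))
    # S = [[l2, x2], [0, y2]]  ->  S^-1 = [[1/l2, -x2/(l2 y2)], [0, 1/y2]]
    m[:, 0, 0] = 1.0 / l2
    m[:, 0, 1] = -x2 / det
    m[:, 1, 0] = 0.0
    m[:, 1, 1] = 1.0 / y2
    return m, 0.5 * det


def stretch_energy(mesh: TriangleMesh, Y: float, nu: float,
                   as_printed: bool = False) -> float:
    """In-plane elastic energy of the solid faces against their rest state.

    Exactly zero when every solid triangle is congruent to its rest triangle.
    """
    if mesh.rest_lengths is None or mesh.solid_face_index is None:
        if len(mesh.solid_faces) == 0 or mesh.rigid_core:
            return 0.0
        raise ValueError("solid faces carry no rest geometry")
    tri = mesh.vertices[mesh.faces[mesh.solid_face_index]]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    g11 = np.einsum("ij,ij->i", e1, e1)
    g22 = np.einsum("ij,ij->i", e2, e2)
    g12 = np.einsum("ij,ij->i", e1, e2)
    m, a0 = _rest_metric_inverse(mesh.rest_lengths)
    tr2, trsq = _strain_invariants(g11, g12, g22, m)
    pref = Y / (2.0 * (1.0 + nu))
    k = nu / (1.0 - nu)
    if as_printed:
        dens = pref * (tr2 ** 2 + k * trsq)
    else:
        dens = pref * (trsq + k * tr2 ** 2)
    return float((dens * a0).sum())


def _strain_invariants(g11, g12, g22, m):
    """Tr eps and Tr eps^2 from the current metric and inverse rest shape."""
    m11, m12, m21, m22 = m[:, 0, 0], m[:, 0, 1], m[:, 1, 0], m[:, 1, 1]
    gm11 = g11 * m11 + g12 * m21
    gm12 = g11 * m12 + g12 * m22
    gm21 = g12 * m11 + g22 * m21
    gm22 = g12 * m12 + g22 * m22
    c11 = m11 * gm11 + m21 * gm21
    c12 = m11 * gm12 + m21 * gm22
    c22 = m12 * gm12 + m22 * gm22
    e11 = 0.5 * (c11 - 1.0)
    e22 = 0.5 * (c22 - 1.0)
    e12 = 0.5 * c12
    return e11 + e22, e11 * e11 + e22 * e22 + 2.0 * e12 * e12


# ---------------------------------------------------------------------------
# line energy and totals
# ---------------------------------------------------------------------------

def line_energy(mesh: TriangleMesh, sigma: float) -> tuple[float, float]:
    """(sigma * P, P) over the single closed solid-fluid boundary loop."""
    loop = boundary_loop(mesh)
    seg = mesh.vertices[np.roll(loop, -1)] - mesh.vertices[loop]
    p = float(np.linalg.norm(seg, axis=1).sum())
    return sigma * p, p


def total_energy(mesh: TriangleMesh, params: MaterialParams) -> EnergyBreakdown:
    """Full energy breakdown; the reduced energy Ebar excludes line energy."""
    has_solid = len(mesh.solid_faces) > 0
    eb_fluid = bending_energy(mesh, params.B, FLUID) if has_solid else \
        bending_energy(mesh, params.B)
    eb_solid = bending_energy(mesh, params.B, SOLID) if has_solid else 0.0
    if mesh.rigid_core or not has_solid:
        es = 0.0
    else:
        es = stretch_energy(mesh, params.Y, params.nu, params.eq2_as_printed)
    if has_solid:
        el, p = line_energy(mesh, params.sigma)
    else:
        el, p = 0.0, 0.0
    return EnergyBreakdown(E_bend_fluid=eb_fluid, E_bend_solid=eb_solid,
                           E_stretch=es, E_line=el, perimeter=p, B=params.B)
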