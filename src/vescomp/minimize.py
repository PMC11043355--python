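"""Constrained minimization of the composite-vesicle elastic energy.

Vertex positions are relaxed by limited-memory quasi-Newton descent
(scipy's L-BFGS-B) on the discrete bending + stretching energy, with the
fixed-area and fixed-volume constraints imposed through quadratic penalties
under a stiffness-continuation schedule.  The in-plane stiffness of the solid
is also continued (soft to near-inextensible) so that the crystal can first
unbend and then flatten without trapping the descent in a stiff landscape.
Gradients come from the package's reverse-mode automatic differentiation of
the same discrete energies the reporting module evaluates.

The rigid effective-core model holds the disk vertices fixed in their planar
layout (a gauge-fixing of the global rigid-body freedom), which enforces
planarity and in-plane rigidity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import _adiff as ad
from .energy import EnergyBreakdown, MaterialParams, total_energy
from .mesh import (FLUID, SOLID, MeshError, TriangleMesh, face_areas,
                   surface_area, enclosed_volume)


class ConvergenceError(RuntimeError):
    """Raised when the full penalty schedule fails to meet the tolerances."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class Stage:
    penalty: float        # penalty stiffness (units of B)
    y_scale: float        # fraction of the final 2D Young's modulus
    maxiter: int


@dataclass
class MinimizeConfig:
    """Targets and schedule for :func:`minimize_shape`.

    Omitted targets default to the input mesh's measured values (``target_V``
    can instead be set through ``vbar`` relative to the total target area).
    """

    target_A_solid: float | None = None
    target_A_fluid: float | None = None
    target_V: float | None = None
    vbar: float | None = None
    stages: list[Stage] = field(default_factory=lambda: [
        Stage(2e2, 1e-7, 200),
        Stage(1e3, 1e-6, 200),
        Stage(5e3, 1e-5, 300),
        Stage(2e4, 1e-4, 400),
        Stage(1e5, 1e-2, 600),
        Stage(2e5, 1.0, 1000),
        Stage(2e6, 1.0, 500),
    ])
    gtol: float = 1e-6
    constraint_tol: float = 1e-3
    equiangulate: bool = True
    min_angle_deg: float = 12.0
    raise_on_failure: bool = False

    def resolved_targets(self, mesh: TriangleMesh) -> tuple[float, float, float]:
        a_s = self.target_A_solid
        a_f = self.target_A_fluid
        if a_s is None:
            a_s = surface_area(mesh, SOLID)
        if a_f is None:
            a_f = surface_area(mesh, FLUID)
        v = self.target_V
        if v is None:
            if self.vbar is not None:
                a_tot = a_s + a_f
                v = self.vbar * a_tot ** 1.5 / np.sqrt(36.0 * np.pi)
            else:
                v = enclosed_volume(mesh)
        return float(a_s), float(a_f), float(v)


# ---------------------------------------------------------------------------
# objective (energy + penalties) with reverse-mode gradient
# ---------------------------------------------------------------------------

def _objective(mesh: TriangleMesh, params: MaterialParams, y_eff: float,
               penalty: float, targets: tuple[float, float, float],
               free_idx: np.ndarray, x_template: np.ndarray):
    faces = mesh.faces
    n = mesh.n_vertices
    f = [faces[:, 0], faces[:, 1], faces[:, 2]]
    solid_fidx = np.flatnonzero(mesh.face_region == SOLID)
    fluid_fidx = np.flatnonzero(mesh.face_region == FLUID)
    t_as, t_af, t_v = targets
    b = params.B

    do_stretch = (y_eff > 0 and not mesh.rigid_core
                  and mesh.rest_lengths is not None and len(solid_fidx))
    if do_stretch:
        from .energy import _rest_metric_inverse
        m_inv, a0 = _rest_metric_inverse(mesh.rest_lengths)
        m11, m12 = m_inv[:, 0, 0], m_inv[:, 0, 1]
        m21, m22 = m_inv[:, 1, 0], m_inv[:, 1, 1]
        sf = faces[mesh.solid_face_index]
        knu = params.nu / (1.0 - params.nu)
        pref = y_eff / (2.0 * (1.0 + params.nu))

    full = len(free_idx) == n

    def fg(xflat: np.ndarray) -> tuple[float, np.ndarray]:
        xfree = ad.Var(xflat.reshape(-1, 3))
        if full:
            x = xfree
        else:
            x = ad.embed(xfree, x_template, free_idx)
        p = [ad.gather(x, fk) for fk in f]

        # cotangents and face areas
        lx_terms = []
        area = None
        for k in range(3):
            u = p[(k + 1) % 3] - p[k]
            v = p[(k + 2) % 3] - p[k]
            cr = ad.cross(u, v)
            den = ad.norm_rows(cr)
            if k == 0:
                area = den * 0.5
            w = ad.expand_last(ad.dot_rows(u, v) / den * 0.5)
            d = p[(k + 1) % 3] - p[(k + 2) % 3]
            lx_terms.append(ad.scatter(f[(k + 1) % 3], w * d, n))
            lx_terms.append(ad.scatter(f[(k + 2) % 3], w * (-1.0) * d, n))
        lx = lx_terms[0]
        for t in lx_terms[1:]:
            lx = lx + t
        av = ad.scatter(f[0], area * (1 / 3), n) + \
            ad.scatter(f[1], area * (1 / 3), n) + \
            ad.scatter(f[2], area * (1 / 3), n)
        e_bend = ad.vsum(ad.dot_rows(lx, lx) / av) * (0.5 * b)

        a_solid = ad.vsum(ad.gather(area, solid_fidx)) if len(solid_fidx) \
            else ad.constant(0.0)
        a_fluid = ad.vsum(ad.gather(area, fluid_fidx))
        vol = ad.vsum(ad.dot_rows(p[0], ad.cross(p[1], p[2]))) * (1.0 / 6.0)

        energy = e_bend
        if do_stretch:
            s0 = ad.gather(x, sf[:, 0])
            e1 = ad.gather(x, sf[:, 1]) - s0
            e2 = ad.gather(x, sf[:, 2]) - s0
            g11 = ad.dot_rows(e1, e1)
            g22 = ad.dot_rows(e2, e2)
            g12 = ad.dot_rows(e1, e2)
            gm11 = g11 * m11 + g12 * m21
            gm12 = g11 * m12 + g12 * m22
            gm21 = g12 * m11 + g22 * m21
            gm22 = g12 * m12 + g22 * m22
            c11 = gm11 * m11 + gm21 * m21
            c12 = gm12 * m11 + gm22 * m21
            c22 = gm12 * m12 + gm22 * m22
            e11 = (c11 - 1.0) * 0.5
            e22 = (c22 - 1.0) * 0.5
            e12 = c12 * 0.5
            tr = e11 + e22
            trsq = e11 * e11 + e22 * e22 + e12 * e12 * 2.0
            if params.eq2_as_printed:
                dens = (tr * tr + trsq * knu) * pref
            else:
                dens = (trsq + tr * tr * knu) * pref
            energy = energy + ad.vsum(dens * a0)

        pen = ((a_fluid - t_af) / t_af) ** 2 + ((vol - t_v) / t_v) ** 2
        if len(solid_fidx) and not mesh.rigid_core:
            pen = pen + ((a_solid - t_as) / t_as) ** 2
        energy = energy + pen * (penalty * b)

        g = ad.grad(energy, xfree)
        return float(energy.value), g.ravel()

    return fg


# ---------------------------------------------------------------------------
# equiangulation (Delaunay edge flips on fluid-fluid edges)
# ---------------------------------------------------------------------------

def equiangulate(mesh: TriangleMesh, max_passes: int = 3) -> int:
    """Flip fluid-fluid edges that violate the local Delaunay criterion.

    The solid patch topology (and hence its rest geometry) is never touched.
    Deterministic; returns the number of flips performed.
    """
    from .mesh import delaunay_flips
    fluid_mask = mesh.face_region == FLUID
    return delaunay_flips(mesh.faces, mesh.vertices, fluid_mask, max_passes)


def min_face_angle(mesh: TriangleMesh) -> float:
    from .mesh import _corner_angles
    return float(_corner_angles(mesh).min())


# ---------------------------------------------------------------------------
# rigid core handle
# ---------------------------------------------------------------------------

@dataclass
class RigidCoreConstraint:
    """Vertices of the planar core, held fixed during descent."""

    vertex_index: np.ndarray
    positions: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: TriangleMesh) -> "RigidCoreConstraint":
        core = enforce_rigid_core(mesh, mesh.solid_faces)
        return core


def enforce_rigid_core(mesh: TriangleMesh, core_faces: np.ndarray) -> RigidCoreConstraint:
    """Build the rigid-core constraint handle for the given disk faces.

    The core faces must form an edge-connected disk (single boundary loop);
    its vertices are frozen at their current (planar) positions, which fixes
    the in-plane distances exactly and removes the rigid-body gauge freedom.
    """
    core_faces = np.asarray(core_faces)
    if len(core_faces) == 0:
        raise MeshError("empty core")
    sub_region = np.where(np.isin(np.arange(len(mesh.faces)), core_faces),
                          SOLID, FLUID).astype(object)
    probe = TriangleMesh(mesh.vertices, mesh.faces, sub_region)
    from .mesh import boundary_loop
    boundary_loop(probe)  # raises unless the core is a disk with one rim
    vidx = np.unique(mesh.faces[core_faces])
    return RigidCoreConstraint(vertex_index=vidx,
                               positions=mesh.vertices[vidx].copy())


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def minimize_shape(mesh: TriangleMesh, params: MaterialParams,
                   config: MinimizeConfig) -> tuple[TriangleMesh, EnergyBreakdown, dict]:
    """Relax vertex positions at fixed phase areas and enclosed volume.

    Returns the relaxed mesh, its energy breakdown, and a diagnostics dict
    (per-stage objective values, constraint residuals, flip counts).
    Non-convergence is reported in ``diagnostics['converged']`` and raises
    :class:`ConvergenceError` when ``config.raise_on_failure`` is set.
    """
    mesh = mesh.copy()
    targets = config.resolved_targets(mesh)
    if mesh.rigid_core:
        core = enforce_rigid_core(mesh, mesh.solid_faces)
        free_idx = np.setdiff1d(np.arange(mesh.n_vertices), core.vertex_index)
    else:
        free_idx = np.arange(mesh.n_vertices)

    diag: dict = {"stages": [], "targets": targets}
    for si, stage in enumerate(config.stages):
        y_eff = params.Y * stage.y_scale
        fg = _objective(mesh, params, y_eff, stage.penalty, targets,
                        free_idx, mesh.vertices)
        x0 = mesh.vertices[free_idx].ravel()
        e0 = fg(x0)[0]
        res = _scipy_minimize(fg, x0, jac=True, method="L-BFGS-B",
                              options={"maxiter": stage.maxiter,
                                       "maxcor": 20,
                                       "gtol": config.gtol,
                                       "ftol": 1e-14})
        newv = mesh.vertices.copy()
        newv[free_idx] = res.x.reshape(-1, 3)
        # accept the stage unless it produced non-finite values, an energy
        # increase (failed line search) or a truly collapsed face; ordinary
        # slivers are left to the equiangulation pass
        reverted = True
        if np.all(np.isfinite(newv)) and np.isfinite(res.fun) \
                and res.fun <= e0 + 1e-10:
            if np.min(face_areas(mesh.copy(vertices=newv))) > 1e-14:
                mesh.vertices = newv
                reverted = False
        flips = 0
        trigger = np.deg2rad(config.min_angle_deg if not mesh.rigid_core
                             else max(config.min_angle_deg, 25.0))
        if (config.equiangulate and si < len(config.stages) - 1
                and min_face_angle(mesh) < trigger):
            flips = equiangulate(mesh)
        diag["stages"].append({
            "penalty": stage.penalty, "y_eff": y_eff,
            "E_start": float(e0), "E_end": float(res.fun),
            "nit": int(res.nit), "flips": flips, "reverted": reverted,
            "grad_norm": float(np.abs(res.jac).max()),
        })

    a_s = surface_area(mesh, SOLID) if len(mesh.solid_faces) else 0.0
    a_f = surface_area(mesh, FLUID)
    vol = enclosed_volume(mesh)
    t_as, t_af, t_v = targets
    resid = {
        "A_solid": abs(a_s - t_as) / t_as if t_as > 0 else 0.0,
        "A_fluid": abs(a_f - t_af) / t_af,
        "V": abs(vol - t_v) / t_v,
    }
    if mesh.rigid_core:
        resid["A_solid"] = 0.0  # held fixed exactly
    diag["residuals"] = resid
    diag["min_angle_deg"] = float(np.rad2deg(min_face_angle(mesh)))
    diag["converged"] = all(r < config.constraint_tol for r in resid.values())
    if not diag["converged"] and config.raise_on_failure:
        raise ConvergenceError(f"constraint residuals {resid} exceed "
                               f"{config.constraint_tol}", diag)
    breakdown = total_energy(mesh, params)
    return mesh, breakdown, diag
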