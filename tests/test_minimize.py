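"""Constrained shape relaxation: sphere ground state, determinism,
rigid-core constraints, developability."""

import numpy as np
import pytest

from vescomp.energy import MaterialParams, total_energy
from vescomp.flower import BuildSpec, build_core_vesicle, build_vesicle
from vescomp.mesh import (MeshError, icosphere, reduced_volume,
                          region_vertex_masks, surface_area,
                          vertex_gaussian_curvature)
from vescomp.minimize import (MinimizeConfig, Stage, enforce_rigid_core,
                              equiangulate, minimize_shape)

FLUID_STAGES = [Stage(1e3, 0.0, 120), Stage(1e5, 0.0, 250)]


@pytest.fixture(scope="module")
def relaxed_sphere():
    m = icosphere(3)
    cfg = MinimizeConfig(vbar=1.0, target_A_solid=0.0,
                         target_A_fluid=4 * np.pi, stages=FLUID_STAGES)
    return minimize_shape(m, MaterialParams(), cfg)


class TestPureFluid:
    def test_sphere_ground_state(self, relaxed_sphere):
        _, eb, diag = relaxed_sphere
        assert eb.Ebar == pytest.approx(1.0, abs=0.01)
        assert diag["converged"]

    def test_constraints_met(self, relaxed_sphere):
        m, _, diag = relaxed_sphere
        assert reduced_volume(m) == pytest.approx(1.0, abs=2e-3)
        assert max(diag["residuals"].values()) < 1e-3

    def test_deflated_prolate_branch_matches_axisymmetric_oracle(self):
        """1 < Ebar(0.95) < Ebar(0.85), with both endpoints within 10% of
        the independent axisymmetric quadrature optimum (the coarse mesh
        both under-resolves curvature and explores non-axisymmetric
        shapes, so the band is two-sided).  Deep deflation is reached by
        walking the volume target down with short, frequently re-meshed
        penalty stages — large jumps nucleate spiky local traps."""
        import sys
        from pathlib import Path
        sys.path.insert(0, str(Path(__file__).parent))
        from oracles import axisym_min_energy
        stages = [Stage(1e3, 0.0, 50)] * 4 + [Stage(1e4, 0.0, 50)] * 4 + \
            [Stage(1e5, 0.0, 50)] * 8
        out = {}
        m = icosphere(3)
        for vb in (0.95, 0.92, 0.89, 0.87, 0.85):
            cfg = MinimizeConfig(vbar=vb, target_A_solid=0.0,
                                 target_A_fluid=4 * np.pi, stages=stages,
                                 min_angle_deg=35.0)
            m, eb, diag = minimize_shape(m, MaterialParams(), cfg)
            out[vb] = eb.Ebar
        assert 1.0 < out[0.95] < out[0.85]
        for vb in (0.95, 0.85):
            oracle = axisym_min_energy(vb)
            assert 0.90 * oracle < out[vb] < 1.10 * oracle

    def test_energy_decreases_within_stage(self, relaxed_sphere):
        _, _, diag = relaxed_sphere
        for st in diag["stages"]:
            assert st["E_end"] <= st["E_start"] + 1e-12


class TestDeterminism:
    def test_identical_inputs_identical_result(self):
        res = []
        for _ in range(2):
            m = build_vesicle(BuildSpec(alpha=1.0, subdivisions=3, seed=3))
            cfg = MinimizeConfig(vbar=0.97,
                                 stages=[Stage(1e3, 1e-6, 60),
                                         Stage(1e4, 1e-4, 60)])
            _, eb, _ = minimize_shape(m, MaterialParams(), cfg)
            res.append(eb.E_elastic)
        assert res[0] == pytest.approx(res[1], abs=1e-10)


class TestRigidCore:
    @pytest.fixture(scope="class")
    def relaxed_core(self):
        m = build_core_vesicle(BuildSpec(core_mode="rigid_disk",
                                         phi_core=0.08, subdivisions=3, seed=0))
        cfg = MinimizeConfig(vbar=0.97,
                             target_A_fluid=4 * np.pi - surface_area(m, "solid"),
                             stages=FLUID_STAGES)
        relaxed, eb, diag = minimize_shape(m, MaterialParams(), cfg)
        return m, relaxed, eb, diag

    def test_core_planarity_preserved(self, relaxed_core):
        _, relaxed, _, _ = relaxed_core
        core_v = np.unique(relaxed.faces[relaxed.solid_faces])
        assert np.ptp(relaxed.vertices[core_v, 2]) < 1e-6

    def test_core_distances_preserved(self, relaxed_core):
        before, relaxed, _, _ = relaxed_core
        core_v = np.unique(relaxed.faces[relaxed.solid_faces])
        d0 = np.linalg.norm(before.vertices[core_v[0]] - before.vertices[core_v[1:]], axis=1)
        d1 = np.linalg.norm(relaxed.vertices[core_v[0]] - relaxed.vertices[core_v[1:]], axis=1)
        assert np.allclose(d0, d1, rtol=1e-8)

    def test_handle_requires_disk_topology(self, relaxed_core):
        before, _, _, _ = relaxed_core
        with pytest.raises(MeshError):
            enforce_rigid_core(before, np.array([0, len(before.faces) - 1]))

    def test_rigid_beats_elastic_energy(self, relaxed_core):
        """Releasing the rigidity constraint can only lower the energy.

        The elastic comparison starts from the relaxed rigid state itself:
        its flat disk becomes an elastic plate with the planar layout as
        rest geometry, and the re-relaxation must go (weakly) downhill.
        """
        _, relaxed, eb_rigid, _ = relaxed_core
        m = relaxed.copy()
        m.rigid_core = False
        tri = m.vertices[m.faces[m.solid_faces]]
        rest = np.empty((len(m.solid_faces), 3))
        for k in range(3):
            rest[:, k] = np.linalg.norm(tri[:, (k + 1) % 3]
                                        - tri[:, (k + 2) % 3], axis=1)
        m.rest_lengths = rest
        m.solid_face_index = m.solid_faces
        cfg = MinimizeConfig(vbar=0.97,
                             stages=[Stage(2e5, 1.0, 400),
                                     Stage(2e6, 1.0, 300)])
        _, eb_free, _ = minimize_shape(m, MaterialParams(), cfg)
        assert eb_rigid.E_elastic >= eb_free.E_elastic - 0.5


class TestMeshQuality:
    def test_equiangulate_improves_min_angle(self, rng):
        m = icosphere(2)
        m2 = m.copy(vertices=m.vertices +
                    0.05 * rng.normal(size=m.vertices.shape))
        from vescomp.minimize import min_face_angle
        before = min_face_angle(m2)
        flips = equiangulate(m2)
        m2.validate()
        assert min_face_angle(m2) >= before

    def test_solid_faces_never_flipped(self, composite_mesh):
        m = composite_mesh.copy()
        solid_before = m.faces[m.solid_faces].copy()
        equiangulate(m)
        m.validate()
        assert np.array_equal(m.faces[m.solid_faces], solid_before)


class TestDevelopability:
    def test_gaussian_curvature_drops_with_stiffness(self):
        """Stiffer solids expel Gaussian curvature more completely."""
        rms = []
        for t_over_r in (3e-2, 3e-3, 8.3e-5):
            m = build_vesicle(BuildSpec(alpha=1.0, phi=0.14,
                                        subdivisions=3, seed=1))
            params = MaterialParams(t_over_R=t_over_r)
            cfg = MinimizeConfig(vbar=0.96)
            relaxed, _, _ = minimize_shape(m, params, cfg)
            sv, fv, _ = region_vertex_masks(relaxed)
            k = vertex_gaussian_curvature(relaxed)
            from vescomp.mesh import mixed_voronoi_areas
            av = mixed_voronoi_areas(relaxed)
            rms.append(np.sqrt((k[sv] ** 2 * av[sv]).sum() / av[sv].sum()))
        assert rms[2] < rms[0]
        assert rms[2] < 0.15  # near-developable at the physical stiffness
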