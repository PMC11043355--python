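"""Inflation-curve analysis on synthetic curves, the effective-core closed
form, relative inflation, and the state map (mesh-driven trends are
exercised in the acceptance suite)."""

import numpy as np
import pandas as pd
import pytest

from vescomp.inflation import (CoreModel, InflationCurve, compact_boundary,
                               effective_core_fit, max_inflation_core,
                               reduced_perimeter, relative_inflation,
                               state_map, tension, zero_tension_volume)


def synthetic_curve(v0=0.93, c=40.0, alpha=1.0, n=11, lo=0.86, hi=1.0):
    v = np.linspace(lo, hi, n)
    return InflationCurve(v, 1.0 + c * (v - v0) ** 2, alpha=alpha, phi=0.14)


class TestZeroTension:
    def test_parabola_vertex_recovered(self):
        c = synthetic_curve(v0=0.93)
        assert zero_tension_volume(c) == pytest.approx(0.93, abs=1e-6)

    def test_tension_vanishes_at_vbar0(self):
        c = synthetic_curve(v0=0.95)
        v0 = zero_tension_volume(c)
        assert tension(c, vbar=v0) == pytest.approx(0.0, abs=1e-6)

    def test_boundary_minimum_rejected(self):
        c = synthetic_curve(v0=0.80)  # vertex below the grid
        with pytest.raises(ValueError, match="boundary"):
            zero_tension_volume(c)


class TestTension:
    def test_analytic_quadratic_derivative(self):
        v0, cc = 0.92, 55.0
        c = synthetic_curve(v0=v0, c=cc)
        a, b = 4 * np.pi, 1.0
        for vb in (0.90, 0.95, 0.98):
            expected = 12 * np.pi * b / a * vb * 2 * cc * (vb - v0)
            assert tension(c, a, b, vb) == pytest.approx(expected, rel=2e-3)

    def test_sign_convention(self):
        c = synthetic_curve(v0=0.93)
        assert tension(c, vbar=0.97) > 0  # inflated above rest: tensed
        assert tension(c, vbar=0.89) < 0

    def test_extrapolation_rejected(self):
        c = synthetic_curve()
        with pytest.raises(ValueError, match="outside"):
            tension(c, vbar=0.5)


class TestCoreGeometry:
    def test_sphere_limit(self):
        assert max_inflation_core(1e-6) == pytest.approx(1.0, abs=1e-5)

    def test_monotone_decreasing(self):
        phis = np.linspace(0.01, 0.3, 25)
        vm = [max_inflation_core(p) for p in phis]
        assert np.all(np.diff(vm) < 0)

    def test_bruteforce_cross_check(self):
        import sys
        from pathlib import Path
        sys.path.insert(0, str(Path(__file__).parent))
        from oracles import core_vmax_bruteforce
        for phi in (0.02, 0.1, 0.14, 0.3):
            assert max_inflation_core(phi) == pytest.approx(
                core_vmax_bruteforce(phi), abs=1e-6)

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            max_inflation_core(0.7)


class TestRelativeInflation:
    def test_endpoints_and_midpoint(self):
        assert relative_inflation(0.93, 0.93, 0.99) == 0.0
        assert relative_inflation(0.99, 0.93, 0.99) == 1.0
        assert relative_inflation(0.96, 0.93, 0.99) == pytest.approx(0.5)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            relative_inflation(0.95, 0.95, 0.95)


class TestEffectiveCoreFit:
    def test_interpolates_matching_candidate(self):
        flower = synthetic_curve(v0=0.94, alpha=3.0)
        cores = {0.04: synthetic_curve(v0=0.96, alpha=np.nan),
                 0.08: synthetic_curve(v0=0.94, alpha=np.nan),
                 0.12: synthetic_curve(v0=0.92, alpha=np.nan)}
        model = effective_core_fit(flower, cores)
        assert model.phi_core == pytest.approx(0.08, abs=1e-3)
        assert model.vbar_max == pytest.approx(max_inflation_core(0.08))
        assert model.curve_rms < 1e-12  # identical parabola shapes

    def test_unbracketed_target_raises(self):
        flower = synthetic_curve(v0=0.99)
        cores = {0.10: synthetic_curve(v0=0.90), 0.2: synthetic_curve(v0=0.88)}
        with pytest.raises(ValueError, match="bracket"):
            effective_core_fit(flower, cores)


class TestStateMap:
    def _curves(self):
        # flowering lowers elastic energy and shifts the minimum upward
        return {1.0: synthetic_curve(v0=0.92, c=60, alpha=1.0),
                2.0: synthetic_curve(v0=0.95, c=45, alpha=2.0),
                4.0: synthetic_curve(v0=0.97, c=35, alpha=4.0)}

    def test_sigma_zero_gives_elastic_optimum(self):
        curves = self._curves()
        df = state_map(curves, np.array([0.90, 0.99]), np.array([100.0]),
                       sigma_scale=0.0)
        for _, row in df.iterrows():
            elastic = {al: 8 * np.pi * float(c.interpolator()(row.vbar))
                       for al, c in curves.items()}
            assert row.alpha_opt == min(elastic, key=elastic.get)

    def test_compact_wins_at_low_inflation(self):
        df = state_map(self._curves(), np.array([0.87]), np.array([500.0]))
        assert set(df.alpha_opt) == {1.0}

    def test_flowering_wins_when_inflated(self):
        # near full inflation the elastic relief of petals beats line energy
        df = state_map(self._curves(), np.array([0.995]), np.array([2.0]))
        assert df.alpha_opt.iloc[0] > 1.0

    def test_alpha_monotone_in_inflation_at_fixed_size(self):
        df = state_map(self._curves(), np.linspace(0.87, 0.995, 12),
                       np.array([3.0]))
        assert np.all(np.diff(df.alpha_opt.to_numpy()) >= 0)

    def test_unique_optimum_with_tie_breaking(self):
        curves = {1.0: synthetic_curve(alpha=1.0),
                  2.0: synthetic_curve(alpha=2.0)}  # identical energies
        df = state_map(curves, np.array([0.90]), np.array([0.0]),
                       sigma_scale=0.0)
        assert df.alpha_opt.iloc[0] == 1.0  # smallest alpha wins exact ties

    def test_perimeter_increases_with_alpha(self):
        p = [reduced_perimeter(al, 0.14) for al in (1.0, 2.0, 4.0)]
        assert p[0] < p[1] < p[2]

    def test_compact_boundary_extraction(self):
        df = state_map(self._curves(), np.linspace(0.87, 0.998, 16),
                       np.array([0.5, 2.0]))
        cb = compact_boundary(df)
        assert len(cb) == 2
        assert cb.vbar_boundary.notna().all()
        # the line-energy term grows with size: flowering needs more
        # inflation on larger vesicles at fixed curve shapes
        assert cb.vbar_boundary.iloc[1] >= cb.vbar_boundary.iloc[0]
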