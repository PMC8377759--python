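import math

import numpy as np
import pytest

from pbfield.pbe import (
    GridSpec,
    ResourceError,
    SolverConfig,
    boundary_potential,
    build_grid,
    coulomb_constant,
    debye_kappa2,
    map_dielectric,
    map_kappa,
    solve_pbe,
    spread_charges,
    write_dx,
)
from pbfield.structures import Atom, Structure
from pbfield.synth import make_dimer


def _atom(pos=(0, 0, 0), q=1.0, r=2.0):
    return Structure([Atom("Q", "ION", 1, "", np.array(pos, dtype=float), q, r)])


class TestGridConstruction:
    def test_dims_from_bounding_box(self):
        g = build_grid(_atom(r=2.0), spacing=1.0, padding=10.0)
        assert g.dims == (25, 25, 25)

    def test_halving_spacing_roughly_doubles_dims(self):
        g1 = build_grid(_atom(r=2.0), spacing=1.0, padding=10.0)
        g2 = build_grid(_atom(r=2.0), spacing=0.5, padding=10.0)
        for d1, d2 in zip(g1.dims, g2.dims):
            assert abs(d2 - 2 * d1) <= 3 and d2 % 2 == 1

    def test_atom_outside_fixed_box_rejected(self):
        with pytest.raises(ResourceError):
            build_grid(
                _atom(pos=(40, 0, 0)),
                spacing=1.0,
                padding=10.0,
                center=np.zeros(3),
                dims=(33, 33, 33),
            )

    def test_oversized_grid_advises_coarser_spacing(self):
        with pytest.raises(ResourceError, match="coarser"):
            build_grid(_atom(), spacing=0.1, padding=20.0)

    def test_min_padding_enforced(self):
        with pytest.raises(ValueError):
            build_grid(_atom(), spacing=1.0, padding=2.0)

    def test_gridspec_invariants(self):
        with pytest.raises(ValueError):
            GridSpec(0.0, (25, 25, 25), (0, 0, 0))
        with pytest.raises(ValueError):
            GridSpec(1.0, (5, 25, 25), (0, 0, 0))


class TestCoefficientMaps:
    def test_empty_structure_uniform_solvent(self):
        g = GridSpec(1.0, (11, 11, 11), (0.0, 0.0, 0.0))
        cfg = SolverConfig()
        eps = map_dielectric(Structure([]), g, cfg)
        assert np.all(eps.ex == cfg.eps_out)
        assert np.all(eps.ey == cfg.eps_out)
        assert np.all(eps.ez == cfg.eps_out)

    def test_edge_midpoint_inside_probe_sphere_gets_eps_in(self):
        s = _atom(pos=(5.0, 5.0, 5.0), r=2.0)
        g = GridSpec(1.0, (11, 11, 11), (0.0, 0.0, 0.0))
        cfg = SolverConfig()
        eps = map_dielectric(s, g, cfg)
        # x-edge between (5,5,5) and (6,5,5): midpoint 0.5 Å from center
        assert eps.ex[5, 5, 5] == cfg.eps_in
        # far corner edge stays solvent
        assert eps.ex[0, 0, 0] == cfg.eps_out

    def test_interior_fraction_grows_with_probe(self):
        s = _atom(pos=(8.0, 8.0, 8.0), r=2.0)
        g = GridSpec(1.0, (17, 17, 17), (0.0, 0.0, 0.0))
        fractions = []
        for probe in (0.0, 1.0, 2.0, 3.0):
            eps = map_dielectric(s, g, SolverConfig(probe_radius=probe))
            fractions.append(float(np.mean(eps.ex == 2.0)))
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > fractions[0]

    def test_salt_zero_kappa_zero(self):
        g = GridSpec(1.0, (11, 11, 11), (0.0, 0.0, 0.0))
        k = map_kappa(_atom(), g, SolverConfig(salt=0.0))
        assert np.all(k.kappa2 == 0.0)

    def test_debye_length_from_physical_constants(self):
        # 0.15 M 1:1 salt in eps 80 at 300 K: Debye length about 7.9 Å
        k2 = debye_kappa2(0.15, 80.0, 300.0)
        assert 1.0 / math.sqrt(k2) == pytest.approx(7.95, abs=0.08)

    def test_stern_layer_boundary(self):
        s = _atom(pos=(8.0, 8.0, 8.0), r=2.0)
        g = GridSpec(1.0, (17, 17, 17), (0.0, 0.0, 0.0))
        cfg = SolverConfig(salt=0.15, stern_layer=2.0)
        k = map_kappa(s, g, cfg)
        # node at distance 3.9 from center: inside radius+stern=4 -> excluded
        assert k.kappa2[12, 8, 8] == 0.0  # distance 4.0 -> on boundary, inside
        assert k.kappa2[13, 8, 8] == pytest.approx(cfg.kappa2_bulk)

    def test_negative_salt_rejected(self):
        with pytest.raises(ValueError):
            debye_kappa2(-0.1, 80.0)


class TestBoundaryConditions:
    def test_single_charge_no_salt_matches_coulomb(self, coulomb_kT):
        s = _atom(q=1.0, r=0.0)
        g = build_grid(s, spacing=1.0, padding=10.0)
        cfg = SolverConfig(salt=0.0, boundary="per_atom")
        phi = boundary_potential(s, g, cfg)
        X, Y, Z = np.meshgrid(*g.axes(), indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        face = np.zeros(g.dims, dtype=bool)
        face[0] = face[-1] = True
        expected = coulomb_kT / (cfg.eps_out * r[face])
        np.testing.assert_allclose(phi[face], expected, rtol=1e-10)

    def test_dipolar_monopole_vanishes_for_neutral_solute(self):
        dimer = make_dimer(1.0, -1.0, 2.0)
        g = build_grid(dimer, spacing=1.0, padding=20.0)
        cfg = SolverConfig(salt=0.0, boundary="dipolar")
        phi = boundary_potential(dimer, g, cfg)
        # neutral solute: boundary is a pure dipole pattern, odd under x-flip
        np.testing.assert_allclose(phi[0, :, :], -phi[-1, :, :], atol=1e-9)

    def test_per_atom_and_dipolar_agree_far_away(self):
        dimer = make_dimer(1.0, -1.0, 1.0)
        g = build_grid(dimer, spacing=1.0, padding=20.0)
        cfg_a = SolverConfig(salt=0.0, boundary="per_atom")
        cfg_d = SolverConfig(salt=0.0, boundary="dipolar")
        pa = boundary_potential(dimer, g, cfg_a)
        pd = boundary_potential(dimer, g, cfg_d)
        face = np.zeros(g.dims, dtype=bool)
        for ax in range(3):
            face[(slice(None),) * ax + (0,)] = True
            face[(slice(None),) * ax + (-1,)] = True
        a, d = pa[face], pd[face]
        big = np.abs(a) > 0.1 * np.abs(a).max()  # skip near-zero equator nodes
        np.testing.assert_allclose(d[big], a[big], rtol=0.05)

    def test_zero_mode(self):
        s = _atom()
        g = build_grid(s, spacing=1.0, padding=10.0)
        phi = boundary_potential(s, g, SolverConfig(boundary="zero"))
        assert np.all(phi == 0.0)


class TestChargeSpreading:
    @pytest.mark.parametrize("method", ["trilinear", "cubic"])
    def test_total_charge_conserved(self, method):
        s = _atom(pos=(0.3, -0.2, 0.7), q=-2.5)
        g = GridSpec(1.0, (21, 21, 21), (-10.0, -10.0, -10.0))
        q = spread_charges(s, g, method)
        assert q.sum() == pytest.approx(-2.5, abs=1e-12)

    @pytest.mark.parametrize("method", ["trilinear", "cubic"])
    def test_dipole_moment_conserved(self, method):
        s = _atom(pos=(0.3, -0.2, 0.7), q=1.0)
        g = GridSpec(1.0, (21, 21, 21), (-10.0, -10.0, -10.0))
        q = spread_charges(s, g, method)
        axes = g.axes()
        com = [float((q.sum(axis=tuple(a for a in range(3) if a != ax)) * axes[ax]).sum())
               for ax in range(3)]
        np.testing.assert_allclose(com, [0.3, -0.2, 0.7], atol=1e-12)

    def test_atom_near_boundary_rejected(self):
        s = _atom(pos=(-9.5, 0, 0))
        g = GridSpec(1.0, (21, 21, 21), (-10.0, -10.0, -10.0))
        with pytest.raises(ValueError):
            spread_charges(s, g, "cubic")


class TestSolver:
    def test_no_charge_zero_boundary_gives_zero(self):
        s = _atom(q=0.0)
        g = build_grid(s, spacing=1.0, padding=10.0)
        pot = solve_pbe(s, g, SolverConfig(boundary="zero", salt=0.0))
        assert np.all(pot.values == 0.0)
        assert pot.convergence.converged

    def test_linearity_in_charges(self, uniform_water):
        s1 = _atom(q=1.0, r=0.0)
        s2 = _atom(q=2.0, r=0.0)
        g = build_grid(s1, spacing=1.0, padding=12.0)
        p1 = solve_pbe(s1, g, uniform_water)
        p2 = solve_pbe(s2, g, uniform_water)
        scale = np.abs(p1.values).max()
        np.testing.assert_allclose(
            p2.values, 2 * p1.values, atol=5 * uniform_water.tolerance * scale
        )

    def test_superposition_uniform_dielectric(self, uniform_water):
        a = Structure([Atom("Q1", "ION", 1, "", np.array([-3.0, 0, 0]), 1.0, 0.0)])
        b = Structure([Atom("Q2", "ION", 2, "", np.array([3.0, 0, 0]), -1.0, 0.0)])
        both = Structure([a[0].copy(), b[0].copy()])
        g = build_grid(both, spacing=1.0, padding=12.0)
        pa = solve_pbe(a, g, uniform_water).values
        pb = solve_pbe(b, g, uniform_water).values
        pab = solve_pbe(both, g, uniform_water).values
        scale = max(np.abs(pa).max(), np.abs(pb).max())
        np.testing.assert_allclose(
            pab, pa + pb, atol=10 * uniform_water.tolerance * scale
        )

    def test_refinement_reduces_coulomb_error(self, uniform_water, coulomb_kT):
        s = _atom(q=1.0, r=0.0)

        def max_err(spacing, dims):
            g = build_grid(
                s, spacing=spacing, padding=14.0, dims=dims, center=np.zeros(3)
            )
            pot = solve_pbe(s, g, uniform_water)
            X, Y, Z = np.meshgrid(*g.axes(), indexing="ij")
            r = np.sqrt(X**2 + Y**2 + Z**2)
            m = (r >= 3) & (r <= 8)
            oracle = coulomb_kT / (80.0 * r[m])
            return np.abs(pot.values[m] - oracle).max() / oracle.max()

        assert max_err(0.5, (65, 65, 65)) < max_err(1.0, (33, 33, 33))

    def test_centered_charge_symmetric_under_axis_permutation(
        self, point_charge_solution
    ):
        _, pot = point_charge_solution
        v = pot.values
        tol = 20 * pot.config.tolerance * np.abs(v).max()
        np.testing.assert_allclose(v, v.transpose(1, 0, 2), atol=tol)
        np.testing.assert_allclose(v, v.transpose(2, 1, 0), atol=tol)

    def test_nonlinear_damps_high_potential_and_matches_linear_at_low_charge(self):
        s = _atom(q=5.0, r=2.0)
        g = build_grid(s, spacing=1.0, padding=10.0)
        lin = solve_pbe(s, g, SolverConfig(salt=0.15, mode="linear"))
        non = solve_pbe(s, g, SolverConfig(salt=0.15, mode="nonlinear"))
        hot = np.abs(lin.values) > 2.0  # counter-ion saturation region
        assert np.abs(non.values[hot]).max() < np.abs(lin.values[hot]).max()
        # weak source: sinh(phi) ~ phi, the two modes coincide
        s0 = _atom(q=0.01, r=2.0)
        lin0 = solve_pbe(s0, g, SolverConfig(salt=0.15, mode="linear"))
        non0 = solve_pbe(s0, g, SolverConfig(salt=0.15, mode="nonlinear"))
        np.testing.assert_allclose(
            non0.values, lin0.values, atol=1e-4 * np.abs(lin0.values).max()
        )

    def test_convergence_report_attached(self, point_charge_solution):
        _, pot = point_charge_solution
        assert pot.convergence.converged
        assert pot.convergence.residual < pot.config.tolerance
        assert len(pot.convergence.history) == pot.convergence.iterations


def test_dx_round_trip(tmp_path, point_charge_solution):
    from gridData import Grid

    _, pot = point_charge_solution
    path = tmp_path / "phi.dx"
    write_dx(pot, path)
    g = Grid(str(path))
    np.testing.assert_allclose(g.grid, pot.values, rtol=1e-6)
    np.testing.assert_allclose(g.origin, pot.grid.origin)


def test_non_convergence_carries_residual_history():
    from pbfield.pbe import ConvergenceError

    s = _atom(q=1.0, r=0.0)
    g = build_grid(s, spacing=1.0, padding=10.0)
    cfg = SolverConfig(salt=0.0, tolerance=1e-12, max_iterations=3)
    with pytest.raises(ConvergenceError) as err:
        solve_pbe(s, g, cfg)
    assert len(err.value.history) == 3
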