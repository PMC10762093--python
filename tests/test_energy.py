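"""Energetics: sharp-interface limits, Gauss-Bonnet quantization, assembly."""

import numpy as np
import pytest

from fusefield import energy as en
from fusefield.fields import compose_union, tanh_interface, tanh_sphere
from fusefield.grid import build_grid
from fusefield.params import ConstraintSet, PhysParams


@pytest.fixture(scope="module")
def sphere20(phys_mod):
    g = build_grid(96, 192, 48.0, -48.0, 48.0)
    return g, tanh_sphere(0.0, 20.0, phys_mod, g)


@pytest.fixture(scope="module")
def phys_mod():
    return PhysParams()


class TestBending:
    def test_psi_vanishes_on_exact_slab(self, grid_fine, phys):
        phi = tanh_interface(0.0, phys, grid_fine)
        psi = en.psi_bending(phi, phys, grid_fine)
        assert np.abs(psi).max() * phys.eps**2 < 1e-6

    def test_psi_on_plateau_and_at_zero(self, grid_coarse):
        p0 = PhysParams(m=0.0)
        ones = np.ones(grid_coarse.shape)
        assert np.abs(en.psi_bending(ones, p0, grid_coarse)).max() < 1e-12
        pm = PhysParams(m=0.5)
        zeros = np.zeros(grid_coarse.shape)
        expected = np.sqrt(2.0) * pm.m / pm.eps
        np.testing.assert_allclose(
            en.psi_bending(zeros, pm, grid_coarse), expected, rtol=1e-12
        )

    def test_slab_energy_negligible(self, grid_coarse, phys):
        phi = tanh_interface(0.0, phys, grid_coarse)
        assert en.energy_bending(phi, phys, grid_coarse) < 1e-4

    def test_sphere_approaches_willmore_value(self, sphere20, phys_mod):
        g, phi = sphere20
        E = en.energy_bending(phi, phys_mod, g)
        assert E == pytest.approx(8.0 * np.pi * phys_mod.k, rel=0.03)

    def test_spontaneous_curvature_cancels_sphere_energy(self, phys_mod):
        R = 20.0
        p = PhysParams(m=1.0 / R)
        g = build_grid(96, 192, 48.0, -48.0, 48.0)
        phi = tanh_sphere(0.0, R, p, g)
        E = en.energy_bending(phi, p, g)
        assert E <= 0.03 * 8.0 * np.pi * p.k


class TestGaussian:
    def test_psi_vanishes_for_unidirectional_field(self, grid_fine, phys):
        phi = tanh_interface(3.0, phys, grid_fine)
        psi = en.psi_gaussian(phi, grid_fine)
        assert np.abs(psi).max() < 1e-6

    def test_psi_zero_for_constant(self, grid_coarse):
        assert np.abs(
            en.psi_gaussian(np.full(grid_coarse.shape, 0.3), grid_coarse)
        ).max() < 1e-12

    def test_sphere_gauss_bonnet(self, sphere20, phys_mod):
        g, phi = sphere20
        EG = en.energy_gaussian(phi, -np.ones(g.shape), phys_mod, g)
        assert EG == pytest.approx(4.0 * np.pi * phys_mod.kG0, rel=0.03)

    def test_patch_everywhere_kills_gaussian_energy(self, sphere20, phys_mod):
        g, phi = sphere20
        EG = en.energy_gaussian(phi, np.ones(g.shape), phys_mod, g)
        assert abs(EG) < 1e-10

    @pytest.mark.parametrize(
        "radii", [(14.0, 14.0), (11.0, 17.0), (9.0, 20.0)]
    )
    def test_topological_jump_independent_of_radii(self, phys_mod, radii):
        # E_G(two spheres) - E_G(one) = 4 pi kG regardless of radii
        Ra, Rb = radii
        h = 0.5
        g = build_grid(64, 256, 32.0, -64.0, 64.0)
        eta = -np.ones(g.shape)
        two = compose_union(
            [
                tanh_sphere(-(Rb + 8.0), Ra, phys_mod, g),
                tanh_sphere(Ra + 8.0, Rb, phys_mod, g),
            ]
        )
        one = tanh_sphere(0.0, Ra, phys_mod, g)
        jump = en.energy_gaussian(two, eta, phys_mod, g) - en.energy_gaussian(
            one, eta, phys_mod, g
        )
        assert jump == pytest.approx(4.0 * np.pi * phys_mod.kG0, rel=0.03)


class TestModulusMap:
    def test_reference_values(self):
        assert en.kg_of_eta(-1.0, -20.0) == pytest.approx(-20.0)
        assert en.kg_of_eta(+1.0, -20.0) == 0.0
        assert en.kg_of_eta(0.0, -20.0) == pytest.approx(-5.0)

    def test_derivative_vanishes_on_patch(self):
        assert en.kg_prime_of_eta(1.0, -20.0) == 0.0


class TestAuxiliaryAndOrthogonality:
    def test_uniform_eta_zero_energy(self, grid_coarse, phys):
        for val in (-1.0, 1.0):
            eta = np.full(grid_coarse.shape, val)
            assert en.energy_auxiliary(eta, phys, grid_coarse) < 1e-20

    def test_equilibrium_eta_profile_near_zero(self, grid_coarse, phys):
        eta = tanh_interface(0.0, phys, grid_coarse)
        assert en.energy_auxiliary(eta, phys, grid_coarse) < 1e-7

    def test_double_width_profile_costs_energy(self, grid_coarse, phys):
        wide = np.tanh(grid_coarse.zmesh / (2.0 * np.sqrt(2.0) * phys.eps))
        assert en.energy_auxiliary(wide, phys, grid_coarse) > 1e-2

    def test_orthogonality_zero_for_constant_eta(self, grid_coarse, phys):
        phi = tanh_interface(0.0, phys, grid_coarse)
        eta = np.full(grid_coarse.shape, -1.0)
        assert en.orthogonality_penalty(phi, eta, grid_coarse) == pytest.approx(0.0)

    def test_orthogonal_gradients_give_zero(self, grid_coarse, phys):
        g = grid_coarse
        phi = tanh_interface(0.0, phys, g)        # varies along z
        eta = np.tanh((10.0 - g.rmesh) / np.sqrt(2.0))  # varies along r
        O = en.orthogonality_penalty(phi, eta, g)
        assert O < 1e-8 * max(en.orthogonality_penalty(phi, phi, g), 1.0)

    def test_self_overlap_matches_direct_quadrature(self, grid_coarse, phys):
        g = grid_coarse
        phi = tanh_interface(0.0, phys, g)
        O = en.orthogonality_penalty(phi, phi, g)
        phi_r, phi_z = g.gradient(phi)
        direct = g.integrate((phi_r**2 + phi_z**2) ** 2)
        assert O == pytest.approx(direct, rel=1e-12)
        assert O > 0.0


class TestConstraintFunctionals:
    def test_plateau_fields_have_zero_area(self, grid_coarse, phys):
        for val in (-1.0, 1.0):
            f = np.full(grid_coarse.shape, val)
            assert en.area_functional(f, phys, grid_coarse) < 1e-20

    def test_sphere_area_and_volume(self, sphere20, phys_mod):
        g, phi = sphere20
        R = 20.0
        assert en.area_functional(phi, phys_mod, g) == pytest.approx(
            4.0 * np.pi * R**2, rel=0.02
        )
        assert en.volume_functional(phi, g) == pytest.approx(
            4.0 / 3.0 * np.pi * R**3, rel=0.02
        )

    def test_volume_limits(self, grid_coarse):
        g = grid_coarse
        assert en.volume_functional(-np.ones(g.shape), g) == pytest.approx(0.0)
        assert en.volume_functional(np.ones(g.shape), g) == pytest.approx(
            g.domain_measure, rel=1e-12
        )

    def test_area_additive_for_disjoint_spheres(self, phys_mod):
        g = build_grid(64, 256, 32.0, -64.0, 64.0)
        a = tanh_sphere(-30.0, 13.0, phys_mod, g)
        b = tanh_sphere(+30.0, 13.0, phys_mod, g)
        A_union = en.area_functional(compose_union([a, b]), phys_mod, g)
        A_sum = en.area_functional(a, phys_mod, g) + en.area_functional(
            b, phys_mod, g
        )
        assert A_union == pytest.approx(A_sum, rel=5e-3)

    def test_patch_area_bounds_and_uniform_cases(self, sphere20, phys_mod):
        g, phi = sphere20
        assert en.patch_area_functional(
            phi, -np.ones(g.shape), phys_mod, g
        ) == pytest.approx(0.0)
        full = en.patch_area_functional(phi, np.ones(g.shape), phys_mod, g)
        assert full == pytest.approx(en.area_functional(phi, phys_mod, g), rel=1e-12)


class TestSharpInterfaceConvergence:
    def test_monotone_error_decay_with_radius(self):
        # relative errors of E_B, E_G, A, V all fall monotonically in R/eps
        p = PhysParams()
        errs = {"EB": [], "EG": [], "A": [], "V": []}
        h = 1.0 / 3.0
        for R in (10.0, 20.0, 40.0, 80.0):
            ext = R + 18.0
            n = int(round(ext / h))
            g = build_grid(n, 2 * n, ext, -ext, ext)
            phi = tanh_sphere(0.0, R, p, g)
            eta = -np.ones(g.shape)
            errs["EB"].append(
                abs(en.energy_bending(phi, p, g) / (8 * np.pi * p.k) - 1)
            )
            errs["EG"].append(
                abs(en.energy_gaussian(phi, eta, p, g) / (4 * np.pi * p.kG0) - 1)
            )
            errs["A"].append(
                abs(en.area_functional(phi, p, g) / (4 * np.pi * R**2) - 1)
            )
            errs["V"].append(
                abs(en.volume_functional(phi, g) / (4 / 3 * np.pi * R**3) - 1)
            )
        for name, seq in errs.items():
            assert all(a > b for a, b in zip(seq, seq[1:])), (name, seq)

    def test_energies_scale_linearly_with_moduli(self, sphere20):
        g, phi = sphere20
        eta = np.tanh((8.0 - np.abs(g.zmesh)) / np.sqrt(2.0))
        p1 = PhysParams(k=20.0, kG0=-20.0)
        p3 = PhysParams(k=60.0, kG0=-60.0)
        assert en.energy_bending(phi, p3, g) == pytest.approx(
            3.0 * en.energy_bending(phi, p1, g), rel=1e-12
        )
        assert en.energy_gaussian(phi, eta, p3, g) == pytest.approx(
            3.0 * en.energy_gaussian(phi, eta, p1, g), rel=1e-12
        )


class TestModifiedEnergyAssembly:
    def test_free_case_reduces_to_elastic_plus_auxiliary(self, sphere20, phys_mod):
        g, phi = sphere20
        eta = -np.ones(g.shape)
        c = ConstraintSet()  # all multipliers and penalties zero
        rep = en.total_modified_energy(phi, eta, phys_mod, c, g)
        assert rep.E_bar == pytest.approx(rep.E_B + rep.E_G + rep.E_A, rel=1e-12)
        assert rep.E == rep.E_B + rep.E_G

    def test_satisfied_constraints_add_nothing(self, sphere20, phys_mod):
        g, phi = sphere20
        eta = -np.ones(g.shape)
        free = en.total_modified_energy(phi, eta, phys_mod, ConstraintSet(), g)
        c = ConstraintSet(
            A0=free.A, V0=free.V, P0=free.P, M1=10.0, M2=10.0, M3=10.0, M4=10.0,
            gamma=1.0, delta_p=1.0, gamma_p=1.0,
        )
        rep = en.total_modified_energy(phi, eta, phys_mod, c, g)
        assert rep.E_bar == pytest.approx(free.E + free.E_A, abs=1e-8)

    def test_quadratic_penalty_increment(self, sphere20, phys_mod):
        g, phi = sphere20
        eta = -np.ones(g.shape)
        free = en.total_modified_energy(phi, eta, phys_mod, ConstraintSet(), g)
        delta = 7.0
        c = ConstraintSet(A0=free.A - delta, V0=free.V, P0=free.P, M1=3.0)
        rep = en.total_modified_energy(phi, eta, phys_mod, c, g)
        assert rep.E_bar - (free.E + free.E_A) == pytest.approx(
            0.5 * 3.0 * delta**2, rel=1e-9
        )

    def test_nonnegativity_of_square_integrals(self, grid_coarse, rng, phys):
        from tests.conftest import smooth_bump_field

        f = smooth_bump_field(grid_coarse, rng)
        h = smooth_bump_field(grid_coarse, rng)
        assert en.energy_bending(f, phys, grid_coarse) >= 0.0
        assert en.energy_auxiliary(h, phys, grid_coarse) >= 0.0
        assert en.orthogonality_penalty(f, h, grid_coarse) >= 0.0
        assert en.area_functional(f, phys, grid_coarse) >= 0.0
        assert en.patch_area_functional(f, h, phys, grid_coarse) >= 0.0
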