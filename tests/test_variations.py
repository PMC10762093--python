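"""Functional derivatives against central finite-difference oracles.

The directional-derivative oracle (E[f + h v] - E[f - h v]) / 2h is the
accuracy authority for every closed-form variation, including the
axisymmetric Gaussian-energy derivative with variable modulus.
"""

import numpy as np
import pytest

from fusefield import energy as en
from fusefield import variations as va
from fusefield.fields import tanh_interface, tanh_sphere
from fusefield.grid import build_grid
from fusefield.params import ConstraintSet, PhysParams

from .conftest import smooth_bump_field


@pytest.fixture(scope="module")
def oracle_setup():
    """Fine grid + representative membrane-like fields + test directions."""
    p = PhysParams()
    g = build_grid(160, 320, 32.0, -32.0, 32.0)   # h = 0.2 eps
    rng = np.random.default_rng(7)
    phi = tanh_sphere(0.0, 14.0, p, g) + 0.05 * smooth_bump_field(g, rng)
    eta = np.tanh((6.0 - np.abs(g.zmesh)) / np.sqrt(2.0)) + 0.05 * smooth_bump_field(g, rng)
    dirs = [smooth_bump_field(g, rng) for _ in range(5)]
    return p, g, phi, eta, dirs


def _fd(ef, f0, v, h):
    return (ef(f0 + h * v) - ef(f0 - h * v)) / (2.0 * h)


class TestBendingVariation:
    def test_zero_on_equilibrium_slab(self, grid_fine, phys):
        phi = tanh_interface(0.0, phys, grid_fine)
        gphi = va.d_bending_dphi(phi, phys, grid_fine)
        assert np.abs(gphi).max() < 1e-3

    def test_zero_on_plateau(self, grid_coarse, phys):
        gphi = va.d_bending_dphi(np.ones(grid_coarse.shape), phys, grid_coarse)
        assert np.abs(gphi).max() < 1e-12

    def test_directional_derivative_oracle(self, oracle_setup):
        p, g, phi, eta, dirs = oracle_setup
        gphi = va.d_bending_dphi(phi, p, g)
        for v in dirs:
            num = _fd(lambda q: en.energy_bending(q, p, g), phi, v, 2e-6)
            ana = g.integrate(gphi * v)
            # floor set by the O(h^2) axis-quadrature adjointness error
            assert abs(num - ana) / abs(num) < 1e-4


class TestGaussianVariation:
    def test_flat_slab_uniform_modulus_inert(self, grid_coarse, phys):
        phi = tanh_interface(0.0, phys, grid_coarse)
        eta = -np.ones(grid_coarse.shape)
        gphi = va.d_gaussian_dphi(phi, eta, phys, grid_coarse)
        assert np.abs(gphi).max() < 1e-4

    def test_uniform_eta_leaves_only_curvature_term(self, oracle_setup):
        # with spatially uniform k_G only the 12 kG phi_r (...) term survives
        p, g, phi, _, _ = oracle_setup
        eta = -np.ones(g.shape)
        full = va.d_gaussian_dphi(phi, eta, p, g)
        phi_r, phi_rr = g.diff(phi, 0, (1, 2))
        phi_zz = g.d_zz(phi)
        phi_rz = g.d_z(phi_r)
        kg = en.kg_of_eta(-1.0, p.kG0)
        term = (
            35.0 / (8.0 * np.sqrt(2.0)) * p.eps**3 / g.rmesh
            * 12.0 * kg * phi_r * (phi_rz**2 - phi_rr * phi_zz)
        )
        np.testing.assert_allclose(full, term, atol=1e-12)

    def test_directional_derivative_oracle_phi(self, oracle_setup):
        p, g, phi, eta, dirs = oracle_setup
        gphi = va.d_gaussian_dphi(phi, eta, p, g)
        for v in dirs[:3]:
            num = _fd(lambda q: en.energy_gaussian(q, eta, p, g), phi, v, 1e-5)
            ana = g.integrate(gphi * v)
            assert abs(num - ana) / abs(num) < 1e-4

    def test_directional_derivative_oracle_eta(self, oracle_setup):
        p, g, phi, eta, dirs = oracle_setup
        geta = va.d_gaussian_deta(phi, eta, p, g)
        for v in dirs[:3]:
            num = _fd(lambda q: en.energy_gaussian(phi, q, p, g), eta, v, 1e-5)
            ana = g.integrate(geta * v)
            assert abs(num - ana) / abs(num) < 1e-4

    def test_patch_interior_exerts_no_eta_force(self, oracle_setup):
        p, g, phi, _, _ = oracle_setup
        eta = np.ones(g.shape)  # modulus derivative vanishes at eta = +1
        geta = va.d_gaussian_deta(phi, eta, p, g)
        assert np.abs(geta).max() == 0.0


class TestConstraintVariations:
    @pytest.mark.parametrize("which", ["area", "volume", "patch_phi",
                                       "patch_eta", "orth_phi", "orth_eta",
                                       "aux_eta"])
    def test_directional_oracles(self, oracle_setup, which):
        p, g, phi, eta, dirs = oracle_setup
        v = dirs[0]
        if which == "area":
            ana = g.integrate(va.d_area_dphi(phi, p, g) * v)
            num = _fd(lambda q: en.area_functional(q, p, g), phi, v, 1e-5)
        elif which == "volume":
            ana = g.integrate(va.d_volume_dphi(g) * v)
            num = _fd(lambda q: en.volume_functional(q, g), phi, v, 1e-5)
        elif which == "patch_phi":
            ana = g.integrate(va.d_patch_dphi(phi, eta, p, g) * v)
            num = _fd(lambda q: en.patch_area_functional(q, eta, p, g), phi, v, 1e-5)
        elif which == "patch_eta":
            ana = g.integrate(va.d_patch_deta(phi, eta, p, g) * v)
            num = _fd(lambda q: en.patch_area_functional(phi, q, p, g), eta, v, 1e-5)
        elif which == "orth_phi":
            ana = g.integrate(va.d_orthogonality_dphi(phi, eta, g) * v)
            num = _fd(lambda q: en.orthogonality_penalty(q, eta, g), phi, v, 1e-5)
        elif which == "orth_eta":
            ana = g.integrate(va.d_orthogonality_deta(phi, eta, g) * v)
            num = _fd(lambda q: en.orthogonality_penalty(phi, q, g), eta, v, 1e-5)
        else:
            ana = g.integrate(va.d_auxiliary_deta(eta, p, g) * v)
            num = _fd(lambda q: en.energy_auxiliary(q, p, g), eta, v, 1e-5)
        assert abs(num - ana) / max(abs(num), 1e-12) < 1e-4


@pytest.fixture(scope="module")
def constraints():
    c = ConstraintSet.for_targets(A0=2000.0, V0=9000.0, P0=60.0, k=20.0)
    c.gamma, c.delta_p, c.gamma_p = 0.3, -0.05, 0.2
    return c


class TestTotalVariation:

    def test_reduces_to_elastic_when_free(self, oracle_setup):
        p, g, phi, _, _ = oracle_setup
        eta = -np.ones(g.shape)
        free = ConstraintSet()
        total = va.d_total_dphi(phi, eta, p, free, g)
        elastic = va.d_bending_dphi(phi, p, g) + va.d_gaussian_dphi(phi, eta, p, g)
        np.testing.assert_allclose(total, elastic, atol=1e-12)

    def test_full_oracle_phi_and_eta(self, oracle_setup, constraints):
        p, g, phi, eta, dirs = oracle_setup
        gphi, geta, _ = va.grad_total(phi, eta, p, constraints, g)
        for v in dirs[:3]:
            num = _fd(
                lambda q: en.total_modified_energy(q, eta, p, constraints, g).E_bar,
                phi, v, 1e-6,
            )
            assert abs(num - g.integrate(gphi * v)) / abs(num) < 1e-4
            num_e = _fd(
                lambda q: en.total_modified_energy(phi, q, p, constraints, g).E_bar,
                eta, v, 1e-6,
            )
            assert abs(num_e - g.integrate(geta * v)) / abs(num_e) < 1e-4

    def test_explicit_euler_step_descends(self, oracle_setup, constraints):
        # gradient-flow consistency with backtracking on the step size
        p, g, phi, eta, _ = oracle_setup
        gphi, geta, _ = va.grad_total(phi, eta, p, constraints, g)
        E0 = en.total_modified_energy(phi, eta, p, constraints, g).E_bar
        dt = 1e-4
        for _ in range(20):
            E1 = en.total_modified_energy(
                phi - dt * gphi, eta - dt * geta, p, constraints, g
            ).E_bar
            if E1 < E0:
                break
            dt /= 2.0
        assert E1 < E0


class TestForceDensity:
    def test_zero_on_equilibrium_slab(self, grid_fine, phys):
        phi = tanh_interface(0.0, phys, grid_fine)
        eta = -np.ones(grid_fine.shape)
        fr, fz = va.force_density(phi, eta, phys, grid_fine)
        assert np.abs(fr).max() < 1e-3
        assert np.abs(fz).max() < 1e-3

    def test_zero_on_plateaus(self, oracle_setup):
        p, g, _, eta, _ = oracle_setup
        phi = tanh_sphere(0.0, 14.0, p, g)
        fr, fz = va.force_density(phi, eta, p, g)
        plateau = np.abs(phi) > 0.9999
        fmax = max(np.abs(fr).max(), np.abs(fz).max())
        assert np.abs(fr[plateau]).max() < 1e-3 * fmax
        assert np.abs(fz[plateau]).max() < 1e-3 * fmax
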