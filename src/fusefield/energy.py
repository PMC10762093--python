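"""Scalar functionals of the diffuse-interface membrane model.

The elastic energy is E[phi, eta] = E_B[phi] + E_G[phi, eta]:

    E_B = k * 3/(4 sqrt2) * eps * Int Psi_B^2 dV
    Psi_B = Lap phi - (phi^2 - 1)(phi + sqrt2 eps m) / eps^2

    E_G = 35/(16 sqrt2) * eps^3 * Int k_G(eta) Psi_G dV

with Psi_G a combination of phi derivatives whose sharp-interface limit
concentrates the Gaussian curvature on the membrane.  In that limit
(interface width small against vesicle size) E_B approaches the
Canham-Helfrich bending energy 2k Int (M - m)^2 dS and E_G approaches
k_G Int G dS, so that for a closed vesicle of genus 0 with uniform k_G the
Gaussian energy is quantized at 4 pi k_G (Gauss-Bonnet).

The locally variable Gaussian modulus is carried by the auxiliary field:
k_G(eta) = kG0 (1 - eta)^2 / 4, i.e. kG0 where eta = -1 and exactly 0 on
the patch where eta = +1.

Constraint functionals: area A[phi], enclosed volume V[phi], patch area
P[phi, eta]; soft functionals: the auxiliary bending energy E_A[eta]
(prefactor 10^-3 k) keeping eta on its tanh profile, and the orthogonality
penalty O[phi, eta] = Int |grad phi . grad eta|^2 dV.  All are assembled
into the augmented-Lagrangian modified energy by total_modified_energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import AxisymGrid
from .params import ConstraintSet, PhysParams

__all__ = [
    "EnergyReport",
    "psi_bending",
    "energy_bending",
    "psi_gaussian",
    "kg_of_eta",
    "energy_gaussian",
    "psi_auxiliary",
    "energy_auxiliary",
    "orthogonality_penalty",
    "area_functional",
    "volume_functional",
    "patch_area_functional",
    "total_modified_energy",
]

C_AREA = 3.0 / (4.0 * np.sqrt(2.0))        # prefactor of A, P and E_B (times k)
C_GAUSS = 35.0 / (16.0 * np.sqrt(2.0))     # prefactor of E_G
AUX_RIGIDITY_FACTOR = 1.0e-3               # eta rigidity relative to k


@dataclass(frozen=True)
class EnergyReport:
    """Breakdown of the modified energy of one (phi, eta) configuration."""

    E_B: float
    E_G: float
    E_A: float
    O_pen: float
    A: float
    V: float
    P: float
    E_bar: float

    @property
    def E(self) -> float:
        """Elastic (Canham-Helfrich-limiting) energy E_B + E_G."""
        return self.E_B + self.E_G


def psi_bending(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    """Bending stress density Psi_B; zero on the exact 1D tanh profile."""
    phi = g.check(phi)
    return g.laplacian_cyl(phi) - (phi**2 - 1.0) * (
        phi + np.sqrt(2.0) * p.eps * p.m
    ) / p.eps**2


def energy_bending(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> float:
    """Diffuse-interface bending energy (k_B*T); -> 8 pi k for a sphere, m=0."""
    psi = psi_bending(phi, p, g)
    return p.k * C_AREA * p.eps * g.integrate(psi**2)


def psi_gaussian(phi: np.ndarray, g: AxisymGrid) -> np.ndarray:
    """Gaussian-curvature density combination Psi_G.

    Vanishes identically for unidirectional (flat-interface) fields; for a
    tanh sphere its weighted integral approaches the Gauss-Bonnet value.
    """
    phi = g.check(phi)
    phi_r, phi_rr = g.diff(phi, 0, (1, 2))
    phi_z, phi_zz = g.diff(phi, 1, (1, 2))
    lap = phi_rr + phi_r / g.rmesh + phi_zz
    q = phi_r**2 + phi_z**2
    q_r, q_rr = g.diff(q, 0, (1, 2))
    q_z, q_zz = g.diff(q, 1, (1, 2))
    lap_q = q_rr + q_r / g.rmesh + q_zz
    lap_r, lap_z = g.gradient(lap)
    return (
        0.5 * (q_r**2 + q_z**2)
        - (q_r * phi_r + q_z * phi_z) * lap
        + q * (lap**2 + phi_r * lap_r + phi_z * lap_z - 0.5 * lap_q)
    )


def kg_of_eta(eta_value: np.ndarray | float, kG0: float) -> np.ndarray | float:
    """Locally variable Gaussian modulus k_G(eta) = kG0 (1 - eta)^2 / 4.

    Interpolates between kG0 (eta = -1) and exactly 0 (eta = +1).  The map
    is meaningful on the physical band |eta| <= 1 + delta; the dynamics
    keeps eta there by projection (see relax), since past eta = +1 the
    parabola would grow again and open an unbounded descent direction.
    """
    return kG0 * (1.0 - eta_value) ** 2 / 4.0


def kg_prime_of_eta(eta_value: np.ndarray | float, kG0: float) -> np.ndarray | float:
    """d k_G / d eta = -kG0 (1 - eta) / 2; zero at eta = +1."""
    return -kG0 * (1.0 - eta_value) / 2.0


def energy_gaussian(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> float:
    """Diffuse-interface Gaussian energy with k_G weighted by eta (k_B*T)."""
    eta = g.check(eta)
    kg = kg_of_eta(eta, p.kG0)
    return C_GAUSS * p.eps**3 * g.integrate(kg * psi_gaussian(phi, g))


def psi_auxiliary(eta: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    """Stress density of the auxiliary field (m = 0 form)."""
    eta = g.check(eta)
    return g.laplacian_cyl(eta) - (eta**2 - 1.0) * eta / p.eps**2


def energy_auxiliary(eta: np.ndarray, p: PhysParams, g: AxisymGrid) -> float:
    """Weak bending energy keeping eta on its tanh profile (k_B*T)."""
    psi = psi_auxiliary(eta, p, g)
    return AUX_RIGIDITY_FACTOR * p.k * C_AREA * p.eps * g.integrate(psi**2)


def orthogonality_penalty(phi: np.ndarray, eta: np.ndarray, g: AxisymGrid) -> float:
    """O[phi, eta] = Int |grad phi . grad eta|^2 dV (nonnegative)."""
    phi_r, phi_z = g.gradient(g.check(phi))
    eta_r, eta_z = g.gradient(g.check(eta))
    return g.integrate((phi_r * eta_r + phi_z * eta_z) ** 2)


def _area_density(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    phi_r, phi_z = g.gradient(phi)
    return (1.0 - phi**2) ** 2 / (2.0 * p.eps**2) + phi_r**2 + phi_z**2


def area_functional(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> float:
    """Total membrane area (sharp-interface limit of the phase-field area)."""
    phi = g.check(phi)
    return C_AREA * p.eps * g.integrate(_area_density(phi, p, g))


def volume_functional(phi: np.ndarray, g: AxisymGrid) -> float:
    """Enclosed volume Int (1 + phi)/2 dV."""
    phi = g.check(phi)
    return g.integrate((1.0 + phi) / 2.0)


def patch_area_functional(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> float:
    """Membrane area weighted onto the eta = +1 patch."""
    phi = g.check(phi)
    eta = g.check(eta)
    w = (eta + 1.0) ** 2 / 4.0
    return C_AREA * p.eps * g.integrate(w * _area_density(phi, p, g))


def total_modified_energy(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    g: AxisymGrid,
) -> EnergyReport:
    """Assemble the augmented-Lagrangian modified energy and its breakdown."""
    E_B = energy_bending(phi, p, g)
    E_G = energy_gaussian(phi, eta, p, g)
    E_A = energy_auxiliary(eta, p, g)
    O = orthogonality_penalty(phi, eta, g)
    A = area_functional(phi, p, g)
    V = volume_functional(phi, g)
    P = patch_area_functional(phi, eta, p, g)
    dA, dV, dP = A - c.A0, V - c.V0, P - c.P0
    E_bar = (
        E_B
        + E_G
        + c.gamma * dA
        + 0.5 * c.M1 * dA**2
        + c.delta_p * dV
        + 0.5 * c.M2 * dV**2
        + c.gamma_p * dP
        + 0.5 * c.M3 * dP**2
        + E_A
        + c.M4 * O**2
    )
    return EnergyReport(E_B=E_B, E_G=E_G, E_A=E_A, O_pen=O, A=A, V=V, P=P, E_bar=E_bar)
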