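"""Functional derivatives of the modified energy with respect to phi and eta.

Every closed-form expression here is validated (tests) against a central
finite-difference directional derivative of the corresponding functional,
which is the accuracy authority: the analytic variations are derived by
hand and the oracle makes any algebra slip detectable.

The variation of the Gaussian energy with a locally variable modulus is
evaluated in its axisymmetric closed form: with subscripts denoting r/z
partials of phi and of k_G(eta(x)),

  dE_G/dphi = 35/(8 sqrt2) eps^3 / r * [ 12 k_G phi_r (phi_rz^2 - phi_rr phi_zz)
      + phi_r phi_z^2 kG_rr + 6 phi_r (phi_r phi_rz - phi_z phi_rr) kG_z
      + phi_r^3 kG_zz - 2 phi_r^2 phi_z kG_rz
      + (4 phi_r phi_z phi_rz + phi_rr phi_z^2 - 5 phi_r^2 phi_zz) kG_r ].

The k_G partials are obtained by chain rule from spectral derivatives of
eta (kG_r = k_G'(eta) eta_r etc.), keeping everything spectrally
consistent.  The sign of the mixed kG_rz term follows from re-deriving
the variation symbolically (Euler-Lagrange of the axisymmetric
functional); the finite-difference oracle in the tests confirms it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (
    AUX_RIGIDITY_FACTOR,
    C_AREA,
    C_GAUSS,
    kg_of_eta,
    kg_prime_of_eta,
    psi_auxiliary,
    psi_bending,
    psi_gaussian,
)
from .grid import AxisymGrid
from .params import ConstraintSet, PhysParams

__all__ = [
    "d_bending_dphi",
    "d_gaussian_dphi",
    "d_gaussian_deta",
    "d_area_dphi",
    "d_volume_dphi",
    "d_patch_dphi",
    "d_patch_deta",
    "d_auxiliary_deta",
    "d_orthogonality_dphi",
    "d_orthogonality_deta",
    "d_total_dphi",
    "d_total_deta",
    "grad_total",
    "force_density",
]


def d_bending_dphi(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    """Euler-Lagrange derivative of the bending energy.

    dE_B/dphi = 2 k c_A eps [Lap Psi_B - (3 phi^2 - 1 + 2 sqrt2 eps m phi)
    Psi_B / eps^2].
    """
    phi = g.check(phi)
    psi = psi_bending(phi, p, g)
    nl = (3.0 * phi**2 - 1.0 + 2.0 * np.sqrt(2.0) * p.eps * p.m * phi) / p.eps**2
    return 2.0 * p.k * C_AREA * p.eps * (g.laplacian_cyl(psi) - nl * psi)


def _gaussian_force_phi(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    phi_r, phi_rr = g.diff(phi, 0, (1, 2))
    phi_z, phi_zz = g.diff(phi, 1, (1, 2))
    phi_rz = g.d_z(phi_r)

    eta_r, eta_rr = g.diff(eta, 0, (1, 2))
    eta_z, eta_zz = g.diff(eta, 1, (1, 2))
    eta_rz = g.d_z(eta_r)

    kg = kg_of_eta(eta, p.kG0)
    kgp = kg_prime_of_eta(eta, p.kG0)
    kgpp = p.kG0 / 2.0  # second derivative of kG0 (1-eta)^2/4
    kG_r = kgp * eta_r
    kG_z = kgp * eta_z
    kG_rr = kgpp * eta_r**2 + kgp * eta_rr
    kG_zz = kgpp * eta_z**2 + kgp * eta_zz
    kG_rz = kgpp * eta_r * eta_z + kgp * eta_rz

    bracket = (
        12.0 * kg * phi_r * (phi_rz**2 - phi_rr * phi_zz)
        + phi_r * phi_z**2 * kG_rr
        + 6.0 * phi_r * (phi_r * phi_rz - phi_z * phi_rr) * kG_z
        + phi_r**3 * kG_zz
        - 2.0 * phi_r**2 * phi_z * kG_rz
        + (4.0 * phi_r * phi_z * phi_rz + phi_rr * phi_z**2 - 5.0 * phi_r**2 * phi_zz)
        * kG_r
    )
    return (35.0 / (8.0 * np.sqrt(2.0))) * p.eps**3 / g.rmesh * bracket


def d_gaussian_dphi(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Variation of the Gaussian energy w.r.t. phi (axisymmetric form)."""
    return _gaussian_force_phi(g.check(phi), g.check(eta), p, g)


def d_gaussian_deta(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """dE_G/deta = c_G eps^3 k_G'(eta) Psi_G (pointwise in eta)."""
    return (
        C_GAUSS * p.eps**3 * kg_prime_of_eta(g.check(eta), p.kG0)
        * psi_gaussian(g.check(phi), g)
    )


def d_area_dphi(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    """dA/dphi = -2 c_A eps (Lap phi + phi (1 - phi^2)/eps^2)."""
    phi = g.check(phi)
    return (
        -2.0 * C_AREA * p.eps
        * (g.laplacian_cyl(phi) + phi * (1.0 - phi**2) / p.eps**2)
    )


def d_volume_dphi(g: AxisymGrid) -> np.ndarray:
    """dV/dphi = 1/2 (constant field)."""
    return 0.5 * np.ones(g.shape)


def d_patch_dphi(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Variation of the patch-area functional w.r.t. phi."""
    phi = g.check(phi)
    eta = g.check(eta)
    w = (eta + 1.0) ** 2 / 4.0
    phi_r, phi_z = g.gradient(phi)
    div = g.divergence_cyl(w * phi_r, w * phi_z)
    return C_AREA * p.eps * (-2.0 * w * phi * (1.0 - phi**2) / p.eps**2 - 2.0 * div)


def d_patch_deta(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Variation of the patch-area functional w.r.t. eta (pointwise)."""
    from .energy import _area_density

    phi = g.check(phi)
    eta = g.check(eta)
    return C_AREA * p.eps * (eta + 1.0) / 2.0 * _area_density(phi, p, g)


def d_auxiliary_deta(eta: np.ndarray, p: PhysParams, g: AxisymGrid) -> np.ndarray:
    """Euler-Lagrange derivative of the auxiliary bending energy."""
    eta = g.check(eta)
    psi = psi_auxiliary(eta, p, g)
    nl = (3.0 * eta**2 - 1.0) / p.eps**2
    return (
        2.0 * AUX_RIGIDITY_FACTOR * p.k * C_AREA * p.eps
        * (g.laplacian_cyl(psi) - nl * psi)
    )


def _orth_scalar(phi, eta, g):
    phi_r, phi_z = g.gradient(phi)
    eta_r, eta_z = g.gradient(eta)
    return phi_r * eta_r + phi_z * eta_z, (phi_r, phi_z), (eta_r, eta_z)


def d_orthogonality_dphi(
    phi: np.ndarray, eta: np.ndarray, g: AxisymGrid
) -> np.ndarray:
    """dO/dphi = -2 div( (grad phi . grad eta) grad eta )."""
    s, _, (eta_r, eta_z) = _orth_scalar(g.check(phi), g.check(eta), g)
    return -2.0 * g.divergence_cyl(s * eta_r, s * eta_z)


def d_orthogonality_deta(
    phi: np.ndarray, eta: np.ndarray, g: AxisymGrid
) -> np.ndarray:
    """dO/deta = -2 div( (grad phi . grad eta) grad phi )."""
    s, (phi_r, phi_z), _ = _orth_scalar(g.check(phi), g.check(eta), g)
    return -2.0 * g.divergence_cyl(s * phi_r, s * phi_z)


@dataclass(frozen=True)
class Functionals:
    """Constraint-functional values shared between force assembly steps."""

    A: float
    V: float
    P: float
    O: float


def _functionals(phi, eta, p, c, g) -> Functionals:
    from .energy import (
        area_functional,
        orthogonality_penalty,
        patch_area_functional,
        volume_functional,
    )

    return Functionals(
        A=area_functional(phi, p, g),
        V=volume_functional(phi, g),
        P=patch_area_functional(phi, eta, p, g),
        O=orthogonality_penalty(phi, eta, g),
    )


def d_total_dphi(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    g: AxisymGrid,
    funcs: Functionals | None = None,
) -> np.ndarray:
    """Full variation of the modified energy w.r.t. phi.

    Constraint terms use the exact augmented-Lagrangian gradient, e.g.
    (gamma + M1 (A - A0)) dA/dphi.
    """
    if funcs is None:
        funcs = _functionals(phi, eta, p, c, g)
    out = d_bending_dphi(phi, p, g) + d_gaussian_dphi(phi, eta, p, g)
    gam = c.gamma + c.M1 * (funcs.A - c.A0)
    if gam != 0.0:
        out += gam * d_area_dphi(phi, p, g)
    dp = c.delta_p + c.M2 * (funcs.V - c.V0)
    if dp != 0.0:
        out += dp * 0.5
    gp = c.gamma_p + c.M3 * (funcs.P - c.P0)
    if gp != 0.0:
        out += gp * d_patch_dphi(phi, eta, p, g)
    if c.M4 != 0.0 and funcs.O != 0.0:
        out += 2.0 * c.M4 * funcs.O * d_orthogonality_dphi(phi, eta, g)
    return out


def d_total_deta(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    g: AxisymGrid,
    funcs: Functionals | None = None,
) -> np.ndarray:
    """Full variation of the modified energy w.r.t. eta."""
    if funcs is None:
        funcs = _functionals(phi, eta, p, c, g)
    out = d_gaussian_deta(phi, eta, p, g) + d_auxiliary_deta(eta, p, g)
    gp = c.gamma_p + c.M3 * (funcs.P - c.P0)
    if gp != 0.0:
        out += gp * d_patch_deta(phi, eta, p, g)
    if c.M4 != 0.0 and funcs.O != 0.0:
        out += 2.0 * c.M4 * funcs.O * d_orthogonality_deta(phi, eta, g)
    return out


def grad_total(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    g: AxisymGrid,
    *,
    need_eta: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, Functionals]:
    """Both variations plus the functional values, in one pass."""
    funcs = _functionals(phi, eta, p, c, g)
    gphi = d_total_dphi(phi, eta, p, c, g, funcs)
    geta = d_total_deta(phi, eta, p, c, g, funcs) if need_eta else None
    return gphi, geta, funcs


def force_density(
    phi: np.ndarray, eta: np.ndarray, p: PhysParams, g: AxisymGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Counterbalancing force field f = -(dE/dphi) grad phi.

    Uses only the elastic energy E = E_B + E_G (no constraint terms):
    the force an external agent must apply to hold the membrane in the
    given configuration against its elastic reaction.
    """
    dE = d_bending_dphi(phi, p, g) + d_gaussian_dphi(phi, eta, p, g)
    phi_r, phi_z = g.gradient(phi)
    return -dE * phi_r, -dE * phi_z
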