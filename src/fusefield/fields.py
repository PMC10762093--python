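"""Construction of phase-field and auxiliary-field configurations.

The membrane phase field phi is +1 in the aqueous interior of a vesicle and
-1 outside, crossing zero on the membrane mid-surface with the equilibrium
profile tanh(s / (sqrt(2) eps)) in the signed distance s.  The auxiliary
field eta marks the membrane patch carrying the modified Gaussian modulus
(+1 on the patch, -1 on the rest of the membrane) with the same tanh
cross-profile.
"""

from __future__ import annotations

import numpy as np

from .grid import AxisymGrid
from .params import PhysParams

__all__ = [
    "tanh_sphere",
    "tanh_interface",
    "tanh_spheroid",
    "compose_union",
    "init_patch_field",
    "signed_distance_interpolate",
]

_CLIP = 1.0 - 1.0e-12
# distance representations saturate smoothly at one membrane thickness
# (6 eps): beyond that the profile is flat and atanh would only amplify
# harmless plateau noise of relaxed fields into spurious roughness
_DIST_CAP_EPS = 6.0


def tanh_profile(signed_distance: np.ndarray, eps: float) -> np.ndarray:
    """Equilibrium interface profile tanh(s / (sqrt(2) eps))."""
    return np.tanh(signed_distance / (np.sqrt(2.0) * eps))


def tanh_sphere(
    center_z: float, radius: float, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Spherical vesicle: phi = tanh((radius - d) / (sqrt(2) eps)).

    d is the distance to the center (0, center_z) on the symmetry axis.
    The sphere must be resolvable (radius > 3 eps) and fit in the domain
    with a margin of at least 6 eps so the plateau is reached before the
    boundary.
    """
    if radius <= 3.0 * p.eps:
        raise ValueError("sphere radius must exceed 3*eps to be resolvable")
    margin = 6.0 * p.eps
    if radius + margin > g.r_max:
        raise ValueError("sphere does not fit radially with a 6*eps margin")
    if center_z - radius - margin < g.z_min or center_z + radius + margin > g.z_max:
        raise ValueError("sphere does not fit axially with a 6*eps margin")
    d = np.sqrt(g.rmesh**2 + (g.zmesh - center_z) ** 2)
    return tanh_profile(radius - d, p.eps)


def tanh_interface(z0: float, p: PhysParams, g: AxisymGrid, sign: float = 1.0) -> np.ndarray:
    """Flat interface (slab profile) phi = sign * tanh((z - z0)/(sqrt(2) eps)).

    A 1D equilibrium solution: useful as an exact zero of the bending
    stress and of the Gaussian-curvature density.
    """
    return sign * tanh_profile(g.zmesh - z0, p.eps)


def tanh_spheroid(
    center_z: float, a: float, c: float, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Prolate/oblate spheroid with equatorial semi-axis a and polar c.

    The signed distance to the spheroid surface is computed against a
    densely sampled generatrix (nearest-neighbor query), giving an
    essentially exact equilibrium tanh profile.
    """
    from scipy.spatial import cKDTree

    if min(a, c) <= 3.0 * p.eps:
        raise ValueError("spheroid semi-axes must exceed 3*eps")
    t = np.linspace(0.0, np.pi, 4096)
    curve = np.column_stack([a * np.sin(t), center_z + c * np.cos(t)])
    tree = cKDTree(curve)
    pts = np.column_stack([g.rmesh.ravel(), g.zmesh.ravel()])
    dist = tree.query(pts)[0].reshape(g.shape)
    inside = (g.rmesh / a) ** 2 + ((g.zmesh - center_z) / c) ** 2 < 1.0
    d = np.where(inside, dist, -dist)
    return tanh_profile(d, p.eps)


def compose_union(fields: list[np.ndarray]) -> np.ndarray:
    """Pointwise maximum of membrane fields (union of interiors).

    Exact away from interface overlaps; for interfaces separated by at
    least ~6 eps the union of two tanh bodies is again a tanh body.
    """
    if not fields:
        raise ValueError("need at least one field")
    shape = np.asarray(fields[0]).shape
    for f in fields[1:]:
        if np.asarray(f).shape != shape:
            raise ValueError("all fields must share one grid")
    return np.maximum.reduce([np.asarray(f) for f in fields])


def init_patch_field(
    phi: np.ndarray,
    contact_z: float,
    area_fraction: float,
    p: PhysParams,
    g: AxisymGrid,
    style: str = "ball",
) -> np.ndarray:
    """Auxiliary field marking the modified-modulus patch.

    The patch is an axisymmetric cap region around the symmetry axis near
    ``contact_z``, with a tanh cross-profile of width eps*sqrt(2); its
    extent is found by bisection so that the patch-area fraction
    P[phi, eta]/A[phi] matches ``area_fraction`` within 0.5% (relative).

    Two cap geometries are available, chosen to start close to
    orthogonality between grad(eta) and grad(phi):

    - ``"ball"``: eta = +1 inside a ball of radius s around the contact
      point.  For membranes passing near the contact point (two apposed
      vesicles) the level sets of the distance function meet the membrane
      nearly perpendicularly (misalignment ~ s / 2R), so this covers the
      facing caps of both vesicles at once.
    - ``"slab"``: eta = +1 in the band |z - contact_z| < w.  Appropriate
      when the membrane crosses the band nearly vertically, e.g. the
      equatorial belt of the fused prolate.

    phi is never modified.
    """
    from .energy import area_functional, patch_area_functional

    g.check(phi)
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must lie in [0, 1]")
    if style not in ("ball", "slab"):
        raise ValueError("style must be 'ball' or 'slab'")
    if area_fraction == 0.0:
        return -np.ones(g.shape)
    if area_fraction == 1.0:
        return np.ones(g.shape)

    A = area_functional(phi, p, g)
    if A <= 0:
        raise ValueError("phi carries no membrane area")

    if style == "ball":
        dist = np.sqrt(g.rmesh**2 + (g.zmesh - contact_z) ** 2)
    else:
        dist = np.abs(g.zmesh - contact_z)

    def eta_of(w: float) -> np.ndarray:
        return tanh_profile(w - dist, p.eps)

    def frac(w: float) -> float:
        return patch_area_functional(phi, eta_of(w), p, g) / A

    w_lo = 0.5 * p.eps
    w_hi = max(g.z_max - g.z_min, g.r_max)
    if frac(w_hi) < area_fraction:
        raise ValueError("requested patch fraction not reachable by a cap")
    for _ in range(60):
        w_mid = 0.5 * (w_lo + w_hi)
        if frac(w_mid) < area_fraction:
            w_lo = w_mid
        else:
            w_hi = w_mid
        if abs(frac(w_mid) - area_fraction) < 5.0e-3 * area_fraction:
            break
    return eta_of(0.5 * (w_lo + w_hi))


def signed_distance_interpolate(
    f_a: np.ndarray, f_b: np.ndarray, s: float, eps: float
) -> np.ndarray:
    """Interpolate two tanh-like fields through their distance representations.

    Both fields are mapped to (capped) signed distances d = sqrt(2) eps
    atanh(f), blended linearly, and mapped back through tanh.  Unlike a
    direct blend of the fields this keeps the interface width uniform at
    every intermediate s.
    """
    knee = (_DIST_CAP_EPS - 2.0) * eps  # exact below, saturating beyond

    def dist(f: np.ndarray) -> np.ndarray:
        d_raw = np.arctanh(np.clip(f, -_CLIP, _CLIP)) * np.sqrt(2.0) * eps
        a = np.abs(d_raw)
        capped = knee + 2.0 * eps * np.tanh((a - knee) / (2.0 * eps))
        return np.sign(d_raw) * np.where(a <= knee, a, capped)

    d_a, d_b = dist(f_a), dist(f_b)
    out = tanh_profile((1.0 - s) * d_a + s * d_b, eps)
    # on shared plateaus (both saturated, same phase) the distance cap is
    # lossy: blend the fields directly there instead, which is exact
    plateau = (
        (np.abs(d_a) >= knee) & (np.abs(d_b) >= knee)
        & (np.sign(d_a) == np.sign(d_b))
    )
    out = np.where(plateau, (1.0 - s) * f_a + s * f_b, out)
    return out
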