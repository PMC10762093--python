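"""Shape and geometry diagnostics of membrane configurations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as _measure

from .energy import area_functional, volume_functional
from .grid import AxisymGrid
from .params import PhysParams

__all__ = ["ShapeMetrics", "extract_contour", "shape_metrics"]


@dataclass(frozen=True)
class ShapeMetrics:
    """Geometric summary of a membrane field.

    D_ve = sqrt(A/pi) is the characteristic vesicle length, v the reduced
    volume V / (pi D_ve^3 / 6) (1 for a sphere, 1/sqrt(2) for two equal
    spheres) and lam = eps/D_ve the width-to-extension ratio controlling
    the sharp-interface limit.
    """

    A: float
    V: float
    D_ve: float
    v: float
    lam: float


def extract_contour(phi: np.ndarray, g: AxisymGrid) -> list[np.ndarray]:
    """phi = 0 level curves in the r-z half-plane.

    Marching squares with linear edge interpolation on the cell-centered
    samples.  Each polyline is an (n, 2) array of (r, z) coordinates;
    single-sign fields yield an empty list.
    """
    phi = g.check(phi)
    if phi.min() >= 0.0 or phi.max() <= 0.0:
        return []
    out = []
    for line in _measure.find_contours(phi, 0.0):
        r = g.r_centers[0] + line[:, 0] * g.dr
        z = g.z_centers[0] + line[:, 1] * g.dz
        out.append(np.column_stack([r, z]))
    return out


def shape_metrics(phi: np.ndarray, p: PhysParams, g: AxisymGrid) -> ShapeMetrics:
    """Area, volume, characteristic length, reduced volume and lambda."""
    A = area_functional(phi, p, g)
    if A <= 0.0:
        raise ValueError("field carries no membrane area")
    V = volume_functional(phi, g)
    D_ve = float(np.sqrt(A / np.pi))
    v = float(V / (np.pi * D_ve**3 / 6.0))
    return ShapeMetrics(A=A, V=V, D_ve=D_ve, v=v, lam=p.eps / D_ve)
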