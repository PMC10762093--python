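"""Shared fixtures: small grids and smooth random axisymmetric fields."""

from __future__ import annotations

import numpy as np
import pytest

from fusefield.grid import AxisymGrid, build_grid
from fusefield.params import PhysParams


@pytest.fixture(scope="session")
def phys() -> PhysParams:
    return PhysParams()


@pytest.fixture(scope="session")
def grid_coarse() -> AxisymGrid:
    """Half-eps spacing, roomy enough for a radius-14 sphere."""
    return build_grid(64, 128, 32.0, -32.0, 32.0)


@pytest.fixture(scope="session")
def grid_fine() -> AxisymGrid:
    """Quarter-eps spacing: used where spectral adjointness must be tight."""
    return build_grid(128, 256, 32.0, -32.0, 32.0)


def smooth_bump_field(g: AxisymGrid, rng: np.random.Generator, n_bumps: int = 4,
                      amplitude: float = 1.0, width_lo: float = 4.0,
                      width_hi: float = 7.0) -> np.ndarray:
    """Random smooth axisymmetric field, compactly supported in the domain.

    Built from Gaussians in (r^2, z) so the even-in-r extension is smooth at
    the axis; widths are a few eps so the field is spectrally resolved.
    """
    R, Z = g.rmesh, g.zmesh
    zmid = 0.5 * (g.z_min + g.z_max)
    zspan = 0.25 * (g.z_max - g.z_min)
    f = np.zeros(g.shape)
    for _ in range(n_bumps):
        r0 = rng.uniform(0.0, 0.45 * g.r_max)
        z0 = rng.uniform(zmid - zspan, zmid + zspan)
        w = rng.uniform(width_lo, width_hi)
        a = rng.uniform(-amplitude, amplitude)
        f += a * np.exp(
            -((R**2 - r0**2) ** 2) / (2.0 * w**2 * (r0 + w) ** 2)
            - (Z - z0) ** 2 / (2.0 * w**2)
        )
    # smooth window forcing compact support away from the outer boundaries
    f *= np.exp(-((Z - zmid) / (0.40 * (g.z_max - g.z_min))) ** 10)
    f *= np.exp(-(R / (0.80 * g.r_max)) ** 10)
    return f


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240102)
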