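"""Run configuration: validated blocks mirroring a YAML config file.

Defaults reproduce the reference fusion setup: two vesicles of diameter
146 nm (membrane thickness 5 nm, so eps = 5/6 nm and D = 175.2 eps), a
[0, 96 eps] x [-245, 245] eps domain at 144 x 735 cells, 100 string
images, k = 20 k_B*T, kG0 = -20 k_B*T, m = 0, and a modified-modulus
patch covering 2% of the membrane area.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "GridConfig",
    "PhysicsConfig",
    "GeometryConfig",
    "ConstraintConfig",
    "StringConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
]


class GridConfig(BaseModel):
    nr: int = Field(144, ge=8)
    nz: int = Field(735, ge=8)
    r_max: float = Field(96.0, gt=0)        # units of eps
    z_min: float = -245.0
    z_max: float = 245.0

    @model_validator(mode="after")
    def _extent(self):
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")
        return self


class PhysicsConfig(BaseModel):
    k: float = Field(20.0, gt=0)            # k_B*T
    kG0: float = -20.0                       # k_B*T
    m: float = 0.0                           # 1/eps
    eps_nm: float = Field(5.0 / 6.0, gt=0)   # physical size of eps
    mobility: float = Field(1.0, gt=0)


class GeometryConfig(BaseModel):
    diameter: float = Field(175.2, gt=0)     # vesicle diameter, units of eps
    gap: float = Field(3.0, ge=0)            # initial surface-to-surface gap
    neck_radius: float = Field(6.0, gt=0)    # open-neck radius of the fused state
    patch_fraction: float = Field(0.02, ge=0.0, le=1.0)


class ConstraintConfig(BaseModel):
    penalty_scale: float = Field(1.0e3, ge=0)
    M4_scale: float = Field(0.1, ge=0)


class StringConfig(BaseModel):
    n_images: int = Field(100, ge=3)
    n_outer: int = Field(2000, ge=1)
    dt: float = Field(0.005, gt=0)
    tol: float = Field(1.0e-6, gt=0)
    steps_per_cycle: int = Field(1, ge=1)
    reparam_every: int = Field(1, ge=1)
    endpoint_steps: int = Field(2000, ge=1)  # relaxation budget per endpoint


class OutputConfig(BaseModel):
    directory: str = "fusion_run"
    snapshot_every: int = Field(0, ge=0)     # 0 = endpoints + final only
    write_vtk: bool = False


class RunConfig(BaseModel):
    grid: GridConfig = GridConfig()
    physics: PhysicsConfig = PhysicsConfig()
    geometry: GeometryConfig = GeometryConfig()
    constraints: ConstraintConfig = ConstraintConfig()
    string: StringConfig = StringConfig()
    output: OutputConfig = OutputConfig()

    @model_validator(mode="after")
    def _fits(self):
        R = self.geometry.diameter / 2.0
        if R + 6.0 > self.grid.r_max:
            raise ValueError("vesicle does not fit radially (6 eps margin)")
        need = 2.0 * R + self.geometry.gap / 2.0 + 6.0
        if need > self.grid.z_max or -need < self.grid.z_min:
            raise ValueError("two-vesicle stack does not fit axially")
        return self

    @classmethod
    def coarse_demo(cls) -> "RunConfig":
        """Small-vesicle demonstration setup (minutes, not hours).

        Uses the smallest vesicle for which the asymptotic elastic
        description is expected to hold (D_ve >= 10 membrane thicknesses)
        at the reference grid spacing of (2/3) eps.
        """
        return cls(
            grid=GridConfig(nr=57, nz=162, r_max=38.0, z_min=-54.0, z_max=54.0),
            geometry=GeometryConfig(diameter=44.0, gap=3.0, neck_radius=5.0,
                                    patch_fraction=0.02),
            string=StringConfig(n_images=14, n_outer=400, endpoint_steps=600),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
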