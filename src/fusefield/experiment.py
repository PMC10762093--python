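"""End-to-end fusion experiment: endpoints, string evolution, artifacts.

The initial state is two spherical vesicles in close apposition carrying a
modified-Gaussian-modulus patch around the contact point; the final state
is the fused prolate vesicle with the same total area and enclosed volume
(reduced volume 1/sqrt(2) for equal spheres).  Both endpoints are
constructed analytically (tanh profiles) and relaxed under the constrained
gradient flow before the string is strung between them and evolved to the
minimal energy pathway.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import fields as fl
from .config import RunConfig
from .diagnostics import shape_metrics
from .energy import area_functional, patch_area_functional, volume_functional
from .fio import save_snapshot, write_extrema_json, write_mep_csv, write_vtk_rectilinear
from .grid import AxisymGrid, build_grid
from .mep import MEPResult, StringState, evolve_string, init_string, mep_profile
from .params import ConstraintSet, PhysParams, RelaxSettings
from .relax import relax_image

__all__ = [
    "prolate_semi_axes",
    "build_two_sphere_state",
    "build_prolate_state",
    "FusionSetup",
    "prepare_fusion",
    "run_fusion_experiment",
]

log = logging.getLogger("fusefield")


def _spheroid_area_volume(a: float, c: float) -> tuple[float, float]:
    V = 4.0 / 3.0 * np.pi * a**2 * c
    if abs(c - a) < 1.0e-12 * a:
        return 4.0 * np.pi * a**2, V
    if c > a:  # prolate
        e = np.sqrt(1.0 - (a / c) ** 2)
        A = 2.0 * np.pi * a**2 * (1.0 + c / (a * e) * np.arcsin(e))
    else:  # oblate
        e = np.sqrt(1.0 - (c / a) ** 2)
        A = 2.0 * np.pi * a**2 * (1.0 + (1.0 - e**2) / e * np.arctanh(e))
    return A, V


def prolate_semi_axes(A0: float, V0: float) -> tuple[float, float]:
    """Semi-axes (a, c) of the prolate spheroid with area A0, volume V0."""

    def v_of_x(x: float) -> float:
        A, V = _spheroid_area_volume(x, 1.0)
        D_ve = np.sqrt(A / np.pi)
        return V / (np.pi * D_ve**3 / 6.0)

    D_ve0 = np.sqrt(A0 / np.pi)
    v_target = V0 / (np.pi * D_ve0**3 / 6.0)
    if not 0.0 < v_target < 1.0:
        raise ValueError(f"reduced volume {v_target:.4f} not reachable by a prolate")
    x = brentq(lambda t: v_of_x(t) - v_target, 1.0e-4, 1.0 - 1.0e-9)
    A_unit, _ = _spheroid_area_volume(x, 1.0)
    scale = np.sqrt(A0 / A_unit)
    return x * scale, scale


def build_two_sphere_state(
    R: float, gap: float, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Two equal tanh spheres stacked on the axis, surface gap ``gap``."""
    zc = R + gap / 2.0
    return fl.compose_union(
        [fl.tanh_sphere(-zc, R, p, g), fl.tanh_sphere(+zc, R, p, g)]
    )


def build_prolate_state(
    A0: float, V0: float, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Tanh prolate spheroid matching the target area and volume."""
    a, c = prolate_semi_axes(A0, V0)
    return fl.tanh_spheroid(0.0, a, c, p, g)


def build_fused_state(
    R: float, neck_radius: float, p: PhysParams, g: AxisymGrid
) -> np.ndarray:
    """Merged two-sphere state: the fused vesicle with an open neck.

    The two spheres are overlapped until their intersection circle has the
    requested neck radius; the union is the tanh guess for the
    post-fusion configuration (same total area and volume as the
    two-sphere state up to the small overlap, restored by the
    constraints during relaxation).  Relaxation rounds the cusp into a
    catenoid-like neck.
    """
    if not 0.0 < neck_radius < R:
        raise ValueError("neck radius must lie in (0, R)")
    zc = float(np.sqrt(R**2 - neck_radius**2))
    return fl.compose_union(
        [fl.tanh_sphere(-zc, R, p, g), fl.tanh_sphere(+zc, R, p, g)]
    )


@dataclass
class FusionSetup:
    """Prepared fusion problem: grid, physics, endpoints and constraints."""

    grid: AxisymGrid
    phys: PhysParams
    constraints: ConstraintSet
    phi_a: np.ndarray
    eta_a: np.ndarray
    phi_b: np.ndarray
    eta_b: np.ndarray
    has_patch: bool


def prepare_fusion(cfg: RunConfig) -> FusionSetup:
    """Build and relax both endpoint states of the fusion pathway."""
    gcfg = cfg.grid
    g = build_grid(gcfg.nr, gcfg.nz, gcfg.r_max, gcfg.z_min, gcfg.z_max)
    p = PhysParams(
        k=cfg.physics.k, kG0=cfg.physics.kG0, m=cfg.physics.m,
        eps=1.0, mobility=cfg.physics.mobility,
    )
    R = cfg.geometry.diameter / 2.0
    has_patch = cfg.geometry.patch_fraction > 0.0

    phi_a = build_two_sphere_state(R, cfg.geometry.gap, p, g)
    if has_patch:
        eta_a = fl.init_patch_field(phi_a, 0.0, cfg.geometry.patch_fraction, p, g, style="ball")
    else:
        eta_a = -np.ones(g.shape)

    A0 = area_functional(phi_a, p, g)
    V0 = volume_functional(phi_a, g)
    P0 = patch_area_functional(phi_a, eta_a, p, g) if has_patch else 0.0
    c = ConstraintSet.for_targets(
        A0=A0, V0=V0, P0=P0, k=p.k,
        penalty_scale=cfg.constraints.penalty_scale,
        M4_scale=cfg.constraints.M4_scale if has_patch else 0.0,
    )
    settings = RelaxSettings(
        dt=cfg.string.dt, n_steps=cfg.string.endpoint_steps, tol=cfg.string.tol
    )
    log.info("relaxing initial (two-sphere) endpoint: A0=%.4g V0=%.4g P0=%.4g", A0, V0, P0)
    phi_a, eta_a, _, rep_a = relax_image(
        phi_a, eta_a, p, c, settings, g, evolve_eta=has_patch
    )

    phi_b = build_fused_state(R, cfg.geometry.neck_radius, p, g)
    if has_patch:
        eta_b = fl.init_patch_field(phi_b, 0.0, cfg.geometry.patch_fraction, p, g, style="ball")
    else:
        eta_b = -np.ones(g.shape)
    log.info("relaxing final (fused, open-neck) endpoint")
    phi_b, eta_b, _, rep_b = relax_image(
        phi_b, eta_b, p, c, settings, g, evolve_eta=has_patch
    )
    log.info("endpoint energies: E_a=%.4f E_b=%.4f (k_BT)", rep_a.E, rep_b.E)
    return FusionSetup(
        grid=g, phys=p, constraints=c,
        phi_a=phi_a, eta_a=eta_a, phi_b=phi_b, eta_b=eta_b,
        has_patch=has_patch,
    )


def run_fusion_experiment(
    cfg: RunConfig, outdir: str | Path | None = None
) -> tuple[StringState, MEPResult]:
    """Full pipeline: endpoints, string evolution, MEP profile, artifacts."""
    setup = prepare_fusion(cfg)
    g, p = setup.grid, setup.phys
    scfg = cfg.string
    string = init_string(
        (setup.phi_a, setup.eta_a),
        (setup.phi_b, setup.eta_b),
        scfg.n_images, p, g,
        constraints=setup.constraints,
    )
    settings = RelaxSettings(dt=scfg.dt, n_steps=1, tol=scfg.tol)

    out = Path(outdir if outdir is not None else cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    (out / "config.yaml.json").write_text(cfg_json + "\n")

    metrics_log = out / "evolution.log"
    with metrics_log.open("w") as fh:
        fh.write(f"# fusefield run, config sha256:{cfg_hash}\n")

        def callback(cycle, s, metric):
            if cycle % 10 == 0 or cycle == 1:
                fh.write(f"cycle {cycle} conv_metric {metric:.6e}\n")
                fh.flush()

        string, history = evolve_string(
            string, p, settings, scfg.n_outer,
            evolve_eta=setup.has_patch,
            steps_per_cycle=scfg.steps_per_cycle,
            reparam_every=scfg.reparam_every,
            conv_tol=scfg.tol,
            callback=callback,
        )

    result = mep_profile(string, p)
    write_mep_csv(out / "mep_profile.csv", result)
    write_extrema_json(out / "extrema.json", result)
    for tag, idx in (("first", 0), ("last", string.n_images - 1)):
        save_snapshot(
            out / f"image_{tag}.h5", g,
            {"phi": string.phi[idx], "eta": string.eta[idx]},
            meta={"alpha": float(string.alpha[idx]), "config_hash": cfg_hash},
        )
        if cfg.output.write_vtk:
            write_vtk_rectilinear(
                out / f"image_{tag}.vtk", g,
                {"phi": string.phi[idx], "eta": string.eta[idx]},
            )
    sm = shape_metrics(string.phi[0], p, g)
    summary = {
        "config_hash": cfg_hash,
        "n_images": string.n_images,
        "principal_barrier_kBT": result.principal_barrier,
        "minima_alpha": [a for _, a in result.minima],
        "saddle_alpha": [a for _, a in result.saddles],
        "reduced_volume": sm.v,
        "D_ve": sm.D_ve,
        "final_conv_metric": history[-1] if history else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info("run complete: principal barrier %.3f k_BT", result.principal_barrier)
    return string, result
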