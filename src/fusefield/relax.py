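"""Semi-implicit constrained gradient flow for a single (phi, eta) image.

The fields follow the relaxational dynamics

    d phi / dt = -M dEbar/dphi,     d eta / dt = -M dEbar/deta,

discretized with a single-step semi-implicit (IMEX) Euler scheme: the
constant-coefficient biharmonic part of each variation — the stiffest term,
responsible for the dt ~ h^4 explicit limit — is treated implicitly through
a diagonal solve in the mirror-extended Fourier basis, everything nonlinear
or variable-coefficient explicitly.  The augmented-Lagrangian multipliers
(gamma, delta_p, gamma_p) are refreshed from the current constraint
residuals each ``multiplier_update_every`` steps.

An automatic guard halves dt (down to a floor) whenever the modified energy
rises persistently, which keeps the explicit terms inside their stability
region without hand-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import AUX_RIGIDITY_FACTOR, C_AREA, EnergyReport, total_modified_energy
from .grid import AxisymGrid
from .params import ConstraintSet, PhysParams, RelaxSettings
from .variations import _functionals, d_total_deta, d_total_dphi

__all__ = ["RelaxDiverged", "RelaxTrace", "relax_image", "update_multipliers"]


class RelaxDiverged(RuntimeError):
    """Raised when the constrained flow produces non-finite fields."""


# admissible band for the order parameters; steps project back onto it.
# Keeps the modulus map k_G(eta) on the branch that interpolates kG0 -> 0
# (past eta = +1 the parabola re-steepens and the energy loses coercivity)
# while allowing the small overshoot the diffuse profiles naturally carry.
FIELD_BAND = 1.1


def _project_band(f: np.ndarray) -> np.ndarray:
    return np.clip(f, -FIELD_BAND, FIELD_BAND, out=f)


@dataclass
class RelaxTrace:
    """Per-checkpoint log of a relaxation run (for CSV export)."""

    step: list[int] = field(default_factory=list)
    E_bar: list[float] = field(default_factory=list)
    res_A: list[float] = field(default_factory=list)
    res_V: list[float] = field(default_factory=list)
    res_P: list[float] = field(default_factory=list)
    max_force: list[float] = field(default_factory=list)
    dt: list[float] = field(default_factory=list)


def update_multipliers(c: ConstraintSet, A: float, V: float, P: float) -> ConstraintSet:
    """Augmented-Lagrangian update of (gamma, delta_p, gamma_p)."""
    return c.updated(A, V, P)


def stiff_coefficients(p: PhysParams) -> tuple[float, float]:
    """Coefficients of the implicit biharmonic part for phi and eta flows."""
    lin_phi = 2.0 * p.k * C_AREA * p.eps * p.mobility
    lin_eta = AUX_RIGIDITY_FACTOR * lin_phi
    return lin_phi, lin_eta


def semi_implicit_step(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    g: AxisymGrid,
    dt: float,
    *,
    evolve_eta: bool = True,
    funcs=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One IMEX Euler step of the constrained flow (multipliers frozen)."""
    if funcs is None:
        funcs = _functionals(phi, eta, p, c, g)
    lin_phi, lin_eta = stiff_coefficients(p)
    gphi = d_total_dphi(phi, eta, p, c, g, funcs)
    rhs = phi - dt * p.mobility * gphi + dt * lin_phi * g.biharmonic_cart(phi)
    phi_new = _project_band(g.helmholtz_like_solve(rhs, dt * lin_phi))
    if evolve_eta:
        geta = d_total_deta(phi, eta, p, c, g, funcs)
        rhs_e = eta - dt * p.mobility * geta + dt * lin_eta * g.biharmonic_cart(eta)
        eta_new = _project_band(g.helmholtz_like_solve(rhs_e, dt * lin_eta))
    else:
        eta_new = eta
    return phi_new, eta_new


def relax_image(
    phi: np.ndarray,
    eta: np.ndarray,
    p: PhysParams,
    c: ConstraintSet,
    s: RelaxSettings,
    g: AxisymGrid,
    *,
    evolve_eta: bool = True,
    trace: RelaxTrace | None = None,
) -> tuple[np.ndarray, np.ndarray, ConstraintSet, EnergyReport]:
    """Relax one image to (near-)stationarity of the modified energy.

    Returns the advanced fields, the updated multiplier set and the final
    energy breakdown.  Raises RelaxDiverged on non-finite fields; persistent
    energy increase triggers dt halving instead (stability guard).
    """
    g.check(phi)
    g.check(eta)
    phi = np.array(phi, dtype=float)
    eta = np.array(eta, dtype=float)
    dt = s.dt
    dt_min = s.dt * s.dt_min_factor
    last_guard_E: float | None = None
    checkpoint = (phi.copy(), eta.copy(), c)
    checkpoint_E: float | None = None

    def _blown(a: np.ndarray) -> bool:
        return not np.all(np.isfinite(a)) or float(np.max(np.abs(a))) > 3.0

    A_ref: float | None = None

    step = 0
    while step < s.n_steps:
        step += 1
        funcs = _functionals(phi, eta, p, c, g)
        # corruption detector: membrane area exploding (grid-scale noise
        # carries huge gradient energy) or non-finite functionals
        healthy = np.isfinite(funcs.A) and (A_ref is None or funcs.A < 3.0 * A_ref)
        if not healthy:
            if dt > dt_min:
                phi, eta, c = (checkpoint[0].copy(), checkpoint[1].copy(), checkpoint[2])
                dt = max(dt / 2.0, dt_min)
                last_guard_E = None
                continue
            raise RelaxDiverged(f"area functional diverged at step {step}")
        if A_ref is None:
            A_ref = max(funcs.A, c.A0, 1.0)
        if step > 1 and (step - 1) % s.multiplier_update_every == 0:
            c = c.updated(funcs.A, funcs.V, funcs.P)
        gphi = d_total_dphi(phi, eta, p, c, g, funcs)
        max_force = float(np.max(np.abs(gphi))) * p.mobility
        if max_force < s.tol:
            break
        lin_phi, lin_eta = stiff_coefficients(p)
        rhs = phi - dt * p.mobility * gphi + dt * lin_phi * g.biharmonic_cart(phi)
        phi = _project_band(g.helmholtz_like_solve(rhs, dt * lin_phi))
        if evolve_eta:
            geta = d_total_deta(phi, eta, p, c, g, funcs)
            rhs_e = eta - dt * p.mobility * geta + dt * lin_eta * g.biharmonic_cart(eta)
            eta = _project_band(g.helmholtz_like_solve(rhs_e, dt * lin_eta))

        if _blown(phi) or _blown(eta):
            if dt > dt_min:
                # rewind to the last healthy checkpoint and retry smaller
                phi, eta, c = (checkpoint[0].copy(), checkpoint[1].copy(), checkpoint[2])
                dt = max(dt / 2.0, dt_min)
                last_guard_E = None
                continue
            raise RelaxDiverged(f"non-finite fields at relaxation step {step}")

        if step % s.guard_window == 0:
            rep = total_modified_energy(phi, eta, p, c, g)
            if trace is not None:
                trace.step.append(step)
                trace.E_bar.append(rep.E_bar)
                trace.res_A.append(abs(rep.A - c.A0))
                trace.res_V.append(abs(rep.V - c.V0))
                trace.res_P.append(abs(rep.P - c.P0))
                trace.max_force.append(max_force)
                trace.dt.append(dt)
            runaway = checkpoint_E is not None and rep.E_bar > checkpoint_E + max(
                1.0, 0.01 * abs(checkpoint_E)
            )
            if runaway and dt > dt_min:
                # severe energy rise: rewind and retry with a smaller step
                phi, eta, c = (checkpoint[0].copy(), checkpoint[1].copy(), checkpoint[2])
                dt = max(dt / 2.0, dt_min)
                last_guard_E = None
                continue
            if (
                last_guard_E is not None
                and rep.E_bar > last_guard_E + 1.0e-7 * (1.0 + abs(last_guard_E))
                and dt > dt_min
            ):
                dt = max(dt / 2.0, dt_min)
            last_guard_E = rep.E_bar
            if checkpoint_E is None or rep.E_bar <= checkpoint_E:
                checkpoint = (phi.copy(), eta.copy(), c)
                checkpoint_E = rep.E_bar

    report = total_modified_energy(phi, eta, p, c, g)
    return phi, eta, c, report
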