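"""Zero-temperature string method for minimal energy pathways.

A path between two stable vesicle states is discretized into N images
(phi_i, eta_i).  Each outer cycle advances every image by one (or a few)
semi-implicit steps of the constrained gradient flow, refreshes the
per-image augmented-Lagrangian multipliers, and reparametrizes the string
to equal arc length in the metric induced by the combined field norm
||(phi, eta)|| = sqrt(||phi||_2^2 + ||eta||_2^2).  At convergence the
string traces the MEP: everywhere tangent to the energy gradient except at
critical points, where barriers are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .energy import EnergyReport, total_modified_energy
from .fields import signed_distance_interpolate
from .grid import AxisymGrid
from .params import ConstraintSet, PhysParams, RelaxSettings
from .relax import RelaxDiverged, semi_implicit_step
from .variations import _functionals

__all__ = [
    "StringState",
    "MEPResult",
    "init_string",
    "string_distance",
    "reparametrize",
    "evolve_string",
    "mep_profile",
]


@dataclass
class StringState:
    """Ordered sequence of N (phi, eta) images with arc-length coordinates.

    Fields are stacked as arrays of shape (N, nr, nz).  The multiplier
    triple (gamma, delta_p, gamma_p) is carried per image; targets and
    penalties are shared through ``constraints``.
    """

    phi: np.ndarray
    eta: np.ndarray
    alpha: np.ndarray
    grid: AxisymGrid
    constraints: ConstraintSet
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    delta_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma_p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_images
        if self.gamma is None:
            self.gamma = np.full(n, self.constraints.gamma, dtype=float)
        if self.delta_p is None:
            self.delta_p = np.full(n, self.constraints.delta_p, dtype=float)
        if self.gamma_p is None:
            self.gamma_p = np.full(n, self.constraints.gamma_p, dtype=float)

    @property
    def n_images(self) -> int:
        return self.phi.shape[0]

    def image_constraints(self, i: int) -> ConstraintSet:
        from dataclasses import replace

        return replace(
            self.constraints,
            gamma=float(self.gamma[i]),
            delta_p=float(self.delta_p[i]),
            gamma_p=float(self.gamma_p[i]),
        )

    def copy(self) -> "StringState":
        return StringState(
            phi=self.phi.copy(),
            eta=self.eta.copy(),
            alpha=self.alpha.copy(),
            grid=self.grid,
            constraints=self.constraints,
            gamma=self.gamma.copy(),
            delta_p=self.delta_p.copy(),
            gamma_p=self.gamma_p.copy(),
        )


@dataclass(frozen=True)
class MEPResult:
    """Energy profile along a converged string with classified extrema."""

    alpha: np.ndarray
    dE: np.ndarray                    # E[phi_a] - E[phi_0], k_B*T
    minima: list[tuple[int, float]]   # (image index, alpha)
    saddles: list[tuple[int, float]]
    barriers: list[float]             # saddle minus preceding minimum
    reports: list[EnergyReport]

    @property
    def principal_barrier(self) -> float:
        return max(self.barriers) if self.barriers else 0.0


def init_string(
    endpoint_a: tuple[np.ndarray, np.ndarray],
    endpoint_b: tuple[np.ndarray, np.ndarray],
    n_images: int,
    p: PhysParams,
    g: AxisymGrid,
    constraints: ConstraintSet | None = None,
) -> StringState:
    """Initial path guess between two endpoint states.

    Intermediate images interpolate the signed-distance representations of
    the endpoint level sets linearly (then map back through tanh), so the
    interface width stays uniform along the guess.  Endpoints are copied
    bit-identically.
    """
    if n_images < 3:
        raise ValueError("a string needs at least 3 images")
    phi_a, eta_a = (g.check(f) for f in endpoint_a)
    phi_b, eta_b = (g.check(f) for f in endpoint_b)
    N = n_images
    phi = np.empty((N, *g.shape))
    eta = np.empty((N, *g.shape))
    alpha = np.linspace(0.0, 1.0, N)
    for i, s in enumerate(alpha):
        phi[i] = signed_distance_interpolate(phi_a, phi_b, s, p.eps)
        eta[i] = signed_distance_interpolate(eta_a, eta_b, s, p.eps)
    phi[0], eta[0] = phi_a.copy(), eta_a.copy()
    phi[-1], eta[-1] = phi_b.copy(), eta_b.copy()
    np.clip(phi[1:-1], -1.0, 1.0, out=phi[1:-1])
    np.clip(eta[1:-1], -1.0, 1.0, out=eta[1:-1])
    if constraints is None:
        constraints = ConstraintSet()
    return StringState(phi=phi, eta=eta, alpha=alpha, grid=g, constraints=constraints)


def string_distance(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    g: AxisymGrid,
) -> float:
    """Distance in the combined norm sqrt(||dphi||_2^2 + ||deta||_2^2)."""
    dphi = g.check(a[0]) - g.check(b[0])
    deta = g.check(a[1]) - g.check(b[1])
    return float(
        np.sqrt(g.integrate(dphi**2) + g.integrate(deta**2))
    )


def _cumulative_arclength(s: StringState) -> np.ndarray:
    N = s.n_images
    d = np.empty(N)
    d[0] = 0.0
    for i in range(1, N):
        d[i] = string_distance(
            (s.phi[i], s.eta[i]), (s.phi[i - 1], s.eta[i - 1]), s.grid
        )
    return np.cumsum(d)


def reparametrize(s: StringState) -> StringState:
    """Redistribute images to equal arc length (piecewise-cubic in alpha).

    Each field value is interpolated pointwise along the path as a cubic
    function of normalized arc length; endpoints are untouched.  A string
    of zero total length is returned unchanged.
    """
    if s.n_images < 3:
        raise ValueError("need at least 3 images to reparametrize")
    cum = _cumulative_arclength(s)
    total = cum[-1]
    # degenerate (images essentially coincide): redistributing would only
    # interpolate noise, so leave the string alone
    scale = s.grid.norm_l2(s.phi[0]) + s.grid.norm_l2(s.eta[0]) + 1.0
    if total <= 1.0e-3 * scale:
        return s
    x = cum / total
    # collapse coincident images (zero-length segments) for interpolation
    keep = np.concatenate(([True], np.diff(x) > 1.0e-12))
    xk = x[keep]
    targets = np.linspace(0.0, 1.0, s.n_images)
    if xk.size < 2:
        return s
    kind = "cubic" if xk.size >= 4 else "linear"
    if kind == "cubic":
        phi_new = CubicSpline(xk, s.phi[keep], axis=0)(targets)
        eta_new = CubicSpline(xk, s.eta[keep], axis=0)(targets)
        gam = CubicSpline(xk, s.gamma[keep])(targets)
        dpp = CubicSpline(xk, s.delta_p[keep])(targets)
        gpp = CubicSpline(xk, s.gamma_p[keep])(targets)
    else:
        def lin(arr):
            w = np.interp(targets, xk, np.arange(xk.size, dtype=float))
            lo = np.floor(w).astype(int)
            hi = np.minimum(lo + 1, xk.size - 1)
            t = (w - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
            return arr[keep][lo] * (1 - t) + arr[keep][hi] * t

        phi_new, eta_new = lin(s.phi), lin(s.eta)
        gam, dpp, gpp = lin(s.gamma), lin(s.delta_p), lin(s.gamma_p)
    phi_new[0], eta_new[0] = s.phi[0], s.eta[0]
    phi_new[-1], eta_new[-1] = s.phi[-1], s.eta[-1]
    return StringState(
        phi=phi_new,
        eta=eta_new,
        alpha=targets,
        grid=s.grid,
        constraints=s.constraints,
        gamma=np.asarray(gam, dtype=float),
        delta_p=np.asarray(dpp, dtype=float),
        gamma_p=np.asarray(gpp, dtype=float),
    )


def evolve_string(
    s: StringState,
    p: PhysParams,
    settings: RelaxSettings,
    n_outer: int,
    *,
    evolve_eta: bool = True,
    steps_per_cycle: int = 1,
    reparam_every: int = 1,
    conv_tol: float | None = None,
    callback=None,
) -> tuple[StringState, list[float]]:
    """Evolve the string by cycles of {relax images, update multipliers,
    reparametrize}.

    The convergence metric per cycle is the maximum over images of the
    field displacement in the combined norm divided by (dt * steps).
    Returns the evolved string and the metric history.  Divergence of any
    image aborts with the image index in the error message.
    """
    g = s.grid
    dt = settings.dt
    history: list[float] = []
    s = s.copy()
    for cycle in range(1, n_outer + 1):
        phi_prev = s.phi.copy()
        eta_prev = s.eta.copy()
        for i in range(s.n_images):
            ci = s.image_constraints(i)
            phi_i, eta_i = s.phi[i], s.eta[i]
            for j in range(steps_per_cycle):
                step_index = (cycle - 1) * steps_per_cycle + j
                funcs = _functionals(phi_i, eta_i, p, ci, g)
                if step_index > 0 and step_index % settings.multiplier_update_every == 0:
                    ci = ci.updated(funcs.A, funcs.V, funcs.P)
                phi_i, eta_i = semi_implicit_step(
                    phi_i, eta_i, p, ci, g, dt, evolve_eta=evolve_eta, funcs=funcs
                )
            if not (np.all(np.isfinite(phi_i)) and np.all(np.isfinite(eta_i))):
                raise RelaxDiverged(f"image {i} diverged at cycle {cycle}")
            s.phi[i], s.eta[i] = phi_i, eta_i
            s.gamma[i], s.delta_p[i], s.gamma_p[i] = ci.gamma, ci.delta_p, ci.gamma_p
        if cycle % reparam_every == 0:
            s = reparametrize(s)
        move = max(
            string_distance((s.phi[i], s.eta[i]), (phi_prev[i], eta_prev[i]), g)
            for i in range(s.n_images)
        )
        metric = move / (dt * steps_per_cycle)
        history.append(metric)
        if callback is not None:
            callback(cycle, s, metric)
        if conv_tol is not None and metric < conv_tol:
            break
    return s, history


def mep_profile(
    s: StringState,
    p: PhysParams,
    *,
    plateau_tol: float = 0.01,
) -> MEPResult:
    """Elastic energy profile along the string with classified extrema.

    dE is the elastic energy E = E_B + E_G relative to image 0.  Interior
    extrema are detected on the discrete profile with a prominence
    threshold ``plateau_tol`` (k_B*T) so that numerical ripples — e.g. a
    neutral-equilibrium stretch of nearly constant energy — are not
    classified as extrema.  Endpoints are included among the minima when
    they lie below their neighbor.
    """
    g = s.grid
    reports = [
        total_modified_energy(s.phi[i], s.eta[i], p, s.image_constraints(i), g)
        for i in range(s.n_images)
    ]
    E = np.array([r.E for r in reports])
    dE = E - E[0]
    n = dE.size

    sad_idx, _ = find_peaks(dE, prominence=plateau_tol)
    min_idx, _ = find_peaks(-dE, prominence=plateau_tol)
    minima = set(int(i) for i in min_idx)
    if dE[0] <= dE[1] + plateau_tol:
        minima.add(0)
    if dE[-1] <= dE[-2] + plateau_tol:
        minima.add(n - 1)
    minima = sorted(minima)
    saddles = sorted(int(i) for i in sad_idx)

    barriers = []
    for j in saddles:
        prev_minima = [i for i in minima if i < j]
        ref = dE[prev_minima[-1]] if prev_minima else dE[0]
        barriers.append(float(dE[j] - ref))
    if not saddles and n > 1 and dE[-1] > dE[0]:
        # monotone uphill profile: single barrier to the far end
        barriers = [float(dE[-1] - dE[0])]

    return MEPResult(
        alpha=s.alpha.copy(),
        dE=dE,
        minima=[(i, float(s.alpha[i])) for i in minima],
        saddles=[(i, float(s.alpha[i])) for i in saddles],
        barriers=barriers,
        reports=reports,
    )
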