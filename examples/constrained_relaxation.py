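"""Augmented-Lagrangian constrained relaxation of a single vesicle.

A tanh sphere is evolved under the semi-implicit constrained gradient
flow with its own area and volume as targets: the constraint residuals
fall well below 0.1% while the bending energy stays at the spherical
value, and the multipliers (tension gamma, pressure-like delta_p) settle
to small stationary values.  Then the target volume is reduced by 7% at
fixed area: the vesicle deflates off the sphere (reduced volume v < 1).
"""

import numpy as np

from fusefield import (
    ConstraintSet,
    PhysParams,
    RelaxSettings,
    build_grid,
    relax_image,
    shape_metrics,
    tanh_sphere,
)
from fusefield.energy import area_functional, volume_functional

p = PhysParams()
g = build_grid(64, 128, 32.0, -32.0, 32.0)
phi = tanh_sphere(0.0, 14.0, p, g)
eta = -np.ones(g.shape)
A0 = area_functional(phi, p, g)
V0 = volume_functional(phi, g)
print(f"targets: A0 = {A0:.1f} eps^2, V0 = {V0:.1f} eps^3")

c = ConstraintSet.for_targets(A0=A0, V0=V0, P0=0.0, k=p.k)
s = RelaxSettings(n_steps=400, tol=1e-5, multiplier_update_every=10)
phi2, _, c2, rep = relax_image(phi, eta, p, c, s, g, evolve_eta=False)
print(f"sphere hold:   |A-A0|/A0 = {abs(rep.A - A0) / A0:.2e}, "
      f"|V-V0|/V0 = {abs(rep.V - V0) / V0:.2e}")
print(f"               E_B = {rep.E_B:.2f} k_BT (8 pi k = {8 * np.pi * p.k:.2f}), "
      f"gamma = {c2.gamma:+.4f}, delta_p = {c2.delta_p:+.5f}")

c3 = ConstraintSet.for_targets(A0=A0, V0=0.93 * V0, P0=0.0, k=p.k)
s3 = RelaxSettings(n_steps=600, tol=1e-5, multiplier_update_every=10)
phi3, _, _, rep3 = relax_image(phi, eta, p, c3, s3, g, evolve_eta=False)
m = shape_metrics(phi3, p, g)
print(f"7% deflation:  v = {m.v:.3f} (< 1: the shape has left the sphere), "
      f"|V-V0'|/V0' = {abs(rep3.V - 0.93 * V0) / (0.93 * V0):.1e}")
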