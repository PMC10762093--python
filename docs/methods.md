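# Methods

## Model

`fusefield` represents a fluid lipid vesicle by a phase field
`phi(r, z)` on an axisymmetric domain: `phi = +1` in the aqueous interior,
`-1` outside, with the membrane as the diffuse transition layer of width
set by the interface parameter `eps` (bilayer thickness `l_me = 6 eps`;
for `l_me = 5 nm`, `eps = 5/6 nm`).  The elastic energy is a
Ginzburg–Landau functional

    E[phi, eta] = E_B[phi] + E_G[phi, eta]

whose two terms approach, in the limit of small width-to-vesicle-size
ratio `lam = eps / D_ve`, the Canham–Helfrich bending energy
`2k Int (M - m)^2 dS` and the Gaussian-curvature energy
`k_G Int G dS` of the sharp membrane surface (the `phi = 0` level set):

    E_B = k * 3/(4 sqrt2) * eps * Int Psi_B^2 dV,
    Psi_B = Lap phi - (phi^2 - 1)(phi + sqrt2 eps m)/eps^2,

    E_G = 35/(16 sqrt2) * eps^3 * Int k_G(eta) Psi_G dV,

with `Psi_G` a combination of first-to-third derivatives of `phi` whose
integral concentrates on the surface Gaussian curvature.  Unlike the
sharp-interface theory, the functional stays finite and smooth through
topological transitions, which is what makes fusion pathways computable.

The second order parameter `eta` (same tanh profile, `+1` on a membrane
patch, `-1` elsewhere) carries a locally variable Gaussian modulus

    k_G(eta) = kG0 (1 - eta)^2 / 4,

i.e. `kG0` on the unperturbed membrane and exactly `0` on the patch.  On
a closed surface Gauss–Bonnet quantizes `Int G dS` at `4 pi` per sphere,
so merging two vesicles with uniform `k_G = -20 k_BT` costs
`+4 pi |k_G| ~ 251 k_BT`; if the merging happens inside a `k_G ~ 0`
patch that cost is waived — the mechanism this package exists to
quantify.

Soft terms keep `eta` well-behaved: a weak profile energy `E_A`
(rigidity `10^-3 k`) holds it on the tanh profile, and a pure quadratic
penalty `M4 * O^2` with `O = Int |grad phi . grad eta|^2 dV` keeps its
level sets perpendicular to the membrane.

## Constraints

Lipid insolubility and osmotic balance fix total area `A`, enclosed
volume `V` and patch area `P` along a pathway.  The phase-field
functionals `A[phi]`, `V[phi]`, `P[phi, eta]` are enforced with an
augmented Lagrangian: multipliers `gamma` (tension), `delta_p`
(pressure-like), `gamma_p` (patch tension) plus quadratic penalties
`M1..M3`, with the multiplier update
`gamma <- gamma + M1 (A - A0)` (and analogues) applied every
`multiplier_update_every` steps.

Defaults and their rationale:

- `M1..M3 = 10^3 k / target^2` — a 100% relative residual costs
  `~10^3 k/2`; strong enough to hold residuals below 0.1% on the sphere
  benchmark, weak enough for the explicit constraint forces to be stable
  at the default time step.
- `M4 = 0.1 k`.  The orthogonality force acts on `eta` as an anisotropic
  diffusion with coefficient `~4 M4 O |grad phi|^2`; values of order `k`
  or larger put it outside the explicit stability region at the default
  `dt` and resolution (observed as an `eta` blow-up within a few
  cycles), while `0.1 k` holds `O` at the same few-tenths level with a
  ~10x stability margin.  The penalty's energy contribution (`M4 O^2`,
  a fraction of a `k_BT`) is negligible either way; only its gradient
  matters.
- Multiplier updates every 10 steps.  Per-step updates give the
  discrete integrator too much gain once residuals are small: the
  multiplier winds up and the coupled system oscillates divergently
  (observed on the fused-state benchmark after ~10^3 steps).

## Numerics

Cell-centered uniform grid in the (r, z) half-plane; fields are sampled
at `r_i = (i + 1/2) dr`, so `r = 0` is never touched and `1/r` factors
are always finite.  Spatial derivatives use even (mirror) extension in
both directions followed by Fourier differentiation on the doubled
domain — exactly the smoothness condition satisfied by axisymmetric
scalars at the axis and by plateau fields at the outer boundaries.
Quadrature is the midpoint rule with the `2 pi r` weight; the domain
measure is exact to machine precision, while integration-by-parts
identities hold to an `O(h^2)` floor set by the axis endpoint (the
practical limit of the finite-difference oracles, ~1e-5..1e-4 relative
at `h = 0.2..0.25 eps`).

Resolution: the reference spacing is `h = (2/3) eps` (the 144x735 grid
of the reference setup).  `E_B`, `A`, `V` are accurate to <0.1% there,
but the Gaussian density `Psi_G` (cubic in derivatives) aliases
strongly for `h >~ 0.8 eps` — a 72x245 half-resolution grid renders
`E_G` meaningless (verified: >100x error on a sphere), so coarse
studies here reduce the *vesicle*, never the resolution below
`(2/3) eps`.  Energy-only evaluations in the tests use `h = 1/2` or
`1/3 eps`, where all four functionals converge monotonically in `R/eps`.

Time stepping is a single-step semi-implicit (IMEX) Euler scheme for the
relaxation dynamics `d phi/dt = -M dEbar/dphi` (mobility absorbed,
`M = 1`): the constant-coefficient biharmonic part of each variation —
the term responsible for the `dt ~ h^4` explicit limit — is inverted
diagonally in the mirror-extended Fourier basis, everything nonlinear or
variable-coefficient is explicit.  The explicit third-order Gaussian
terms then set the step limit; `dt = 0.005` (in `eps^4` time units) is
stable with margin at `h = (2/3) eps`, and an automatic guard halves
`dt` and rewinds to the last healthy checkpoint whenever the modified
energy rises sharply or the area functional explodes (the signature of
grid-scale corruption, which can masquerade as *low* energy through
aliasing of `E_G`).

Both fields are projected onto the band `|f| <= 1.1` after every step
(the natural overshoot tolerance of the diffuse profiles).  This is a
projected gradient flow: the modulus map `k_G(eta)` is kept as the
exact, smooth parabola — whose continuation past `eta = +1` would
re-steepen and open an unbounded descent channel wherever `Psi_G > 0` —
and the projection simply forbids that unphysical region.  A `C^1`
saturating modulus map was tried instead and rejected: its curvature
discontinuity invalidates the `k_G` second-derivative terms of the
Gaussian variation, which the finite-difference oracle immediately
exposes.

The closed-form variation of `E_G` with variable `k_G` deserves a note:
the axisymmetric expression was re-derived symbolically
(Euler–Lagrange via sympy) and validated against central
finite-difference directional derivatives; the mixed-derivative term is
`-2 phi_r^2 phi_z k_G,rz` (sign fixed by the derivation and confirmed
by the oracle).  All `k_G` partials are evaluated by chain rule from
spectral derivatives of `eta`.

## String method

A pathway is discretized into `N` images `(phi_i, eta_i)`.  Each outer
cycle advances every image by a few IMEX steps of the constrained flow
(per-image multipliers, shared targets), then reparametrizes the string
to equal arc length in the combined norm
`||(phi, eta)|| = sqrt(||phi||_2^2 + ||eta||_2^2)` (volume-weighted
L2), interpolating each field pointwise with a cubic spline in arc
length; endpoints are never replaced by interpolants and evolve freely
into their minima.  The initial guess interpolates the *signed-distance
representations* of the endpoints (smoothly saturated at one membrane
thickness so that plateau noise of relaxed fields is not amplified
through `atanh`) — this keeps the interface width uniform along the
guess, where a direct field blend would smear it.

Profile analysis evaluates the elastic energy `E = E_B + E_G` per image
and classifies extrema of `dE(alpha)` with a 0.01 k_BT prominence
threshold so that numerical ripples and neutral stretches are not
reported as extrema; barriers are saddle minus preceding minimum.

## Endpoints of the fusion problem

The initial state is two equal tanh spheres stacked on the axis with a
surface-to-surface gap; the final state is the *fused* configuration:
the union of the two spheres overlapped until their intersection circle
has a prescribed open-neck radius, relaxed under the constraints into a
smooth open-neck (pore) shape.  The modified-modulus patch is
initialized as a ball around the contact point (its distance level sets
meet membranes passing near that point almost perpendicularly,
misalignment `~s/2R`), with the cap size bisected to the requested area
fraction; a z-slab variant exists for equatorial belts.  A prolate
spheroid constructor (exact signed distance via a sampled generatrix)
is provided for shape studies at prescribed `(A, V)`.

## What the reduced-size studies do and do not show

The full reference computation (two 146 nm vesicles, 144x735 grid,
N = 100 images) takes hours on one CPU; tests and examples run reduced
problems chosen on physical grounds, with two hard floors:

- resolution at `(2/3) eps` (see above), and
- vesicle size large enough that a 2% patch can cover the fusion neck:
  the patch cap radius scales like `R sqrt(2 * fraction)` while the neck
  and its rim occupy a fixed `~10 eps`, so below `R ~ 40 eps` the
  intermediates protrude from the patch and pay Gauss–Bonnet costs the
  mechanism is supposed to waive.  (At `R = 22 eps` this is visible as
  the disappearance of the stable open pore.)

The qualitative MEP studies therefore use `R = 44 eps` (half scale,
N = 12 images, h = (2/3) eps).  They reproduce the structure of the
pathway — an approach stretch, a small positive entry barrier
(~10 k_BT), a contact ("hemifusion-like") interior minimum at or below
the separated state, and a patch/no-patch contrast in which removing
the patch removes the intermediate entirely and replaces it with a
single monotone barrier of several hundred k_BT (the Gauss-Bonnet
quantum plus neck bending at this size) — but not the full-scale
barrier values.  Three reduced-scale artifacts are documented
deliberately: diffuse-tail adhesion makes close apposition weakly
attractive (at full scale the approach is neutral); the open-neck
(pore) final state is only metastable, because even at `R = 44` its rim
pokes outside the 2% patch cap, so the *third* minimum of the
full-scale pathway does not classify here; and endpoint convergence is
slow because long-wavelength shape modes of the first-order flow relax
at a rate `~ k q^4`.

## Known limitations

- No hydrodynamics, electrostatics or thermal fluctuations: the flow is
  purely relaxational and the string method is the zero-temperature
  variant.
- The area (tension) multiplier is ill-conditioned against the
  interface-profile mode at coarse resolution; the volume multiplier is
  the one that cleanly matches the least-squares Lagrange decomposition
  (tested at 10%).
- Quantitative barrier heights require the full-scale configuration;
  reduced-scale runs are structural/qualitative by design.
- Axisymmetry is assumed throughout; non-axisymmetric intermediates
  (e.g. off-axis stalks) are out of scope.
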