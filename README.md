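# fusefield

Diffuse-interface mechanics of fluid lipid vesicles: minimal energy
pathways (MEPs) for membrane fusion with a locally variable Gaussian
modulus.

## The problem

Fusion of two lipid vesicles changes the topology of the membrane.  In
the Canham–Helfrich picture the elastic energy of a closed membrane
surface Γ is

    E_CH = 2k ∫_Γ (M − m)² dS + k_G ∫_Γ G dS,

with bending rigidity `k ≈ 20 k_BT`, Gaussian modulus `k_G ≈ −k`,
spontaneous curvature `m` and the mean/Gaussian curvatures `M`, `G`.
By Gauss–Bonnet, `∫ G dS = 4π` per spherical vesicle, so merging two
vesicles into one costs `+4π|k_G| ≈ 250 k_BT` — far beyond thermal
reach, which is why membranes are such good barriers and why the
biology of fusion (viral entry, neurotransmission, fertilization) needs
a catalytic mechanism.

`fusefield` implements a phase-field (Ginzburg–Landau) version of this
energy that stays well defined *through* the topology change: the
membrane is the diffuse transition layer of a smooth field `φ(r, z)`
(+1 inside, −1 outside, width set by `ε = ℓ_me/6`), and a second field
`η` marks a membrane patch on which the Gaussian modulus is locally
driven to zero, `k_G(η) = k_G0 (1−η)²/4`.  If the merging region lies
inside that patch, the topological penalty is waived and the fusion
barrier collapses by an order of magnitude.  The package computes:

- the elastic functionals (bending, Gaussian, auxiliary, orthogonality)
  and their sharp-interface limits,
- analytic functional derivatives of everything, validated against
  finite-difference oracles,
- constrained relaxation (augmented-Lagrangian area / volume /
  patch-area constraints) with a semi-implicit Fourier-spectral scheme
  on an axisymmetric cell-centered grid,
- zero-temperature string-method MEPs between the separated and the
  fused vesicle states, with energy profiles, classified minima /
  saddles and barrier heights.

## Worked example

Topological quantization of the Gaussian energy — the number at the
heart of the fusion-barrier problem (`examples/gauss_bonnet_jump.py`):

    $ python examples/gauss_bonnet_jump.py
    radii (eps)   E_G(two)    E_G(one)    jump     4*pi*|kG0|
      14,  14     -502.69    -251.34    251.34     251.33
      11,  17     -502.69    -251.35    251.34     251.33
       9,  20     -502.71    -251.36    251.35     251.33

    the jump is quantized at 4 pi |kG0| whatever the radii: it counts
    topology, not shape.

Two tanh-profile vesicles carry Gaussian energy `2 × 4π k_G0 ≈ −503
k_BT`; one fused vesicle carries `≈ −251 k_BT`.  The difference —
`+251 k_BT` for `k_G0 = −20 k_BT`, independent of the radii — is the
elastic price of fusion with a uniform modulus, and exactly the price
the `k_G ≈ 0` patch removes.

Other examples: `sphere_energetics.py` (sharp-interface convergence of
all four functionals), `constrained_relaxation.py` (augmented-
Lagrangian constraint handling on a single vesicle),
`fusion_mep_demo.py` (a reduced-scale fusion pathway end to end, with
and without the patch).

A full-scale run (two 146 nm vesicles on the 144×735 reference grid,
100 images — hours on one CPU) is configured by the defaults of
`RunConfig()` and driven either from Python
(`fusefield.experiment.run_fusion_experiment`) or the thin CLI:

    fusefield run config.yaml -o outdir     # YAML mirroring RunConfig
    fusefield run --coarse-demo             # built-in small setup
    fusefield analyze outdir                # profile + extrema summary
    fusefield check                         # quick invariant suite

## Layout

    src/fusefield/
      grid.py         axisymmetric cell-centered grid, FFT-spectral operators
      fields.py       tanh spheres/spheroids, unions, patch + string initializers
      energy.py       all scalar functionals and the modified energy
      variations.py   functional derivatives and the force-density diagnostic
      relax.py        semi-implicit constrained gradient flow (IMEX + guard)
      mep.py          string method: evolution, reparametrization, profiles
      diagnostics.py  contours (marching squares), shape metrics
      fio.py          HDF5 snapshots, VTK export, CSV/JSON reports
      config.py       validated run configuration (YAML)
      experiment.py   endpoint construction and the end-to-end fusion run
      cli.py          thin command-line interface
    docs/methods.md   model, numerics, parameter choices, limitations
    examples/         narrative scripts, one per capability
    tests/            pytest suite (unit, property and acceptance tests)
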