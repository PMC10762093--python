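"""Physical parameters, constraint bookkeeping and relaxation settings.

Unit conventions
----------------
Energies are expressed in units of the thermal energy k_B*T throughout.
Lengths are expressed in units of the interface parameter ``eps`` unless a
grid with a different length unit is used; the default ``eps = 1`` makes the
grid coordinate the natural nondimensional length.  The membrane (bilayer)
thickness is tied to the interface parameter, ``l_me = 6 eps``; with the
physical thickness l_me = 5 nm this fixes eps = 5/6 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["PhysParams", "ConstraintSet", "RelaxSettings"]


@dataclass(frozen=True)
class PhysParams:
    """Elastic and model constants of the diffuse-interface membrane.

    Parameters
    ----------
    k : float
        Bending rigidity, in k_B*T.  Typical lipid bilayers: ~20 k_B*T.
    kG0 : float
        Baseline (unperturbed-membrane) Gaussian modulus, in k_B*T.
        Stability of a flat bilayer requires -2k < kG0 < 0; the common
        estimate is kG0 = -k.
    m : float
        Spontaneous mean curvature, 1/length.
    eps : float
        Interface-width parameter; the phase field crosses between its
        bulk values over a few eps.
    mobility : float
        Mobility M of the relaxational dynamics; it only rescales time,
        so the default M = 1 absorbs it into the time step.
    """

    k: float = 20.0
    kG0: float = -20.0
    m: float = 0.0
    eps: float = 1.0
    mobility: float = 1.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.k < 0:
            raise ValueError("bending rigidity k must be nonnegative")

    @property
    def ell_me(self) -> float:
        """Membrane (bilayer) thickness, always 6*eps."""
        return 6.0 * self.eps


@dataclass
class ConstraintSet:
    """Targets, augmented-Lagrangian multipliers and penalty constants.

    The modified energy adds to the elastic energy the terms
    ``gamma*(A-A0) + M1/2*(A-A0)^2`` (total area), the analogous volume and
    patch-area terms with multipliers ``delta_p`` and ``gamma_p``, and a pure
    quadratic penalty ``M4*O^2`` on the field-orthogonality functional O.
    """

    A0: float = 0.0
    V0: float = 0.0
    P0: float = 0.0
    gamma: float = 0.0
    delta_p: float = 0.0
    gamma_p: float = 0.0
    M1: float = 0.0
    M2: float = 0.0
    M3: float = 0.0
    M4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.M1, self.M2, self.M3, self.M4) < 0:
            raise ValueError("penalty constants M1..M4 must be nonnegative")

    def updated(self, A: float, V: float, P: float) -> "ConstraintSet":
        """Augmented-Lagrangian multiplier update (one step).

        gamma   <- gamma   + M1 (A - A0)
        delta_p <- delta_p + M2 (V - V0)
        gamma_p <- gamma_p + M3 (P - P0)

        Penalties and targets are unchanged.
        """
        return replace(
            self,
            gamma=self.gamma + self.M1 * (A - self.A0),
            delta_p=self.delta_p + self.M2 * (V - self.V0),
            gamma_p=self.gamma_p + self.M3 * (P - self.P0),
        )

    @classmethod
    def for_targets(
        cls,
        A0: float,
        V0: float,
        P0: float = 0.0,
        k: float = 20.0,
        *,
        penalty_scale: float = 1.0e3,
        M4_scale: float = 0.1,
    ) -> "ConstraintSet":
        """Build a constraint set with penalties scaled to the targets.

        M1..M3 are chosen so that a relative residual of 100% costs
        ``penalty_scale * k/2`` — strong enough to pull residuals below
        0.1% of the targets, weak enough not to dominate the time-step
        stability of the explicit constraint forces.
        """
        if A0 <= 0 or V0 <= 0:
            raise ValueError("fusion-run targets A0 and V0 must be positive")
        M3 = penalty_scale * k / P0**2 if P0 > 0 else 0.0
        return cls(
            A0=A0,
            V0=V0,
            P0=P0,
            M1=penalty_scale * k / A0**2,
            M2=penalty_scale * k / V0**2,
            M3=M3,
            M4=M4_scale * k,
        )


@dataclass
class RelaxSettings:
    """Settings of the semi-implicit constrained gradient flow.

    dt is in nondimensional time units (mobility absorbed, M = 1); with the
    stiff fourth-order part treated implicitly the scheme tolerates dt of
    order 0.1*eps^4 at the default penalties.
    """

    dt: float = 0.005
    n_steps: int = 500
    tol: float = 1.0e-6
    multiplier_update_every: int = 1
    guard_window: int = 25
    dt_min_factor: float = 1.0 / 64.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.multiplier_update_every < 1:
            raise ValueError("multiplier_update_every must be >= 1")
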