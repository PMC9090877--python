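"""Electric-double-layer electrostatics: Zeta potential to charge mapping.

The only experimentally accessible proxy for a nanoparticle's charge state
is its Zeta potential (Zp), the potential at the outer edge of the mobile
ion layer.  The Gouy-Chapman solution of the 1-D Poisson-Boltzmann
equation links Zp to an effective surface charge density,

    delta_eff = sqrt(8 c N eps k_B T) * sinh(e zeta / (2 k_B T)),

with the ion concentration c in mol/m^3.  The particle's total charge is
delta_eff times the sphere surface area pi d_p^2 and is treated as a point
charge at the particle centre.  All functions take and return SI units;
mV and nm belong at the config/CLI boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalConstants",
    "SolutionModel",
    "ParticleSpec",
    "CONSTANTS",
    "AGAROSE_VISCOSITY",
    "IF_VISCOSITY",
    "effective_charge_density",
    "particle_charge",
    "debye_length",
    "flat_plate_potential",
]

#: dilute (0.3%) agarose at 310 K, Pa.s — numerically water at body temperature
AGAROSE_VISCOSITY = 6.9152e-4
#: brain interstitial fluid, Pa.s
IF_VISCOSITY = 3.5e-3


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI).  Immutable."""

    k_B: float = 1.38e-23      # Boltzmann constant, J/K
    e: float = 1.60e-19        # elementary charge, C
    N_A: float = 6.02e23       # Avogadro constant, 1/mol
    eps0: float = 8.85e-12     # vacuum permittivity, C/(V m)


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class SolutionModel:
    """Electrolyte and fluid parameters of the suspending medium.

    Defaults are normal saline at body temperature with interstitial-fluid
    viscosity; pass ``mu=AGAROSE_VISCOSITY`` for the dilute-agarose medium.
    """

    ion_concentration: float = 0.154   # mol/L
    eps: float = 6.55e-10              # absolute permittivity of NS, C/(V m)
    temperature: float = 310.0         # K
    mu: float = IF_VISCOSITY           # dynamic viscosity, Pa.s

    def __post_init__(self) -> None:
        for name in ("ion_concentration", "eps", "temperature", "mu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def c_si(self) -> float:
        """Ion concentration in mol/m^3."""
        return self.ion_concentration * 1e3


@dataclass
class ParticleSpec:
    """A nanoparticle species: size, Zeta potential and derived charge.

    ``fixed_charge`` overrides the Gouy-Chapman mapping (used for the
    constant-surface-charge sweeps, e.g. q = -200 e); otherwise the charge
    is derived from ``zeta`` on demand via :func:`particle_charge`.
    """

    diameter: float                    # m
    zeta: float = 0.0                  # V (non-positive in this study)
    fixed_charge: float | None = None  # C, overrides the zeta mapping
    density: float = 1.0e3             # kg/m^3 (unused in overdamped mode)
    surface_charge: float = field(init=False, default=0.0)  # C, cached

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("particle diameter must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


def effective_charge_density(
    zeta: float,
    solution: SolutionModel = SolutionModel(),
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Gouy-Chapman effective surface charge density, C/m^2.

    Odd and strictly monotone in zeta; sign matches sign of zeta.
    """
    kBT = constants.k_B * solution.temperature
    pref = np.sqrt(8.0 * solution.c_si * constants.N_A * solution.eps * kBT)
    return float(pref * np.sinh(constants.e * zeta / (2.0 * kBT)))


def particle_charge(
    spec: ParticleSpec,
    solution: SolutionModel = SolutionModel(),
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Total particle charge, C: delta_eff times sphere area pi d_p^2.

    In fixed-charge mode the configured charge is returned regardless of
    size.  The result is cached on the spec.
    """
    if spec.fixed_charge is not None:
        q = float(spec.fixed_charge)
    else:
        q = effective_charge_density(spec.zeta, solution, constants) * (
            np.pi * spec.diameter**2
        )
    spec.surface_charge = q
    return q


def debye_length(
    solution: SolutionModel = SolutionModel(),
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Debye screening length kappa^-1 of the electrolyte, m."""
    kBT = constants.k_B * solution.temperature
    denom = 2.0 * constants.N_A * solution.c_si * constants.e**2
    return float(np.sqrt(solution.eps * kBT / denom))


def flat_plate_potential(
    sigma: float,
    solution: SolutionModel = SolutionModel(),
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Inverse Gouy-Chapman: surface potential (V) of a flat plate with the
    given charge density.  Exact inverse of :func:`effective_charge_density`.
    """
    kBT = constants.k_B * solution.temperature
    pref = np.sqrt(8.0 * solution.c_si * constants.N_A * solution.eps * kBT)
    return float(2.0 * kBT / constants.e * np.arcsinh(sigma / pref))
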