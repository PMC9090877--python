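"""Per-particle force contributions.

Four forces act on a suspended nanoparticle: stochastic Brownian forcing,
slip-corrected Stokes drag from the fluid, pairwise Coulomb repulsion from
the other charged particles, and the DLVO particle-membrane interaction
(screened electric-double-layer repulsion plus van der Waals attraction)
near axon surfaces.  Buoyancy and gravity are negligible at these sizes.

These are the reference implementations; the time integrator in
:mod:`ecsdiff.dynamics` evaluates equivalent expressions inside a compiled
kernel, pinned against these by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .electrostatics import (
    CONSTANTS,
    ParticleSpec,
    PhysicalConstants,
    SolutionModel,
    debye_length,
    particle_charge,
)
from .geometry import RVEGeometry, nearest_membrane

__all__ = [
    "FluidModel",
    "MembraneModel",
    "slip_correction",
    "brownian_force",
    "drag_force",
    "coulomb_forces",
    "membrane_potential",
    "membrane_force",
]


@dataclass(frozen=True)
class FluidModel:
    """Bulk fluid state: ambient flow (zero — the fluid is static in this
    study) and the Knudsen number controlling slip at the particle surface."""

    flow_velocity: tuple[float, float] = (0.0, 0.0)  # m/s
    knudsen: float = 0.025

    def __post_init__(self) -> None:
        if self.knudsen < 0:
            raise ValueError("Knudsen number must be non-negative")


@dataclass(frozen=True)
class MembraneModel:
    """Axon membrane interaction parameters.

    zeta_membrane : V
        Membrane surface potential (lipid bilayers are negative; -20 mV).
    hamaker : J
        Hamaker constant of the particle/water/membrane system.
    cutoff : m
        Surface separation beyond which the membrane force is zero.
    h_min : m
        Separation clamp preventing the vdW 1/h^2 singularity.
    """

    zeta_membrane: float = -20e-3
    hamaker: float = 1e-20
    cutoff: float = 10e-9
    h_min: float = 1e-9

    def __post_init__(self) -> None:
        if not self.cutoff > self.h_min > 0:
            raise ValueError("require cutoff > h_min > 0")


def slip_correction(K_n: float) -> float:
    """Cunningham slip-correction factor, >= 1.

    C_slip = 1 + 2 K_n (1.257 + 0.4 exp(-1.1 / (2 K_n))); the K_n -> 0
    limit is exactly 1 (the exponential underflows before the division
    blows up, handled explicitly).
    """
    if K_n < 0:
        raise ValueError("Knudsen number must be non-negative")
    if K_n == 0.0:
        return 1.0
    return 1.0 + 2.0 * K_n * (1.257 + 0.4 * np.exp(-1.1 / (2.0 * K_n)))


def brownian_force(
    r_p: float,
    solution: SolutionModel,
    dt: float,
    noise: np.ndarray,
    constants: PhysicalConstants = CONSTANTS,
    slip_factor: float = 1.0,
) -> np.ndarray:
    """Brownian force over one time step, N.

    Each component is Phi_i * sqrt(12 pi k_B mu T r_p / (slip_factor dt))
    with Phi a standard-normal draw.  With ``slip_factor=1`` this is the
    white-noise amplitude for the bare Stokes drag 6 pi mu r_p; passing the
    Cunningham factor keeps fluctuation-dissipation exact when the mobility
    is slip-corrected (the integrator does so).
    """
    if dt <= 0 or r_p <= 0:
        raise ValueError("dt and r_p must be positive")
    amp = np.sqrt(
        12.0 * np.pi * constants.k_B * solution.mu * solution.temperature * r_p
        / (slip_factor * dt)
    )
    return amp * np.asarray(noise, dtype=float)


def drag_force(
    r_p: float,
    solution: SolutionModel,
    fluid: FluidModel,
    v_particle: np.ndarray,
) -> np.ndarray:
    """Slip-corrected Stokes drag, N: 6 pi mu r_p (v_flow - v_p) / C_slip."""
    if r_p <= 0:
        raise ValueError("r_p must be positive")
    c = slip_correction(fluid.knudsen)
    v_rel = np.asarray(fluid.flow_velocity, dtype=float) - np.asarray(
        v_particle, dtype=float
    )
    return 6.0 * np.pi * solution.mu * r_p * v_rel / c


def coulomb_forces(
    positions: np.ndarray,
    charges: np.ndarray,
    constants: PhysicalConstants = CONSTANTS,
    mode: str = "unscreened",
    kappa: float = 0.0,
    min_separation: float = 0.0,
    eps: float | None = None,
) -> np.ndarray:
    """Pairwise Coulomb forces on every particle, N, shape (n, 2).

    Unscreened mode is the Coulomb sum
    F_i = sum_j q_i q_j (r_i - r_j) / (4 pi eps |r_i - r_j|^3); screened
    mode multiplies each pair term by exp(-kappa d)(1 + kappa d), the force
    of a Yukawa pair potential.  ``eps`` is the absolute permittivity and
    defaults to the vacuum value; the simulation layer passes the
    suspending medium's permittivity instead (Coulomb interactions in an
    electrolyte are reduced by the solvent's dielectric response).
    ``min_separation`` caps the interaction at that distance (the
    integrator passes one particle diameter, standing in for the neglected
    hard collisions).  Vectorized O(n^2).
    """
    if mode not in ("unscreened", "screened"):
        raise ValueError(f"unknown coulomb mode {mode!r}")
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    n = pos.shape[0]
    if q.shape[0] != n:
        raise ValueError("positions and charges length mismatch")
    if n < 2:
        return np.zeros((n, 2))
    diff = pos[:, None, :] - pos[None, :, :]          # r_i - r_j
    dist = np.hypot(diff[..., 0], diff[..., 1])
    coincident = (dist < 1e-18) & ~np.eye(n, dtype=bool)
    if np.any(coincident) and min_separation <= 0:
        i, j = np.argwhere(coincident)[0]
        raise ValueError(f"particles {i} and {j} are coincident")
    np.fill_diagonal(dist, np.inf)
    if min_separation > 0:
        dist = np.maximum(dist, min_separation)
    if eps is None:
        eps = constants.eps0
    qq = q[:, None] * q[None, :]
    mag = qq / (4.0 * np.pi * eps * dist**3)
    if mode == "screened":
        with np.errstate(invalid="ignore", over="ignore"):
            mag = mag * np.exp(-kappa * dist) * (1.0 + kappa * dist)
    np.fill_diagonal(mag, 0.0)  # self-interaction (0 * inf on the diagonal)
    return np.einsum("ij,ijk->ik", mag, diff)


def membrane_potential(
    h: float,
    q_p: float,
    d_p: float,
    membrane: MembraneModel,
    kappa: float,
) -> float:
    """DLVO interaction energy at surface separation h, J.

    U(h) = q_p zeta_m exp(-kappa h) - A_H d_p / (12 h), i.e. the particle's
    point charge in the membrane's screened Gouy-Chapman surface potential
    plus the sphere-plate van der Waals term.  h is clamped at h_min.
    """
    h = max(h, membrane.h_min)
    u_edl = q_p * membrane.zeta_membrane * np.exp(-kappa * h)
    u_vdw = -membrane.hamaker * d_p / (12.0 * h)
    return float(u_edl + u_vdw)


def membrane_force(
    position: np.ndarray,
    spec: ParticleSpec,
    geometry: RVEGeometry,
    membrane: MembraneModel,
    solution: SolutionModel,
    constants: PhysicalConstants = CONSTANTS,
) -> np.ndarray:
    """DLVO force from the nearest axon membrane, N, shape (2,).

    F = -dU/dh along the outward normal of the nearest disk:
    repulsive EDL term kappa q_p zeta_m exp(-kappa h) (positive for like
    signs) plus attractive vdW term -A_H d_p / (12 h^2).  Zero beyond the
    cutoff; h is clamped at h_min below.  ``h <= 0`` (penetration) is the
    collision handler's job and raises here.

    Geometry coordinates are micrometres; ``position`` is in micrometres,
    the returned force in newtons.
    """
    dist_um, _, normal = nearest_membrane(position, geometry)
    h = dist_um * 1e-6 - spec.radius  # surface-to-surface separation, m
    if h <= 0:
        raise ValueError(
            f"particle at {position} penetrates a membrane (h={h:.3g} m); "
            "collision handling must intervene"
        )
    if h >= membrane.cutoff:
        return np.zeros(2)
    h = max(h, membrane.h_min)
    q_p = particle_charge(spec, solution, constants)
    kappa = 1.0 / debye_length(solution, constants)
    f_edl = kappa * q_p * membrane.zeta_membrane * np.exp(-kappa * h)
    f_vdw = -membrane.hamaker * spec.diameter / (12.0 * h * h)
    return (f_edl + f_vdw) * normal
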