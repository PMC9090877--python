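"""Overdamped Brownian-dynamics integration of nanoparticle ensembles.

The printed equation of motion for these particles is inertial, but at
nanoparticle Reynolds numbers inertia relaxes in picoseconds, far below
any usable time step; the integrator therefore uses the overdamped
(inertia-free) form in which slip-corrected Stokes drag instantaneously
balances the other forces:

    v = v_flow + C_slip * (F_C + F_membrane) / (6 pi mu r_p)
    dr = v dt + sqrt(2 D dt) * Phi,   D = C_slip k_B T / (6 pi mu r_p)

The stochastic term is the Brownian force integrated over the step with an
amplitude consistent with the slip-corrected drag, so free diffusion
recovers the Cunningham-corrected Stokes-Einstein coefficient exactly
(fluctuation-dissipation).

Boundary conditions follow the physical picture: diffuse (cosine-law)
scattering at axon membranes with continuous segment-circle collision
detection so fast particles cannot tunnel through thin gaps, and removal
of particles that reach the domain boundary.  For strongly charged
ensembles the step is adaptively shortened so no deterministic
displacement exceeds a configured cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .electrostatics import (
    CONSTANTS,
    ParticleSpec,
    PhysicalConstants,
    SolutionModel,
    debye_length,
    particle_charge,
)
from .forces import FluidModel, MembraneModel, slip_correction
from .geometry import RVEGeometry

logger = logging.getLogger("ecsdiff")

__all__ = [
    "SimulationConfig",
    "ParticleEnsemble",
    "TrajectoryRecord",
    "release_particles",
    "step",
    "handle_membrane_collision",
    "handle_domain_exit",
    "run_simulation",
    "save_trajectory",
    "load_trajectory",
]

_MAX_REFLECTIONS = 8


@dataclass(frozen=True)
class SimulationConfig:
    """Integration parameters.

    dt : s
        Base time step.  The effective step is shortened adaptively whenever
        the fastest deterministic displacement would exceed ``dx_max``.
    n_steps, n_particles, record_stride : int
        Step count, ensemble size (900 reproduces the published release),
        and the number of steps between trajectory records.
    release_size : m
        Side of the central square release region (0.2 um default).
    dx_max : m
        Deterministic per-step displacement cap (adaptive dt); <= 0 disables.
    coulomb_mode : "unscreened" | "screened" | "vacuum" | "off"
        Particle-particle interaction model.  "unscreened" (default) is the
        direct Coulomb sum at the suspending medium's permittivity;
        "vacuum" is the same sum at eps0 (the printed-equation reading,
        kept for sensitivity studies); "screened" adds Yukawa screening at
        the Debye length.
    medium : "WM" | "pure-IF" | "agarose"
        Label only; the geometry argument (or None) selects hindrance.
    brownian : bool
        Disable to integrate the deterministic forces alone.
    early_stop_alive_frac : fraction
        Stop early once the alive fraction drops below this (0 disables).
    """

    dt: float = 1e-7
    n_steps: int = 20_000
    n_particles: int = 900
    release_size: float = 0.2e-6
    seed: int = 0
    record_stride: int = 20
    medium: str = "WM"
    dx_max: float = 10e-9
    coulomb_mode: str = "unscreened"
    brownian: bool = True
    membrane_forces: bool = True
    early_stop_alive_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.coulomb_mode not in ("unscreened", "screened", "vacuum", "off"):
            raise ValueError(f"unknown coulomb_mode {self.coulomb_mode!r}")


@dataclass
class ParticleEnsemble:
    """State of the traced ensemble (SI units)."""

    positions: np.ndarray            # (n, 2) m
    velocities: np.ndarray           # (n, 2) m/s
    radius: float                    # m, shared
    charge: float                    # C, shared
    alive: np.ndarray                # (n,) bool
    exit_times: np.ndarray           # (n,) s, NaN while alive
    release_positions: np.ndarray    # (n, 2) m
    time: float = 0.0
    rng_counter: int = 0

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectoryRecord:
    """Recorded trajectory: positions at record-stride intervals."""

    times: np.ndarray                # (m,) s
    positions: np.ndarray            # (m, n, 2) m
    alive: np.ndarray                # (m, n) bool
    release_positions: np.ndarray    # (n, 2) m
    exit_times: np.ndarray           # (n,) s
    meta: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def n_alive(self) -> np.ndarray:
        return self.alive.sum(axis=1)


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scatter_direction(nx: float, ny: float, u: float):
    """Cosine-weighted (Lambertian) outgoing direction about the normal.

    In 2-D the diffuse law has density 0.5 cos(theta) on [-pi/2, pi/2];
    theta = arcsin(2u - 1) with u uniform inverts its CDF.
    """
    theta = np.arcsin(2.0 * u - 1.0)
    c, s = np.cos(theta), np.sin(theta)
    return nx * c - ny * s, ny * c + nx * s


@njit(cache=True)
def _segment_circle_hit(px, py, dx, dy, cx, cy, R):
    """Earliest t in (0, 1] where p + t d crosses |. - c| = R, else -1."""
    fx = px - cx
    fy = py - cy
    a = dx * dx + dy * dy
    if a == 0.0:
        return -1.0
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - R * R
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return -1.0
    sq = np.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    if 1e-14 < t1 <= 1.0:
        return t1
    t2 = (-b + sq) / (2.0 * a)
    if c < 0.0:
        # started inside (numerical drift); treat as immediate contact
        return 0.0
    if 1e-14 < t2 <= 1.0:
        return t2
    return -1.0


@njit(cache=True)
def _advance_with_collisions(
    px, py, dx, dy,
    centers, radii_eff,
    cell_start, cell_items, ncell, cell_size,
):
    """Move a particle by (dx, dy) with diffuse scattering at axon surfaces.

    Continuous collision detection: the segment is tested against every disk
    registered in the grid cells its bounding box overlaps; on contact the
    particle is placed at the contact point and re-emitted in a
    cosine-weighted direction about the outward normal, with the remaining
    path length preserved.  Returns (x, y, ok); ok=False means the multi-
    reflection budget was exhausted (caller reverts the step).
    """
    for _ in range(_MAX_REFLECTIONS):
        if dx == 0.0 and dy == 0.0:
            return px, py, True
        # cells overlapped by the segment bbox
        x0 = min(px, px + dx)
        x1 = max(px, px + dx)
        y0 = min(py, py + dy)
        y1 = max(py, py + dy)
        i0 = max(0, int(x0 / cell_size))
        i1 = min(ncell - 1, int(x1 / cell_size))
        j0 = max(0, int(y0 / cell_size))
        j1 = min(ncell - 1, int(y1 / cell_size))
        best_t = 2.0
        best_k = -1
        for ci in range(i0, i1 + 1):
            for cj in range(j0, j1 + 1):
                cidx = ci * ncell + cj
                for m in range(cell_start[cidx], cell_start[cidx + 1]):
                    k = cell_items[m]
                    t = _segment_circle_hit(
                        px, py, dx, dy, centers[k, 0], centers[k, 1],
                        radii_eff[k],
                    )
                    if 0.0 <= t < best_t:
                        best_t = t
                        best_k = k
        if best_k < 0:
            return px + dx, py + dy, True
        # contact point, nudged just off the surface along the normal
        hx = px + best_t * dx
        hy = py + best_t * dy
        cx = centers[best_k, 0]
        cy = centers[best_k, 1]
        nx = hx - cx
        ny = hy - cy
        nrm = np.sqrt(nx * nx + ny * ny)
        if nrm < 1e-30:
            return px, py, False
        nx /= nrm
        ny /= nrm
        R = radii_eff[best_k]
        hx = cx + nx * (R + 1e-13)
        hy = cy + ny * (R + 1e-13)
        remaining = np.sqrt(dx * dx + dy * dy) * (1.0 - best_t)
        ox, oy = _scatter_direction(nx, ny, np.random.random())
        px, py = hx, hy
        dx = ox * remaining
        dy = oy * remaining
    return px, py, False


@njit(cache=True)
def _nearest_surface(px, py, centers, radii_eff,
                     cell_start, cell_items, ncell, cell_size, search):
    """Signed distance and outward normal to the nearest axon surface within
    ``search`` of the point; returns (h, nx, ny) with h=inf when none."""
    i0 = max(0, int((px - search) / cell_size))
    i1 = min(ncell - 1, int((px + search) / cell_size))
    j0 = max(0, int((py - search) / cell_size))
    j1 = min(ncell - 1, int((py + search) / cell_size))
    best_h = np.inf
    bx = 0.0
    by = 0.0
    for ci in range(i0, i1 + 1):
        for cj in range(j0, j1 + 1):
            cidx = ci * ncell + cj
            for m in range(cell_start[cidx], cell_start[cidx + 1]):
                k = cell_items[m]
                ddx = px - centers[k, 0]
                ddy = py - centers[k, 1]
                d = np.sqrt(ddx * ddx + ddy * ddy)
                h = d - radii_eff[k]
                if h < best_h and d > 1e-30:
                    best_h = h
                    bx = ddx / d
                    by = ddy / d
    return best_h, bx, by


@njit(cache=True)
def _run_kernel(
    pos, alive, exit_times, t0,
    L, gamma, D_coef,
    vfx, vfy,
    dt_base, dx_max, n_steps, stride,
    q, coulomb_mode, kappa_c, min_sep,
    centers, radii_eff,
    cell_start, cell_items, ncell, cell_size,
    membrane_on, kappa, zeta_m, hamaker, d_p, cutoff, h_min,
    eps_coulomb, brownian_on, early_frac, seed,
    rec_times, rec_pos, rec_alive,
):
    n = pos.shape[0]
    have_disks = centers.shape[0] > 0
    F = np.zeros((n, 2))
    coul_pref = q * q / (4.0 * np.pi * eps_coulomb)
    np.random.seed(seed)
    t = t0
    n_rec = 0
    # initial record
    rec_times[n_rec] = t
    for i in range(n):
        rec_pos[n_rec, i, 0] = pos[i, 0]
        rec_pos[n_rec, i, 1] = pos[i, 1]
        rec_alive[n_rec, i] = alive[i]
    n_rec += 1

    for s in range(n_steps):
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
        # pairwise Coulomb among alive particles
        if coulomb_mode > 0 and q != 0.0:
            for i in range(n):
                if not alive[i]:
                    continue
                for j in range(i + 1, n):
                    if not alive[j]:
                        continue
                    ddx = pos[i, 0] - pos[j, 0]
                    ddy = pos[i, 1] - pos[j, 1]
                    d = np.sqrt(ddx * ddx + ddy * ddy)
                    if d < min_sep:
                        d = min_sep
                    fac = coul_pref / (d * d * d)
                    if coulomb_mode == 2:
                        fac *= np.exp(-kappa_c * d) * (1.0 + kappa_c * d)
                    fx = fac * ddx
                    fy = fac * ddy
                    F[i, 0] += fx
                    F[i, 1] += fy
                    F[j, 0] -= fx
                    F[j, 1] -= fy
        # DLVO membrane force from the nearest axon surface
        if membrane_on and have_disks:
            for i in range(n):
                if not alive[i]:
                    continue
                h, nx, ny = _nearest_surface(
                    pos[i, 0], pos[i, 1], centers, radii_eff,
                    cell_start, cell_items, ncell, cell_size,
                    cutoff + cell_size,
                )
                if h < cutoff:
                    hh = h if h > h_min else h_min
                    f = (kappa * q * zeta_m * np.exp(-kappa * hh)
                         - hamaker * d_p / (12.0 * hh * hh))
                    F[i, 0] += f * nx
                    F[i, 1] += f * ny
        # adaptive step: cap the deterministic displacement
        vmax = 0.0
        for i in range(n):
            if not alive[i]:
                continue
            v = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2) / gamma
            if v > vmax:
                vmax = v
        dt = dt_base
        if dx_max > 0.0 and vmax * dt_base > dx_max:
            dt = dx_max / vmax
        sig = np.sqrt(2.0 * D_coef * dt) if brownian_on else 0.0

        n_alive = 0
        for i in range(n):
            if not alive[i]:
                continue
            dx = (vfx + F[i, 0] / gamma) * dt
            dy = (vfy + F[i, 1] / gamma) * dt
            if sig > 0.0:
                dx += sig * np.random.normal()
                dy += sig * np.random.normal()
            if have_disks:
                nxp, nyp, ok = _advance_with_collisions(
                    pos[i, 0], pos[i, 1], dx, dy, centers, radii_eff,
                    cell_start, cell_items, ncell, cell_size,
                )
                if ok:
                    pos[i, 0] = nxp
                    pos[i, 1] = nyp
            else:
                pos[i, 0] += dx
                pos[i, 1] += dy
            if not np.isfinite(pos[i, 0]) or not np.isfinite(pos[i, 1]):
                return n_rec, t, -(i + 1)  # non-finite state: abort marker
            if (pos[i, 0] < 0.0 or pos[i, 0] > L
                    or pos[i, 1] < 0.0 or pos[i, 1] > L):
                alive[i] = False
                exit_times[i] = t + dt
            else:
                n_alive += 1
        t += dt

        stop = (early_frac > 0.0 and n_alive < early_frac * n) or n_alive == 0
        if (s + 1) % stride == 0 or stop or s == n_steps - 1:
            rec_times[n_rec] = t
            for i in range(n):
                rec_pos[n_rec, i, 0] = pos[i, 0]
                rec_pos[n_rec, i, 1] = pos[i, 1]
                rec_alive[n_rec, i] = alive[i]
            n_rec += 1
        if stop:
            break
    return n_rec, t, 0


# ---------------------------------------------------------------------------
# geometry preparation
# ---------------------------------------------------------------------------

def _disk_grid(geometry: RVEGeometry | None, r_p: float):
    """Disk arrays in metres (radii inflated by the particle radius) plus a
    uniform-grid index registering each disk in every cell its bbox overlaps."""
    if geometry is None or geometry.n_disks == 0:
        L = 18e-6 if geometry is None else geometry.domain_size * 1e-6
        empty = np.empty((0, 2))
        return (L, empty, np.empty(0), np.zeros(2, dtype=np.int64),
                np.empty(0, dtype=np.int64), 1, L)
    L = geometry.domain_size * 1e-6
    centers = geometry.centers * 1e-6
    radii_eff = geometry.radii * 1e-6 + r_p
    rmax = float(radii_eff.max())
    ncell = max(1, int(L / max(rmax, 0.25e-6)))
    cell_size = L / ncell
    cells: list[list[int]] = [[] for _ in range(ncell * ncell)]
    for k in range(len(radii_eff)):
        x, y = centers[k]
        r = radii_eff[k] + 1e-12
        i0 = max(0, int((x - r) / cell_size))
        i1 = min(ncell - 1, int((x + r) / cell_size))
        j0 = max(0, int((y - r) / cell_size))
        j1 = min(ncell - 1, int((y + r) / cell_size))
        for ci in range(i0, i1 + 1):
            for cj in range(j0, j1 + 1):
                cells[ci * ncell + cj].append(k)
    counts = np.array([len(c) for c in cells], dtype=np.int64)
    cell_start = np.zeros(ncell * ncell + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    cell_items = np.array(
        [k for c in cells for k in c], dtype=np.int64
    ) if counts.sum() else np.empty(0, dtype=np.int64)
    return L, centers, radii_eff, cell_start, cell_items, ncell, cell_size


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def release_particles(
    config: SimulationConfig,
    geometry: RVEGeometry | None,
    spec: ParticleSpec,
    solution: SolutionModel = SolutionModel(),
    constants: PhysicalConstants = CONSTANTS,
    max_attempts: int = 200,
) -> ParticleEnsemble:
    """Place the ensemble uniformly in the fluid fraction of the central
    release square (rejection sampling against the axon disks), with zero
    initial velocity.  Deterministic under the config seed."""
    L, centers, radii_eff, *_ = _disk_grid(geometry, spec.radius)
    half = config.release_size / 2.0
    if config.release_size > L:
        raise ValueError("release region larger than the domain")
    c0 = L / 2.0
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    out = np.empty((n, 2))
    got = 0
    for _ in range(max_attempts):
        need = n - got
        cand = c0 + (rng.random((2 * need + 8, 2)) - 0.5) * 2 * half
        if centers.shape[0]:
            d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            ok = np.all(d2 >= (radii_eff[None, :] ** 2), axis=1)
            cand = cand[ok]
        take = min(need, cand.shape[0])
        out[got:got + take] = cand[:take]
        got += take
        if got == n:
            break
    else:
        raise RuntimeError(
            f"release region contains too little fluid: placed {got}/{n} "
            "particles within the attempt budget"
        )
    q = particle_charge(spec, solution, constants)
    return ParticleEnsemble(
        positions=out,
        velocities=np.zeros((n, 2)),
        radius=spec.radius,
        charge=q,
        alive=np.ones(n, dtype=bool),
        exit_times=np.full(n, np.nan),
        release_positions=out.copy(),
    )


def _kernel_args(config, spec, solution, fluid, membrane, geometry, constants):
    c_slip = slip_correction(fluid.knudsen)
    gamma = 6.0 * np.pi * solution.mu * spec.radius / c_slip
    D_coef = constants.k_B * solution.temperature / gamma
    L, centers, radii_eff, cell_start, cell_items, ncell, cell_size = _disk_grid(
        geometry, spec.radius
    )
    kappa = 1.0 / debye_length(solution, constants)
    mode = {"off": 0, "unscreened": 1, "screened": 2,
            "vacuum": 1}[config.coulomb_mode]
    eps_coulomb = (constants.eps0 if config.coulomb_mode == "vacuum"
                   else solution.eps)
    membrane_on = bool(config.membrane_forces and membrane is not None
                       and centers.shape[0] > 0)
    if membrane is None:
        membrane = MembraneModel()
    return dict(
        L=L, gamma=gamma, D_coef=D_coef,
        vfx=float(fluid.flow_velocity[0]), vfy=float(fluid.flow_velocity[1]),
        coulomb_mode=mode, kappa_c=kappa, min_sep=spec.diameter,
        centers=centers, radii_eff=radii_eff, cell_start=cell_start,
        cell_items=cell_items, ncell=ncell, cell_size=cell_size,
        membrane_on=membrane_on, kappa=kappa,
        zeta_m=membrane.zeta_membrane, hamaker=membrane.hamaker,
        d_p=spec.diameter, cutoff=membrane.cutoff, h_min=membrane.h_min,
        eps_coulomb=eps_coulomb,
    )


def _run(ensemble, config, spec, solution, fluid, membrane, geometry,
         constants, n_steps, seed):
    ka = _kernel_args(config, spec, solution, fluid, membrane, geometry,
                      constants)
    # decorrelate: the kernel's legacy MT19937 seeding yields correlated
    # streams for numerically related seeds; mix through a SeedSequence
    seed = int(np.random.SeedSequence([int(seed)]).generate_state(1)[0])
    stride = max(1, config.record_stride)
    max_rec = n_steps // stride + 3
    n = ensemble.n
    rec_times = np.empty(max_rec)
    rec_pos = np.empty((max_rec, n, 2))
    rec_alive = np.empty((max_rec, n), dtype=np.bool_)
    n_rec, t_end, status = _run_kernel(
        ensemble.positions, ensemble.alive, ensemble.exit_times,
        ensemble.time,
        ka["L"], ka["gamma"], ka["D_coef"], ka["vfx"], ka["vfy"],
        config.dt, config.dx_max, n_steps, stride,
        ensemble.charge, ka["coulomb_mode"], ka["kappa_c"], ka["min_sep"],
        ka["centers"], ka["radii_eff"], ka["cell_start"], ka["cell_items"],
        ka["ncell"], ka["cell_size"],
        ka["membrane_on"], ka["kappa"], ka["zeta_m"], ka["hamaker"],
        ka["d_p"], ka["cutoff"], ka["h_min"],
        ka["eps_coulomb"], config.brownian, config.early_stop_alive_frac,
        int(seed) % (2**31 - 1),
        rec_times, rec_pos, rec_alive,
    )
    if status < 0:
        raise FloatingPointError(
            f"non-finite state for particle {-status - 1} at t={t_end:.3e} s"
        )
    ensemble.time = t_end
    return rec_times[:n_rec], rec_pos[:n_rec], rec_alive[:n_rec]


def step(
    ensemble: ParticleEnsemble,
    geometry: RVEGeometry | None,
    config: SimulationConfig,
    spec: ParticleSpec,
    solution: SolutionModel = SolutionModel(),
    fluid: FluidModel = FluidModel(),
    membrane: MembraneModel | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> ParticleEnsemble:
    """Advance the ensemble by one time step (in place; also returned).

    Convenience wrapper over the compiled kernel for single-step use; long
    runs should go through :func:`run_simulation`.
    """
    seed = (config.seed * 1_000_003 + ensemble.rng_counter) % (2**31 - 1)
    _run(ensemble, config, spec, solution, fluid, membrane, geometry,
         constants, 1, seed)
    ensemble.rng_counter += 1
    return ensemble


def handle_membrane_collision(
    position_before: np.ndarray,
    position_after: np.ndarray,
    disk: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse scattering of one segment against one disk (SI units).

    ``disk`` is (cx, cy, R) with R already inflated by the particle radius.
    If the segment reaches the surface the particle is placed at the contact
    point and re-emitted in a cosine-weighted direction about the outward
    normal with the remaining path length preserved; otherwise the endpoint
    is returned unchanged.  Returns (new_position, outgoing_direction).
    """
    p0 = np.asarray(position_before, dtype=float)
    p1 = np.asarray(position_after, dtype=float)
    d = p1 - p0
    cx, cy, R = disk
    t = _segment_circle_hit(p0[0], p0[1], d[0], d[1], cx, cy, R)
    if t < 0.0:
        return p1, d / max(np.hypot(*d), 1e-300)
    hit = p0 + t * d
    normal = hit - np.array([cx, cy])
    normal /= np.hypot(*normal)
    contact = np.array([cx, cy]) + normal * (R + 1e-13)
    ox, oy = _scatter_direction(normal[0], normal[1], float(rng.random()))
    out = np.array([ox, oy])
    remaining = np.hypot(*d) * (1.0 - t)
    new_pos = contact + out * remaining
    if np.hypot(new_pos[0] - cx, new_pos[1] - cy) < R:
        return p0.copy(), out  # rejection fallback (concave corner contract)
    return new_pos, out


def handle_domain_exit(
    ensemble: ParticleEnsemble, config: SimulationConfig, domain_size: float
) -> ParticleEnsemble:
    """Mark particles beyond the domain box as exited (removal boundary)."""
    p = ensemble.positions
    outside = (
        (p[:, 0] < 0) | (p[:, 0] > domain_size)
        | (p[:, 1] < 0) | (p[:, 1] > domain_size)
    )
    newly = outside & ensemble.alive
    ensemble.alive[newly] = False
    ensemble.exit_times[newly] = ensemble.time
    return ensemble


def run_simulation(
    config: SimulationConfig,
    geometry: RVEGeometry | None,
    spec: ParticleSpec,
    solution: SolutionModel = SolutionModel(),
    fluid: FluidModel = FluidModel(),
    membrane: MembraneModel | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> TrajectoryRecord:
    """Release an ensemble and integrate it, returning the trajectory record.

    Reproducible: identical (config, geometry, spec) and seed give an
    identical record.  ``geometry=None`` is the pure-IF mode: no membranes,
    no scattering, removal at the same 18 um box.
    """
    ensemble = release_particles(config, geometry, spec, solution, constants)
    times, positions, alive = _run(
        ensemble, config, spec, solution, fluid, membrane, geometry,
        constants, config.n_steps, config.seed,
    )
    n_exited = int((~ensemble.alive).sum())
    logger.info(
        "run finished: t=%.4g s, %d/%d exited, %d records",
        ensemble.time, n_exited, ensemble.n, len(times),
    )
    c_slip = slip_correction(fluid.knudsen)
    meta = {
        "seed": config.seed,
        "dt": config.dt,
        "n_steps": config.n_steps,
        "medium": config.medium,
        "coulomb_mode": config.coulomb_mode,
        "diameter_m": spec.diameter,
        "zeta_V": spec.zeta,
        "charge_C": ensemble.charge,
        "mu_Pa_s": solution.mu,
        "temperature_K": solution.temperature,
        "c_slip": c_slip,
        "D_free_m2_s": c_slip * constants.k_B * solution.temperature
        / (6 * np.pi * solution.mu * spec.radius),
        "geometry_hash": geometry.content_hash() if geometry is not None else "",
        "n_exited": n_exited,
    }
    return TrajectoryRecord(
        times=times,
        positions=positions,
        alive=alive,
        release_positions=ensemble.release_positions,
        exit_times=ensemble.exit_times,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def save_trajectory(record: TrajectoryRecord, path: str | Path) -> None:
    """Write a trajectory record to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=record.times)
        fh.create_dataset("positions", data=record.positions,
                          compression="gzip", compression_opts=4)
        fh.create_dataset("alive", data=record.alive)
        fh.create_dataset("release_positions", data=record.release_positions)
        fh.create_dataset("exit_times", data=record.exit_times)
        for k, v in record.meta.items():
            fh.attrs[k] = v


def load_trajectory(path: str | Path) -> TrajectoryRecord:
    import h5py

    with h5py.File(path, "r") as fh:
        return TrajectoryRecord(
            times=fh["times"][:],
            positions=fh["positions"][:],
            alive=fh["alive"][:].astype(bool),
            release_positions=fh["release_positions"][:],
            exit_times=fh["exit_times"][:],
            meta=dict(fh.attrs),
        )


def export_trajectory_csv(record: TrajectoryRecord, path: str | Path) -> None:
    """Flat CSV export (time, particle, x, y, alive) for small runs."""
    m, n, _ = record.positions.shape
    with open(path, "w") as fh:
        fh.write("time_s,particle,x_m,y_m,alive\n")
        for k in range(m):
            t = record.times[k]
            for i in range(n):
                fh.write(
                    f"{float(t)!r},{i},{float(record.positions[k, i, 0])!r},"
                    f"{float(record.positions[k, i, 1])!r},"
                    f"{int(record.alive[k, i])}\n"
                )
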