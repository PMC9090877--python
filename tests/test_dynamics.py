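"""Overdamped integration: release, stepping, scattering, exits."""

import numpy as np
import pytest
from scipy import stats

from ecsdiff import (
    AGAROSE_VISCOSITY,
    CONSTANTS,
    MembraneModel,
    ParticleEnsemble,
    ParticleSpec,
    SimulationConfig,
    SolutionModel,
    handle_domain_exit,
    handle_membrane_collision,
    load_trajectory,
    release_particles,
    run_simulation,
    save_trajectory,
    slip_correction,
    step,
)
from ecsdiff.msd import analyze_trajectory


class TestRelease:
    def test_pure_if_release_centered_in_square(self, solution_if):
        cfg = SimulationConfig(n_particles=900, seed=3)
        ens = release_particles(cfg, None, ParticleSpec(40e-9), solution_if)
        assert ens.n == 900
        c = 9e-6
        assert np.all(np.abs(ens.positions - c) <= 0.1e-6 + 1e-15)
        assert np.allclose(ens.positions.mean(axis=0), c, atol=0.02e-6)
        assert np.all(ens.velocities == 0.0)

    def test_deterministic_under_seed(self, solution_if):
        cfg = SimulationConfig(n_particles=1, seed=11)
        e1 = release_particles(cfg, None, ParticleSpec(40e-9), solution_if)
        e2 = release_particles(cfg, None, ParticleSpec(40e-9), solution_if)
        assert np.array_equal(e1.positions, e2.positions)

    def test_wm_release_avoids_axons(self, wm_geom, solution_if):
        spec = ParticleSpec(98e-9)
        cfg = SimulationConfig(n_particles=300, seed=5)
        ens = release_particles(cfg, wm_geom, spec, solution_if)
        # exhaustive point-in-disk oracle, inflated by the particle radius
        pos_um = ens.positions * 1e6
        for p in pos_um:
            d = np.hypot(wm_geom.centers[:, 0] - p[0],
                         wm_geom.centers[:, 1] - p[1])
            assert np.all(d >= wm_geom.radii + 0.098 / 2 - 1e-9)


class TestStep:
    def test_no_forces_no_noise_no_motion(self, wm_geom, solution_if):
        spec = ParticleSpec(40e-9, zeta=0.0)
        cfg = SimulationConfig(n_particles=20, seed=1, brownian=False,
                               coulomb_mode="off", membrane_forces=False)
        ens = release_particles(cfg, wm_geom, spec, solution_if)
        before = ens.positions.copy()
        step(ens, wm_geom, cfg, spec, solution_if)
        assert np.array_equal(ens.positions, before)

    def test_like_charges_separate_monotonically(self, solution_if):
        spec = ParticleSpec(40e-9, zeta=-20e-3)
        cfg = SimulationConfig(n_particles=2, seed=1, brownian=False,
                               coulomb_mode="unscreened",
                               membrane_forces=False, dx_max=0.0)
        ens = release_particles(cfg, None, spec, solution_if)
        ens.positions[:] = [[9e-6, 9e-6], [9.2e-6, 9e-6]]
        gaps = [0.2e-6]
        for _ in range(5):
            step(ens, None, cfg, spec, solution_if)
            gaps.append(abs(ens.positions[1, 0] - ens.positions[0, 0]))
        assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_free_diffusion_recovers_stokes_einstein(self, solution_agarose):
        # fluctuation-dissipation: MSD slope / 4 must equal
        # D0 = C_slip kT / (6 pi mu r) within Monte-Carlo error
        spec = ParticleSpec(20e-9)
        cfg = SimulationConfig(dt=1e-6, n_steps=10_000, n_particles=300,
                               seed=9, record_stride=10, coulomb_mode="off")
        rec = run_simulation(cfg, None, spec, solution_agarose)
        _, est = analyze_trajectory(rec)
        D0 = slip_correction(0.025) * CONSTANTS.k_B * 310.0 / (
            6 * np.pi * AGAROSE_VISCOSITY * 10e-9
        )
        assert abs(est.D - D0) < max(3 * est.stderr, 0.06 * D0)


class TestMembraneCollision:
    DISK = (9e-6, 9e-6, 1e-6)  # cx, cy, effective radius (m)

    def test_no_contact_leaves_trajectory_unchanged(self, rng):
        p0 = np.array([11e-6, 9e-6])
        p1 = np.array([10.5e-6, 9e-6])  # stops 0.5 um short of the surface
        new, _ = handle_membrane_collision(p0, p1, self.DISK, rng)
        assert np.array_equal(new, p1)

    def test_head_on_reemission_is_outward(self, rng):
        p0 = np.array([10.5e-6, 9e-6])
        p1 = np.array([9.7e-6, 9e-6])  # would penetrate deeply
        for _ in range(200):
            new, out = handle_membrane_collision(p0, p1, self.DISK, rng)
            assert out[0] > 0.0  # positive component along the outward normal
            assert np.hypot(new[0] - 9e-6, new[1] - 9e-6) >= 1e-6 - 1e-18

    def test_outgoing_angles_follow_cosine_law(self):
        # chi-square test of the Lambertian density 0.5 cos(theta)
        from ecsdiff.dynamics import _scatter_direction

        rng = np.random.default_rng(42)
        u = rng.random(100_000)
        thetas = np.array([
            np.arctan2(*reversed(_scatter_direction(0.0, 1.0, ui))) for ui in u
        ])
        # normal along +y: theta measured from +x; angle from normal:
        ang = thetas - np.pi / 2
        edges = np.linspace(-np.pi / 2, np.pi / 2, 21)
        obs, _ = np.histogram(ang, edges)
        cdf = 0.5 * (np.sin(edges) + 1.0)
        exp = len(ang) * np.diff(cdf)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=len(obs) - 1)


class TestDomainExit:
    def _ensemble(self, positions):
        n = len(positions)
        return ParticleEnsemble(
            positions=np.array(positions, dtype=float),
            velocities=np.zeros((n, 2)),
            radius=20e-9, charge=0.0,
            alive=np.ones(n, dtype=bool),
            exit_times=np.full(n, np.nan),
            release_positions=np.full((n, 2), 9e-6),
            time=1.5e-3,
        )

    def test_outside_marked_with_exit_time(self):
        L = 18e-6
        ens = self._ensemble([[L + 1e-9, 5e-6], [5e-6, 5e-6]])
        handle_domain_exit(ens, SimulationConfig(), L)
        assert not ens.alive[0] and ens.alive[1]
        assert ens.exit_times[0] == pytest.approx(1.5e-3)
        assert np.isnan(ens.exit_times[1])

    def test_inside_unchanged_and_mass_balance(self):
        ens = self._ensemble([[5e-6, 5e-6], [1e-6, 17e-6]])
        handle_domain_exit(ens, SimulationConfig(), 18e-6)
        assert ens.alive.all()
        assert ens.alive.sum() + (~ens.alive).sum() == ens.n


class TestRunSimulation:
    def test_zero_steps_returns_initial_state(self, solution_if):
        spec = ParticleSpec(40e-9)
        cfg = SimulationConfig(n_steps=0, n_particles=50, seed=2)
        rec = run_simulation(cfg, None, spec, solution_if)
        assert rec.positions.shape[0] == 1
        assert np.array_equal(rec.positions[0], rec.release_positions)

    def test_same_seed_bit_identical(self, wm_geom, solution_if):
        spec = ParticleSpec(40e-9, zeta=-5e-3)
        cfg = SimulationConfig(dt=1e-7, n_steps=300, n_particles=40, seed=7,
                               record_stride=10)
        r1 = run_simulation(cfg, wm_geom, spec, solution_if,
                            membrane=MembraneModel())
        r2 = run_simulation(cfg, wm_geom, spec, solution_if,
                            membrane=MembraneModel())
        assert np.array_equal(r1.positions, r2.positions)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.alive, r2.alive)

    def test_alive_particles_never_inside_axons(self, wm_geom, solution_agarose):
        # post-step audit at every record, brute force over all disks
        spec = ParticleSpec(40e-9)
        cfg = SimulationConfig(dt=5e-7, n_steps=2000, n_particles=60, seed=3,
                               record_stride=50, coulomb_mode="off")
        rec = run_simulation(cfg, wm_geom, spec, solution_agarose,
                             membrane=MembraneModel())
        centers = wm_geom.centers * 1e-6
        radii_eff = wm_geom.radii * 1e-6 + spec.radius
        for k in range(rec.positions.shape[0]):
            for i in np.flatnonzero(rec.alive[k]):
                d = np.hypot(centers[:, 0] - rec.positions[k, i, 0],
                             centers[:, 1] - rec.positions[k, i, 1])
                assert np.all(d >= radii_eff - 1e-12)

    def test_hindrance_wm_slower_than_pure_if(self, wm_geom, solution_if):
        spec = ParticleSpec(40e-9)
        base = dict(dt=2e-6, n_steps=20_000, n_particles=150,
                    record_stride=20, coulomb_mode="off")
        rec_if = run_simulation(SimulationConfig(seed=21, medium="pure-IF",
                                                 **base),
                                None, spec, solution_if)
        rec_wm = run_simulation(SimulationConfig(seed=21, **base),
                                wm_geom, spec, solution_if,
                                membrane=MembraneModel())
        _, est_if = analyze_trajectory(rec_if)
        _, est_wm = analyze_trajectory(rec_wm)
        assert est_wm.D < est_if.D

    def test_trajectory_hdf5_round_trip(self, solution_if, tmp_path):
        spec = ParticleSpec(40e-9)
        cfg = SimulationConfig(n_steps=100, n_particles=10, seed=1,
                               record_stride=10)
        rec = run_simulation(cfg, None, spec, solution_if)
        p = tmp_path / "traj.h5"
        save_trajectory(rec, p)
        rec2 = load_trajectory(p)
        assert np.array_equal(rec.positions, rec2.positions)
        assert np.array_equal(rec.times, rec2.times)
        assert rec2.meta["seed"] == cfg.seed
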