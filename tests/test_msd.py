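"""MSD curves, stage-II detection and diffusivity estimation."""

import numpy as np
import pytest

from ecsdiff import (
    StageWindowError,
    detect_stage2,
    estimate_D,
    msd_curve,
)
from ecsdiff.dynamics import TrajectoryRecord
from ecsdiff.experiments import make_free_diffusion_record, make_staged_msd_record


def _record(times, positions, alive=None, release=None):
    m, n, _ = positions.shape
    if alive is None:
        alive = np.ones((m, n), dtype=bool)
    if release is None:
        release = positions[0].copy()
    return TrajectoryRecord(
        times=np.asarray(times, float), positions=positions, alive=alive,
        release_positions=release, exit_times=np.full(n, np.nan),
    )


class TestMSDCurve:
    def test_stationary_particles_zero_curve(self):
        pos = np.zeros((10, 5, 2)) + 9e-6
        c = msd_curve(_record(np.linspace(0, 1, 10), pos))
        assert np.all(c.msd_total == 0.0)

    def test_ballistic_motion_is_quadratic(self):
        t = np.linspace(0, 1, 50)
        v = 2e-6
        pos = np.zeros((50, 3, 2))
        pos[..., 0] = v * t[:, None]
        c = msd_curve(_record(t, pos))
        assert np.allclose(c.msd_x, (v * t) ** 2)
        assert np.allclose(c.msd_y, 0.0)

    def test_total_is_sum_of_axes(self, rng):
        pos = rng.normal(0, 1e-6, (30, 20, 2)).cumsum(axis=0)
        c = msd_curve(_record(np.linspace(0, 1, 30), pos))
        assert np.allclose(c.msd_total, c.msd_x + c.msd_y)

    def test_random_walk_slope_recovers_4D(self):
        D = 1e-10
        rec = make_free_diffusion_record(D=D, n_particles=500, n_records=400,
                                         seed=3)
        c = msd_curve(rec)
        slope = np.polyfit(c.times, c.msd_total, 1)[0]
        assert slope == pytest.approx(4 * D, rel=0.1)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            msd_curve(_record([0.0], np.zeros((1, 3, 2))))

    def test_all_exited_before_second_record(self):
        alive = np.ones((10, 4), dtype=bool)
        alive[1:] = False
        with pytest.raises(StageWindowError):
            msd_curve(_record(np.linspace(0, 1, 10), np.zeros((10, 4, 2)),
                              alive=alive))


class TestDetectStage2:
    def test_pure_linear_curve_full_window(self):
        rec = make_free_diffusion_record(D=1e-10, n_particles=4000,
                                         n_records=120, seed=5)
        c = msd_curve(rec)
        t0, t1 = detect_stage2(c)
        assert t0 <= c.times[3]
        assert t1 >= c.times[-4]

    def test_planted_changepoints_recovered(self):
        rec, t1, t2 = make_staged_msd_record(seed=8)
        c = msd_curve(rec)
        w0, w1 = detect_stage2(c)
        span = c.times[-1]
        assert w0 >= t1 - 0.05 * span  # excludes the steep stage-I transient
        assert w1 <= t2 + 0.05 * span  # excludes the depleted noisy tail

    def test_depleted_curve_raises(self):
        alive = np.ones((50, 10), dtype=bool)
        alive[3:, :] = False
        alive[3:, 0] = True  # one survivor: fraction 0.1 < 0.8
        t = np.linspace(0, 1, 50)
        pos = np.zeros((50, 10, 2))
        with pytest.raises(StageWindowError):
            detect_stage2(msd_curve(_record(t, pos, alive=alive)))


class TestEstimateD:
    def test_exact_line_recovered_exactly(self):
        t = np.linspace(0, 1, 60)
        pos = np.zeros((60, 2, 2))
        rec = _record(t, pos)
        c = msd_curve(rec)
        c.msd_x = 2e-10 * t
        c.msd_y = 2e-10 * t
        c.msd_total = c.msd_x + c.msd_y
        est = estimate_D(c, (0.0, 1.0))
        assert est.D_x == pytest.approx(1e-10, rel=1e-12)
        assert est.D == pytest.approx(1e-10, rel=1e-12)
        assert est.stderr == pytest.approx(0.0, abs=1e-16)

    def test_isotropic_fixture_axes_agree(self):
        n = 2000
        rec = make_free_diffusion_record(D=1e-10, n_particles=n,
                                         n_records=200, seed=6)
        c = msd_curve(rec)
        est = estimate_D(c, (c.times[0], c.times[-1]))
        # each axis slope fluctuates ~ sqrt(2/n) relative; the difference
        # of the two independent axes ~ sqrt(2) times that
        assert abs(est.D_x - est.D_y) < 3 * 2 * 1e-10 / np.sqrt(n)

    def test_translation_invariance(self):
        rec = make_free_diffusion_record(D=1e-10, n_particles=100,
                                         n_records=100, seed=7)
        shifted = TrajectoryRecord(
            times=rec.times, positions=rec.positions + 5e-6,
            alive=rec.alive, release_positions=rec.release_positions + 5e-6,
            exit_times=rec.exit_times,
        )
        c1 = msd_curve(rec)
        c2 = msd_curve(shifted)
        e1 = estimate_D(c1, (c1.times[0], c1.times[-1]))
        e2 = estimate_D(c2, (c2.times[0], c2.times[-1]))
        assert e1.D == pytest.approx(e2.D, rel=1e-12)

    def test_time_rescaling_equivariance(self):
        rec = make_free_diffusion_record(D=1e-10, n_particles=100,
                                         n_records=100, seed=7)
        c = msd_curve(rec)
        e1 = estimate_D(c, (c.times[0], c.times[-1]))
        c.times = c.times * 2.0
        e2 = estimate_D(c, (c.times[0], c.times[-1]))
        assert e2.D == pytest.approx(e1.D / 2.0, rel=1e-12)

    def test_survivorship_unbiased_for_random_exits(self):
        # removing particles at random (independent of displacement) must
        # not bias the free-diffusion estimate
        D = 1e-10
        rec = make_free_diffusion_record(D=D, n_particles=2000,
                                         n_records=150, seed=9)
        rng = np.random.default_rng(0)
        alive = rec.alive.copy()
        for k in range(1, 150):
            alive[k] = alive[k - 1] & (rng.random(2000) > 0.004)
        rec = TrajectoryRecord(times=rec.times, positions=rec.positions,
                               alive=alive,
                               release_positions=rec.release_positions,
                               exit_times=rec.exit_times)
        c = msd_curve(rec)
        est = estimate_D(c, detect_stage2(c, min_alive_fraction=0.4))
        assert est.D == pytest.approx(D, rel=0.1)

    def test_singular_window_rejected(self):
        t = np.linspace(0, 1, 60)
        pos = np.zeros((60, 2, 2))
        c = msd_curve(_record(t, pos))
        with pytest.raises(ValueError):
            estimate_D(c, (0.5, 0.500001))
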