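"""Force contributions: slip drag, Brownian forcing, Coulomb, membrane DLVO."""

import numpy as np
import pytest

from ecsdiff import (
    CONSTANTS,
    FluidModel,
    MembraneModel,
    ParticleSpec,
    RVEGeometry,
    SolutionModel,
    brownian_force,
    coulomb_forces,
    debye_length,
    drag_force,
    membrane_force,
    particle_charge,
    slip_correction,
)
from ecsdiff.forces import membrane_potential


class TestSlipCorrection:
    @pytest.mark.parametrize("kn, expected", [
        (0.0, 1.0),
        (0.025, 1.06285),
        (0.5, 2.39015),
    ])
    def test_values(self, kn, expected):
        assert slip_correction(kn) == pytest.approx(expected, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            slip_correction(-0.1)


class TestBrownianForce:
    def test_zero_noise_zero_force(self, solution_if):
        f = brownian_force(10e-9, solution_if, 1e-6, np.zeros(2))
        assert np.all(f == 0.0)

    def test_amplitude_hand_value(self, solution_if):
        # 10 nm radius, mu = 3.5e-3 Pa.s, T = 310 K, dt = 1e-6 s
        f = brownian_force(10e-9, solution_if, 1e-6, np.array([1.0, 0.0]))
        assert f[0] == pytest.approx(2.3759e-12, rel=1e-3)
        assert f[1] == 0.0

    def test_monte_carlo_variance(self, solution_if, rng):
        n = 100_000
        noise = rng.standard_normal((n, 2))
        f = brownian_force(10e-9, solution_if, 1e-6, noise)
        expected = 12 * np.pi * CONSTANTS.k_B * solution_if.mu \
            * solution_if.temperature * 10e-9 / 1e-6
        var = f[:, 0].var()
        se = expected * np.sqrt(2.0 / n)  # SE of a sample variance
        assert abs(var - expected) < 3 * se

    def test_slip_factor_scales_amplitude(self, solution_if):
        f1 = brownian_force(10e-9, solution_if, 1e-6, np.ones(2))
        f2 = brownian_force(10e-9, solution_if, 1e-6, np.ones(2),
                            slip_factor=1.06285)
        assert f2[0] == pytest.approx(f1[0] / np.sqrt(1.06285))


class TestDragForce:
    def test_comoving_particle_feels_nothing(self, solution_if):
        fluid = FluidModel(flow_velocity=(1e-6, -2e-6))
        f = drag_force(50e-9, solution_if, fluid, np.array([1e-6, -2e-6]))
        assert np.allclose(f, 0.0)

    def test_hand_value_50nm(self, solution_if):
        # 1 um/s particle in still fluid, Kn = 0.025
        f = drag_force(50e-9, solution_if, FluidModel(), np.array([1e-6, 0.0]))
        assert f[0] == pytest.approx(-3.1036e-15, rel=1e-3)
        assert f[1] == 0.0

    def test_linear_in_radius(self, solution_if):
        v = np.array([1e-6, 0.0])
        f1 = drag_force(25e-9, solution_if, FluidModel(), v)
        f2 = drag_force(50e-9, solution_if, FluidModel(), v)
        assert f2[0] / f1[0] == pytest.approx(2.0, rel=1e-12)


class TestCoulombForces:
    def test_two_equal_charges_coulomb_law(self):
        q = 1e-17
        pos = np.array([[0.0, 0.0], [1e-6, 0.0]])
        f = coulomb_forces(pos, [q, q])
        mag = q * q / (4 * np.pi * CONSTANTS.eps0 * 1e-12)
        assert f[0, 0] == pytest.approx(-mag, rel=1e-12)  # repulsive
        assert f[1, 0] == pytest.approx(+mag, rel=1e-12)

    def test_middle_of_symmetric_line_feels_nothing(self):
        pos = np.array([[0.0, 0.0], [1e-6, 0.0], [2e-6, 0.0]])
        f = coulomb_forces(pos, [1e-17] * 3)
        assert np.allclose(f[1], 0.0, atol=1e-25)

    def test_matches_naive_double_loop(self, rng):
        n = 7
        pos = rng.uniform(0, 1e-5, (n, 2))
        q = rng.uniform(-1e-16, 1e-16, n)
        f = coulomb_forces(pos, q)
        naive = np.zeros((n, 2))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = pos[i] - pos[j]
                r = np.hypot(*d)
                naive[i] += q[i] * q[j] * d / (4 * np.pi * CONSTANTS.eps0 * r**3)
        assert np.allclose(f, naive, rtol=1e-12, atol=0.0)

    def test_newtons_third_law_sum_zero(self, rng):
        pos = rng.uniform(0, 1e-5, (12, 2))
        q = rng.uniform(-1e-16, 1e-16, 12)
        f = coulomb_forces(pos, q)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-22)

    def test_screened_mode_yukawa_factor(self):
        pos = np.array([[0.0, 0.0], [1e-8, 0.0]])
        q = [1e-17, 1e-17]
        kappa = 1e9
        f_u = coulomb_forces(pos, q)
        f_s = coulomb_forces(pos, q, mode="screened", kappa=kappa)
        factor = np.exp(-kappa * 1e-8) * (1 + kappa * 1e-8)
        assert f_s[0, 0] == pytest.approx(f_u[0, 0] * factor, rel=1e-12)

    def test_medium_permittivity_reduces_force(self, solution_if):
        pos = np.array([[0.0, 0.0], [1e-6, 0.0]])
        q = [1e-17, 1e-17]
        f0 = coulomb_forces(pos, q)
        fm = coulomb_forces(pos, q, eps=solution_if.eps)
        assert fm[0, 0] == pytest.approx(
            f0[0, 0] * CONSTANTS.eps0 / solution_if.eps, rel=1e-12
        )

    def test_coincident_pair_raises_with_names(self):
        pos = np.array([[1e-6, 1e-6], [1e-6, 1e-6]])
        with pytest.raises(ValueError, match="0 and 1"):
            coulomb_forces(pos, [1e-17, 1e-17])

    def test_min_separation_caps_instead(self):
        pos = np.array([[1e-6, 1e-6], [1e-6, 1e-6]])
        f = coulomb_forces(pos, [1e-17, 1e-17], min_separation=1e-7)
        assert np.all(np.isfinite(f))


@pytest.fixture()
def single_disk_geometry():
    # one 1 um axon centered in the box, surface at x = 10 um
    return RVEGeometry(domain_size=18.0, centers=[[9.0, 9.0]], radii=[1.0])


class TestMembraneForce:
    def test_zero_beyond_cutoff(self, single_disk_geometry, solution_if):
        spec = ParticleSpec(40e-9, zeta=-20e-3)
        mem = MembraneModel(cutoff=10e-9)
        f = membrane_force(np.array([10.5, 9.0]), spec, single_disk_geometry,
                           mem, solution_if)
        assert np.all(f == 0.0)

    def test_vdw_magnitude_hand_value(self, single_disk_geometry, solution_if):
        # uncharged 100 nm particle, A_H = 1e-20 J, h = 10 nm:
        # |F| = A_H d / (12 h^2) ~ 8.33e-13 N, directed at the membrane
        spec = ParticleSpec(100e-9, zeta=0.0)
        mem = MembraneModel(cutoff=50e-9)
        h = 10e-9 + spec.radius
        x_um = 10.0 + h * 1e6
        f = membrane_force(np.array([x_um, 9.0]), spec, single_disk_geometry,
                           mem, solution_if)
        assert f[0] == pytest.approx(-8.333e-13, rel=1e-3)

    def test_edl_repulsive_for_like_signs(self, single_disk_geometry,
                                          solution_if):
        spec = ParticleSpec(40e-9, zeta=-20e-3)
        mem = MembraneModel(cutoff=50e-9, hamaker=0.0)
        for h_nm in (1.5, 2.0, 3.0, 5.0):
            x_um = 10.0 + (h_nm * 1e-9 + spec.radius) * 1e6
            f = membrane_force(np.array([x_um, 9.0]), spec,
                               single_disk_geometry, mem, solution_if)
            assert f[0] > 0.0  # away from the membrane

    def test_equals_negative_potential_gradient(self, solution_if):
        # central-difference oracle on the configured DLVO potential
        spec = ParticleSpec(60e-9, zeta=-20e-3)
        mem = MembraneModel(cutoff=50e-9)
        q = particle_charge(spec, solution_if)
        kappa = 1.0 / debye_length(solution_if)
        geom = RVEGeometry(domain_size=18.0, centers=[[9.0, 9.0]], radii=[1.0])
        for h in (2e-9, 3e-9, 5e-9):
            x_um = 10.0 + (h + spec.radius) * 1e6
            f = membrane_force(np.array([x_um, 9.0]), spec, geom, mem,
                               solution_if)
            dh = h * 1e-5
            dU = (membrane_potential(h + dh, q, spec.diameter, mem, kappa)
                  - membrane_potential(h - dh, q, spec.diameter, mem, kappa))
            assert f[0] == pytest.approx(-dU / (2 * dh), rel=1e-4)

    def test_penetration_raises(self, single_disk_geometry, solution_if):
        spec = ParticleSpec(40e-9, zeta=0.0)
        with pytest.raises(ValueError):
            membrane_force(np.array([9.5, 9.0]), spec, single_disk_geometry,
                           MembraneModel(), solution_if)


def test_membrane_model_validates_ranges():
    with pytest.raises(ValueError):
        MembraneModel(cutoff=1e-9, h_min=2e-9)
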