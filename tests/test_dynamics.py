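"""Force evaluation, Langevin integration, constraints and bond rupture."""

import numpy as np
import pytest

from actinmech.dynamics import (IntegrationError, SimConfig, SimState, forces,
                                potential_energy, run)
from actinmech.geometry import (HelicalGeometry, PotentialParams,
                                build_filament, equilibrium_bond_lengths)
from actinmech.protocols import constant_end_force, tether_ends
from actinmech.units import make_units

PARAMS = PotentialParams(40.0, 100.0, 20.0)


def _lattice(n=20, params=PARAMS):
    return build_filament(HelicalGeometry(n_subunits=n), params)


class TestPotentialAndForces:
    def test_undeformed_lattice_has_zero_energy_in_every_term(self):
        lat = _lattice()
        e = potential_energy(lat.positions, lat)
        for key in ("bond", "angle", "dihedral"):
            assert e[key] == pytest.approx(0.0, abs=1e-18)

    def test_single_bond_stretch_costs_half_k_delta_squared(self):
        # displace the terminal subunit along its diagonal-bond direction:
        # only bonds (n-2, n-1) and (n-3, n-1) change; compare the bond term
        # against the two-spring closed form
        lat = _lattice(params=PotentialParams(40.0, 0.0, 0.0))
        pos = lat.positions.copy()
        n = len(pos)
        u = pos[-1] - pos[-2]
        u /= np.linalg.norm(u)
        delta = 0.11
        pos[-1] += delta * u
        l_diag, l_long = equilibrium_bond_lengths(lat.geometry)
        d_long = np.linalg.norm(pos[-1] - pos[-3])
        expect = 0.5 * 40.0 * delta**2 + 0.5 * 40.0 * (d_long - l_long) ** 2
        assert potential_energy(pos, lat)["bond"] == pytest.approx(expect)

    def test_forces_are_minus_gradient_of_potential(self, rng):
        lat = _lattice()
        pos = lat.positions + rng.normal(0.0, 0.05, lat.positions.shape)
        F = forces(pos, lat)
        eps = 1e-6
        for i in (0, 7, 13, 19):
            for c in range(3):
                p = pos.copy()
                p[i, c] += eps
                ep = potential_energy(p, lat)["total"]
                p[i, c] -= 2 * eps
                em = potential_energy(p, lat)["total"]
                fd = -(ep - em) / (2 * eps)
                assert F[i, c] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_internal_forces_have_no_net_force_or_torque(self, rng):
        lat = _lattice()
        pos = lat.positions + rng.normal(0.0, 0.1, lat.positions.shape)
        F = forces(pos, lat)
        assert np.abs(F.sum(axis=0)).max() < 1e-9
        torque = np.cross(pos, F).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_equilibrium_forces_vanish(self):
        lat = _lattice()
        assert np.abs(forces(lat.positions, lat)).max() < 1e-9

    def test_nan_coordinates_rejected(self):
        lat = _lattice()
        bad = lat.positions.copy()
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            potential_energy(bad, lat)


class TestIntegrator:
    def test_identical_seed_reproduces_bit_identical_frames(self):
        lat = _lattice(30)
        cfg = SimConfig(n_steps=3000, frame_interval=500, seed=99)
        t1 = run(lat, cfg)
        t2 = run(lat, cfg)
        assert np.array_equal(t1.frames, t2.frames)

    def test_different_seeds_diverge(self):
        lat = _lattice(30)
        t1 = run(lat, SimConfig(n_steps=3000, frame_interval=500, seed=1))
        t2 = run(lat, SimConfig(n_steps=3000, frame_interval=500, seed=2))
        assert not np.array_equal(t1.frames[-1], t2.frames[-1])

    def test_frame_count_contract(self):
        lat = _lattice()
        traj = run(lat, SimConfig(n_steps=1000, frame_interval=250, seed=0))
        assert traj.n_frames == 1000 // 250 + 1
        assert (np.diff(traj.times) > 0).all()

    def test_overdamped_zero_temperature_relaxes_to_equilibrium(self, rng):
        lat = _lattice(20)
        pos0 = lat.positions + rng.normal(0.0, 0.05, lat.positions.shape)
        state = SimState(positions=pos0, velocities=np.zeros_like(pos0),
                         bond_intact=np.ones(len(lat.bonds), bool))
        e0 = potential_energy(pos0, lat)["total"]
        traj = run(lat, SimConfig(n_steps=20000, gamma=20.0, temperature_K=0.0,
                                  frame_interval=20000, seed=0),
                   initial_state=state)
        e1 = potential_energy(traj.frames[-1], lat)["total"]
        assert e1 < 0.05 * e0

    def test_energy_conservation_in_symplectic_limit(self, rng):
        # gamma = 0, T = 0: BAOAB reduces to velocity Verlet; total energy
        # drift over 1e4 steps stays below 0.1%
        lat = _lattice(20)
        pos0 = lat.positions + rng.normal(0.0, 0.02, lat.positions.shape)
        state = SimState(positions=pos0, velocities=np.zeros_like(pos0),
                         bond_intact=np.ones(len(lat.bonds), bool))
        e0 = potential_energy(pos0, lat)["total"]
        traj = run(lat, SimConfig(n_steps=10000, gamma=0.0, temperature_K=0.0,
                                  frame_interval=10000, seed=0),
                   initial_state=state)
        pe = potential_energy(traj.frames[-1], lat)["total"]
        ke = 0.5 * np.sum(traj.final_velocities**2)
        assert pe + ke == pytest.approx(e0, rel=1e-3)

    def test_thermal_equipartition_of_potential_energy(self):
        lat = _lattice(30)
        traj = run(lat, SimConfig(n_steps=150000, gamma=5.0, frame_interval=1000,
                                  seed=5))
        pes = [potential_energy(f, lat)["total"] for f in traj.frames[50:]]
        expect = (3 * 30 - 6) / 2  # kT/2 per quadratic mode
        assert np.mean(pes) == pytest.approx(expect, rel=0.15)

    def test_unstable_timestep_aborts_with_diagnostic(self):
        lat = _lattice(20, PotentialParams(4000.0, 100.0, 20.0))
        with pytest.raises(IntegrationError, match="dt"):
            run(lat, SimConfig(n_steps=5000, dt=0.1, seed=0))

    def test_fixed_subunits_never_move(self):
        lat = _lattice(30)
        traj = run(lat, SimConfig(n_steps=5000, frame_interval=500, seed=3),
                   tether_ends(5, 0, 30))
        assert np.ptp(traj.frames[:, :5], axis=0).max() < 1e-12

    def test_rigid_end_group_translates_without_deforming(self):
        lat = _lattice(30)
        traj = run(lat, SimConfig(n_steps=5000, frame_interval=500, seed=3),
                   constant_end_force(10.0, "compression", 30))
        group = traj.frames[:, -5:]
        internal = group - group.mean(axis=1, keepdims=True)
        assert np.ptp(internal, axis=0).max() < 1e-9
        # and the group actually moved toward the anchor
        assert not np.allclose(group[0], group[-1])


class TestRupture:
    def test_equilibrium_lattice_has_no_ruptures(self):
        lat = _lattice()
        state = SimState(positions=lat.positions.copy(),
                         velocities=np.zeros_like(lat.positions),
                         bond_intact=np.ones(len(lat.bonds), bool))
        from actinmech.dynamics import check_ruptures
        assert check_ruptures(state, lat, (4.5247, 6.5519)) == []

    def test_overstretched_diagonal_bond_breaks_at_threshold(self):
        lat = _lattice()
        pos = lat.positions.copy()
        u = pos[1] - pos[0]
        pos[0] -= (4.60 / np.linalg.norm(u) - 1.0) * u  # bond 0 -> 4.60 nm
        state = SimState(positions=pos, velocities=np.zeros_like(pos),
                         bond_intact=np.ones(len(lat.bonds), bool))
        from actinmech.dynamics import check_ruptures
        broken = check_ruptures(state, lat, (4.5247, 6.5519))
        assert 0 in broken

    def test_rupture_is_irreversible(self):
        lat = _lattice()
        from actinmech.dynamics import check_ruptures
        pos = lat.positions.copy()
        u = pos[1] - pos[0]
        pos[0] -= (4.60 / np.linalg.norm(u) - 1.0) * u
        state = SimState(positions=pos, velocities=np.zeros_like(pos),
                         bond_intact=np.ones(len(lat.bonds), bool))
        check_ruptures(state, lat, (4.5247, 6.5519))
        state.positions = lat.positions.copy()  # geometry restored
        assert check_ruptures(state, lat, (4.5247, 6.5519)) == []
        assert not state.bond_intact[0]

    def test_strong_tension_ruptures_filament_in_simulation(self):
        lat = _lattice(30)
        cfg = SimConfig(n_steps=120000, frame_interval=2000, seed=8,
                        rupture_enabled=True)
        traj = run(lat, cfg, constant_end_force(400.0, "tension", 30))
        assert traj.rupture_events, "400 pN tension should sever the filament"
        step0 = traj.first_rupture_step()
        # bond flags in frames after the first rupture reflect the break
        after = traj.times * 0 + step0 <= traj.times / cfg.dt
        assert (~traj.bond_intact[after].all(axis=1)).any()


class TestRuptureOrdering:
    """Tension severs the filament while it is still straight; compression
    buckles it into a supercoil before (and independent of) severing."""

    @staticmethod
    def _first_supercoil_and_rupture(mode, force_pn, seed):
        from actinmech.presets import DEFAULT_POTENTIALS
        from actinmech.protocols import constant_end_force
        from actinmech.traces import frame_supercoil_calls
        n = 200
        lat = build_filament(HelicalGeometry(n_subunits=n), DEFAULT_POTENTIALS)
        cfg = SimConfig(n_steps=220000, gamma=2.0, frame_interval=1000,
                        seed=seed, rupture_enabled=True)
        traj = run(lat, cfg, constant_end_force(force_pn, mode, n))
        calls = frame_supercoil_calls(traj.frames)
        first_sc = next((i for i, c in enumerate(calls) if c.is_supercoil),
                        None)
        first_rupture = traj.first_rupture_step()
        sc_step = None if first_sc is None else first_sc * cfg.frame_interval
        return sc_step, first_rupture

    def test_tension_ruptures_without_prior_supercoiling(self):
        sc, rupture = self._first_supercoil_and_rupture("tension", 300.0, 61)
        assert rupture is not None
        assert sc is None or sc > rupture

    def test_compression_supercoils_before_rupture(self):
        sc, rupture = self._first_supercoil_and_rupture("compression", 40.0, 62)
        assert sc is not None
        if rupture is not None:
            assert sc < rupture


class TestThermalShapeProperties:
    def test_cumulative_twist_variance_grows_with_subunit_index(self):
        from actinmech.calibration import measure_twist_variance, thermal_trajectory
        from actinmech.presets import DEFAULT_POTENTIALS
        traj = thermal_trajectory(DEFAULT_POTENTIALS, n_subunits=60,
                                  n_steps=300000, frame_interval=1000, seed=17)
        idx, var = measure_twist_variance(traj, edge_exclude=10)
        slope = np.polyfit(idx, var, 1)[0]
        assert slope > 0
        # roughly linear growth: halves' slopes agree within a factor of 2.5
        half = len(idx) // 2
        s1 = np.polyfit(idx[:half], var[:half], 1)[0]
        s2 = np.polyfit(idx[half:], var[half:], 1)[0]
        assert 0.4 < s2 / s1 < 2.5
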