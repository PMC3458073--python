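"""Gō potential, forces, Langevin dynamics and trajectory observables."""

import numpy as np
import pytest

import gofold as gf
from gofold.simulate import SimulationConfig


def finite_difference_forces(topology, coords, h=1e-5):
    fd = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            xp = coords.copy()
            xp[i, d] += h
            xm = coords.copy()
            xm[i, d] -= h
            fd[i, d] = -(gf.potential_energy(topology, xp)
                         - gf.potential_energy(topology, xm)) / (2 * h)
    return fd


class TestPotentialEnergy:
    def test_native_u_chain_is_minus_one_per_contact(self, u_chain,
                                                     u_topology):
        v = gf.potential_energy(u_topology, u_chain.coords)
        assert abs(v - (-u_topology.n_contacts)) < 1e-3

    def test_bond_stretch_adds_harmonic_energy(self, u_chain, u_topology):
        x = u_chain.coords.copy()
        v0 = gf.potential_energy(u_topology, x)
        # stretch the last bond along its own axis by 0.1 A
        x[5] += np.array([-0.1, 0.0, 0.0])
        v1 = gf.potential_energy(u_topology, x)
        # K_r (dr)^2 = 100 * 0.01 = 1.0 eps, plus tiny nonbonded shifts
        assert v1 - v0 == pytest.approx(1.0, abs=2e-2)

    def test_bonded_terms_vanish_at_native(self, hairpin30,
                                           hairpin30_topology):
        top = gf.build_topology(hairpin30)
        top.contacts = np.zeros((0, 2), dtype=int)
        top.contact_r0 = np.zeros(0)
        top.excluded_pairs = np.zeros((0, 2), dtype=int)
        top.sigma_nonnative = 1e-9
        assert gf.potential_energy(top, hairpin30.coords) \
            == pytest.approx(0.0, abs=1e-20)

    def test_overlapping_beads_rejected(self, u_chain, u_topology):
        x = u_chain.coords.copy()
        x[4] = x[0] + 1e-9
        with pytest.raises(ValueError, match="overlap"):
            gf.potential_energy(u_topology, x)


class TestForces:
    def test_native_forces_nearly_zero(self, u_chain, u_topology):
        f = gf.forces(u_topology, u_chain.coords)
        # only the non-native repulsion tail can contribute here
        assert np.abs(f).max() < 1e-3

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_finite_differences(self, hairpin30, hairpin30_topology,
                                        seed):
        rng = np.random.default_rng(seed)
        x = hairpin30.coords + rng.normal(0.0, 0.25, hairpin30.coords.shape)
        fa = gf.forces(hairpin30_topology, x)
        fd = finite_difference_forces(hairpin30_topology, x)
        rel = np.abs(fa - fd).max() / np.abs(fd).max()
        assert rel < 1e-5

    def test_net_force_is_zero(self, hairpin30, hairpin30_topology):
        rng = np.random.default_rng(7)
        x = hairpin30.coords + rng.normal(0.0, 0.3, hairpin30.coords.shape)
        f = gf.forces(hairpin30_topology, x)
        assert np.abs(f.sum(axis=0)).max() < 1e-9


class TestComputeQ:
    def test_native_is_one(self, u_chain, u_topology):
        q, formed = gf.compute_q(u_topology, u_chain.coords)
        assert q == 1.0 and formed.all()

    def test_straightened_u_chain_is_zero(self, u_topology):
        line = gf.synth.make_straight_chain(6).coords
        q, formed = gf.compute_q(u_topology, line)
        assert q == 0.0 and not formed.any()

    def test_large_gamma_forms_everything(self, u_topology):
        line = gf.synth.make_straight_chain(6).coords
        q, _ = gf.compute_q(u_topology, line, gamma=1e6)
        assert q == 1.0

    def test_monotone_in_gamma(self, hairpin30, hairpin30_topology):
        rng = np.random.default_rng(0)
        x = hairpin30.coords + rng.normal(0.0, 1.0, hairpin30.coords.shape)
        qs = [gf.compute_q(hairpin30_topology, x, gamma=g)[0]
              for g in (1.05, 1.2, 1.5, 2.0, 3.0)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_empty_contact_list_convention(self, caplog):
        top = gf.build_topology(gf.synth.make_straight_chain(8))
        with caplog.at_level("WARNING", logger="gofold"):
            q, _ = gf.compute_q(top, gf.synth.make_straight_chain(8).coords)
        assert q == 1.0
        assert "no native contacts" in caplog.text


class TestLangevin:
    def test_same_seed_bit_identical(self, u_chain, u_topology):
        cfg = SimulationConfig(temperature=0.5, n_steps=2000,
                               timestep=0.005, save_every=100, seed=3)
        a = gf.run_langevin(u_topology, u_chain.coords, cfg)
        b = gf.run_langevin(u_topology, u_chain.coords, cfg)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.energies, b.energies)

    def test_low_temperature_stays_folded(self, u_chain, u_topology):
        cfg = SimulationConfig(temperature=0.1, n_steps=100_000,
                               timestep=0.005, save_every=500, seed=5)
        traj = gf.run_langevin(u_topology, u_chain.coords, cfg)
        assert traj.q_values.mean() > 0.9

    def test_zero_contact_topology_runs_with_q_one(self, caplog):
        st = gf.synth.make_straight_chain(8)
        top = gf.build_topology(st)
        cfg = SimulationConfig(temperature=0.5, n_steps=1000,
                               timestep=0.005, save_every=100, seed=1)
        with caplog.at_level("WARNING", logger="gofold"):
            traj = gf.run_langevin(top, st.coords, cfg)
        assert np.all(traj.q_values == 1.0)

    def test_blow_up_advises_smaller_timestep(self, u_chain, u_topology):
        cfg = SimulationConfig(temperature=1.0, n_steps=2000,
                               timestep=0.5, save_every=100, seed=1)
        with pytest.raises(RuntimeError, match="timestep"):
            gf.run_langevin(u_topology, u_chain.coords, cfg)

    def test_energy_conservation_without_friction(self, u_chain,
                                                  u_topology):
        # friction -> 0 turns BAOAB into velocity Verlet; with a small
        # timestep total energy should be conserved to high accuracy
        cfg = SimulationConfig(temperature=0.2, n_steps=10_000,
                               timestep=0.0005, friction=1e-12,
                               save_every=100, seed=9)
        traj = gf.run_langevin(u_topology, u_chain.coords, cfg)
        total = traj.energies + traj.kinetic
        assert np.ptp(total) < 1e-3

    def test_equipartition_kinetic_energy(self, hairpin30,
                                          hairpin30_topology):
        cfg = SimulationConfig(temperature=0.3, n_steps=100_000,
                               timestep=0.005, save_every=200, seed=12)
        traj = gf.run_langevin(hairpin30_topology, hairpin30.coords, cfg)
        ke_per_dof = traj.kinetic[traj.n_frames // 4:].mean() \
            / (3 * hairpin30.n_residues)
        assert ke_per_dof == pytest.approx(0.15, rel=0.05)

    def test_mean_energy_increases_with_temperature(self, u_chain,
                                                    u_topology):
        means = []
        for i, temp in enumerate((0.2, 0.5, 0.9)):
            cfg = SimulationConfig(temperature=temp, n_steps=50_000,
                                   timestep=0.005, save_every=200,
                                   seed=20 + i)
            traj = gf.run_langevin(u_topology, u_chain.coords, cfg)
            means.append(traj.energies[traj.n_frames // 4:].mean())
        assert means[0] < means[1] < means[2]


class TestObservables:
    def test_rmsd_identical_is_zero(self, hairpin30):
        assert gf.rmsd(hairpin30.coords, hairpin30.coords) \
            == pytest.approx(0.0, abs=1e-12)

    def test_rmsd_translation_removed_by_superposition(self, hairpin30):
        moved = hairpin30.coords + np.array([5.0, -3.0, 2.0])
        assert gf.rmsd(moved, hairpin30.coords, superpose=True) \
            == pytest.approx(0.0, abs=1e-9)
        assert gf.rmsd(moved, hairpin30.coords, superpose=False) \
            == pytest.approx(np.sqrt(38.0), rel=1e-12)

    def test_rmsd_symmetric_stretch_of_a_pair(self):
        delta = 0.7
        a = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[-delta, 0, 0], [2.0 + delta, 0, 0]])
        assert gf.rmsd(b, a, superpose=True) == pytest.approx(delta)

    def test_rg_two_beads(self):
        assert gf.radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) \
            == pytest.approx(1.0)

    def test_rg_coincident_beads(self):
        assert gf.radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_rg_matches_brute_force(self, hairpin30):
        x = hairpin30.coords
        mu = x.mean(axis=0)
        expect = np.sqrt(np.sum((x - mu) ** 2) / len(x))
        assert gf.radius_of_gyration(x) == pytest.approx(expect, rel=1e-12)

    def _traj_from_frames(self, frames, topology):
        cfg = SimulationConfig(temperature=1.0, n_steps=len(frames),
                               save_every=1)
        f = np.asarray(frames, float)
        z = np.zeros(len(f))
        return gf.Trajectory(frames=f, energies=z, q_values=z, kinetic=z,
                             config=cfg, topology=topology)

    def test_rmsf_identical_frames_is_zero(self, hairpin30,
                                           hairpin30_topology):
        traj = self._traj_from_frames([hairpin30.coords] * 5,
                                      hairpin30_topology)
        assert np.allclose(gf.rmsf(traj), 0.0)

    def test_rmsf_two_point_alternation(self, hairpin30,
                                        hairpin30_topology):
        d = 1.0
        a = hairpin30.coords.copy()
        b = hairpin30.coords.copy()
        b[0, 2] += 2 * d
        traj = self._traj_from_frames([a, b] * 10, hairpin30_topology)
        vals = gf.rmsf(traj, superpose=False)
        assert vals[0] == pytest.approx(d)
        assert np.allclose(vals[1:], 0.0)

    def test_rmsf_discard_slices_frames(self, hairpin30,
                                        hairpin30_topology):
        a = hairpin30.coords
        frames = [a + 5.0] * 5 + [a] * 5     # first half displaced
        traj = self._traj_from_frames(frames, hairpin30_topology)
        vals = gf.rmsf(traj, discard_first=0.5, superpose=False)
        assert np.allclose(vals, 0.0)

    def test_rmsf_too_few_frames(self, hairpin30, hairpin30_topology):
        traj = self._traj_from_frames([hairpin30.coords] * 2,
                                      hairpin30_topology)
        with pytest.raises(ValueError, match="frames"):
            gf.rmsf(traj, discard_first=0.9)


class TestTrajectoryIO:
    def test_xyz_and_sidecar_round_trip(self, tmp_path, u_chain,
                                        u_topology):
        cfg = SimulationConfig(temperature=0.5, n_steps=2000,
                               timestep=0.005, save_every=200, seed=4)
        traj = gf.run_langevin(u_topology, u_chain.coords, cfg)
        gf.write_trajectory(traj, tmp_path)
        frames = gf.simulate.read_trajectory_xyz(tmp_path / "traj.xyz")
        side = gf.simulate.read_trajectory_sidecar(tmp_path / "traj.tsv")
        assert frames.shape == traj.frames.shape
        assert np.allclose(frames, traj.frames, atol=1e-3)
        np.testing.assert_allclose(side["q"], traj.q_values)
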