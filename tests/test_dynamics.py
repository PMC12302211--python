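import math

import numpy as np
import pytest
from scipy import stats

import memligkin as mk
from memligkin import potentials as pot
from memligkin.builders import BuildRecipe, build_planar_bilayer, build_system
from memligkin.dynamics import (
    ConfigurationError,
    IntegrationBlowUpError,
    IntegratorParams,
    Simulation,
)
from memligkin.model import BOND_FENE, Box, ParticleSystem, Topology


def _fene_dimer(ff):
    box = Box([20.0, 20.0, 20.0])
    pos = np.array([[10.0, 10.0, 10.0], [11.0, 10.0, 10.0]])
    vel = np.array([[0.2, 0.1, 0.0], [-0.2, -0.1, 0.3]])
    system = ParticleSystem(pos, vel, np.array([1, 1], np.int8), box)
    topo = Topology(lipids=np.zeros((0, 3)),
                    bonds=np.array([[0, 1, BOND_FENE]]))
    return system, topo


def _ideal_gas(n, box_len, seed):
    local = np.random.default_rng(seed)
    pos = local.uniform(0, box_len, (n, 3))
    return ParticleSystem(pos, np.zeros((n, 3)), np.full(n, 3, np.int8),
                          Box([box_len] * 3)), Topology(lipids=np.zeros((0, 3)))


class TestIntegrator:
    def test_symplectic_limit_energy_conservation(self, ff_semirigid):
        """gamma = 0, no noise: secular energy drift of a FENE dimer stays
        below 1e-4 relative over 1e4 steps at dt = 0.005."""
        system, topo = _fene_dimer(ff_semirigid)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.005, gamma=0.0, seed=0))
        energies = []
        for _ in range(10000):
            sim.step(1)
            energies.append(sim.kinetic_energy + sim.potential_energy)
        # secular drift: phase-averaged energy early vs late (the bounded
        # Verlet oscillation itself is not drift)
        early = np.mean(energies[:2000])
        late = np.mean(energies[-2000:])
        assert abs(late - early) / abs(early) < 1e-4

    def test_trajectories_bit_identical_for_same_seed(self, ff_semirigid):
        runs = []
        for _ in range(2):
            system, topo = _fene_dimer(ff_semirigid)
            sim = Simulation(system, topo, ff_semirigid,
                             IntegratorParams(dt=0.005, gamma=1.0, seed=42))
            sim.step(2000)
            runs.append((sim.system.positions.copy(),
                         sim.system.velocities.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_different_seeds_diverge(self, ff_semirigid):
        finals = []
        for seed in (1, 2):
            system, topo = _fene_dimer(ff_semirigid)
            sim = Simulation(system, topo, ff_semirigid,
                             IntegratorParams(dt=0.005, gamma=1.0, seed=seed))
            sim.step(500)
            finals.append(sim.system.positions.copy())
        assert not np.allclose(finals[0], finals[1])

    def test_equipartition_dilute_gas(self, ff_semirigid):
        """Time-averaged kinetic energy per bead = (3/2) kBT within 3
        standard errors (block-averaged) for a thermostatted dilute gas."""
        system, topo = _ideal_gas(50, 50.0, seed=11)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.005, gamma=1.0, kBT=1.1,
                                          seed=5))
        sim.step(2000)  # thermalize
        samples = []
        for _ in range(1000):
            sim.step(100)
            samples.append(sim.kinetic_energy / 50)
        blocks = np.array(samples).reshape(20, 50).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(len(blocks))
        assert np.mean(samples) == pytest.approx(1.5 * 1.1, abs=3 * se)

    def test_velocity_distribution_is_maxwell_boltzmann(self, ff_semirigid):
        """KS statistic of sampled velocity components against the normal
        distribution sqrt(kBT/m) stays below the 1% critical value."""
        system, topo = _ideal_gas(50, 50.0, seed=13)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.005, gamma=1.0, kBT=1.1,
                                          seed=7))
        sim.step(2000)
        samples = []
        for _ in range(80):
            sim.step(250)  # ~1.25 friction times between samples
            samples.append(sim.system.velocities.ravel().copy())
        v = np.concatenate(samples)
        d, _ = stats.kstest(v, "norm", args=(0.0, math.sqrt(1.1)))
        n = len(v)
        critical_1pct = 1.63 / math.sqrt(n)
        assert d < critical_1pct

    def test_blowup_reported(self, ff_semirigid):
        system, topo = _fene_dimer(ff_semirigid)
        system.velocities[0] = [200.0, 0.0, 0.0]  # guaranteed overstretch
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.005, gamma=0.0, seed=0))
        with pytest.raises(IntegrationBlowUpError):
            sim.step(200)


class TestNeighborList:
    def test_cell_list_forces_equal_brute_force(self, ff_semirigid):
        """Forces from the cell-list kernels match the all-pairs reference
        to near machine precision on random jittered-lattice configs."""
        local = np.random.default_rng(99)
        for trial in range(50):
            n_side = int(local.integers(3, 6))
            spacing = 1.1
            grid = np.stack(np.meshgrid(*[np.arange(n_side)] * 3,
                                        indexing="ij"), -1).reshape(-1, 3)
            pos = (grid * spacing + 0.5
                   + local.uniform(-0.25, 0.25, grid.shape))
            n = len(pos)
            box_len = max(n_side * spacing + 0.6, 2 * 2.623 + 0.1)
            types = local.integers(0, 6, n).astype(np.int8)
            box = Box([box_len] * 3)
            system = ParticleSystem(box.wrap(pos), np.zeros((n, 3)),
                                    types, box)
            topo = Topology(lipids=np.zeros((0, 3)))
            sim = Simulation(system, topo, ff_semirigid,
                             IntegratorParams(seed=trial))
            f_ref, e_ref, v_ref = pot.total_energy_forces(
                system, topo, ff_semirigid)
            scale = max(1.0, np.abs(f_ref).max())
            assert np.abs(sim.forces - f_ref).max() / scale < 1e-11
            for name in ("repulsion", "attraction"):
                assert sim.energy_terms[name] == pytest.approx(
                    e_ref[name], rel=1e-9, abs=1e-9)

    def test_list_stays_valid_during_dynamics(self, small_membrane):
        """After thousands of steps with automatic rebuilds, kernel forces
        still agree with the brute-force reference."""
        sim = small_membrane
        f_ref, _, _ = pot.total_energy_forces(sim.system, sim.topology,
                                              sim.ff, sim.partner_r)
        scale = max(1.0, np.abs(f_ref).max())
        assert np.abs(sim.forces - f_ref).max() / scale < 1e-11


class TestZeroTension:
    def test_prestretched_membrane_relaxes_and_holds(self, ff_semirigid):
        """After equilibrating to the tensionless area, a +5% area stretch
        contracts back toward it under zero-tension control, while an
        unstretched membrane shows no systematic area drift."""
        system, topo = build_planar_bilayer(100.0, box_height=22.0,
                                            seed=21)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.002, seed=3))
        sim.step(2000)
        sim.params.dt = 0.005
        sim.params.tension_control = "zero_tension"
        sim.step(50000)
        a_eq = sim.system.box.area_xy
        # hold: no systematic drift at the tensionless area
        sim.step(12000)
        assert abs(sim.system.box.area_xy - a_eq) / a_eq < 0.015
        a_eq = sim.system.box.area_xy
        # stretch +5% and watch it come back
        from memligkin import _kernels as K
        K.scale_lateral(sim.system.positions, sim.system.box.lengths,
                        math.sqrt(1.05))
        sim._rebuild_neighbors()
        sim._compute_forces()
        a0 = sim.system.box.area_xy
        areas = [a0]
        for _ in range(8):
            sim.step(3500)
            areas.append(sim.system.box.area_xy)
        assert areas[-1] < a0 - 0.5 * (a0 - a_eq)   # most of the way back
        shrink_steps = sum(b < a for a, b in zip(areas, areas[1:]))
        assert shrink_steps >= 6                    # monotone in trend

    def test_tension_control_off_box_never_changes(self, small_membrane):
        sim = small_membrane
        lengths = sim.system.box.lengths.copy()
        sim.step(500)
        assert np.array_equal(lengths, sim.system.box.lengths)

    def test_rejected_for_soluble_systems(self, ff_semirigid):
        recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=1,
                             ecd_beads=4, box_height=15.0, seed=1)
        system, topo = build_system(recipe, ff_semirigid)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(tension_control="zero_tension"))
        with pytest.raises(ConfigurationError):
            sim.step(10)


class TestRunAndCheckpoint:
    def test_zero_steps_calls_observers_once(self, ff_semirigid):
        system, topo = _fene_dimer(ff_semirigid)
        sim = Simulation(system, topo, ff_semirigid, IntegratorParams(seed=1))
        pos0 = sim.system.positions.copy()
        calls = []
        sim.run(0, observers=[(10, lambda s: calls.append(s.step_index))])
        assert calls == [0]
        assert np.array_equal(pos0, sim.system.positions)

    def test_observer_stride(self, ff_semirigid):
        system, topo = _fene_dimer(ff_semirigid)
        sim = Simulation(system, topo, ff_semirigid, IntegratorParams(seed=1))
        calls = []
        sim.run(100, observers=[(25, lambda s: calls.append(s.step_index))])
        assert calls == [0, 25, 50, 75, 100]

    def test_checkpoint_restart_bit_identity(self, ff_rigid, tmp_path):
        """run(1000); checkpoint; restore; run(1000) equals a single
        run(2000) bit for bit (same seed stream)."""
        recipe = BuildRecipe(shape="soluble", n_receptors=2, n_ligands=2,
                             ecd_beads=4, box_height=15.0, seed=8)
        system, topo = build_system(recipe, ff_rigid)
        sim_a = Simulation(system.copy(), topo, ff_rigid,
                           IntegratorParams(seed=77))
        sim_a.step(2000)

        sim_b = Simulation(system.copy(), topo, ff_rigid,
                           IntegratorParams(seed=77))
        sim_b.step(1000)
        ckpt = tmp_path / "state.h5"
        sim_b.checkpoint(ckpt)
        sim_c = Simulation.restore(ckpt)
        sim_c.step(1000)
        assert np.array_equal(sim_a.system.positions, sim_c.system.positions)
        assert np.array_equal(sim_a.system.velocities, sim_c.system.velocities)
        assert np.array_equal(sim_a.partner_r, sim_c.partner_r)

    def test_corrupted_checkpoint_detected(self, ff_rigid, tmp_path):
        import h5py
        from memligkin.dynamics import CheckpointCorruptionError
        system, topo = _fene_dimer(ff_rigid)
        sim = Simulation(system, topo, ff_rigid, IntegratorParams(seed=1))
        ckpt = tmp_path / "state.h5"
        sim.checkpoint(ckpt)
        with h5py.File(ckpt, "r+") as f:
            f["positions"][0, 0] = 99.0
        with pytest.raises(CheckpointCorruptionError):
            Simulation.restore(ckpt)


class TestMembraneStability:
    def test_bilayer_stays_cohesive(self, ff_semirigid):
        """No lipid evaporation over a sustained run: every tail bead keeps
        at least one foreign tail neighbor within 1.5 sigma0, and the
        bilayer remains one connected tail-adjacency cluster."""
        from scipy.spatial import cKDTree
        import networkx as nx
        system, topo = build_planar_bilayer(120.0, box_height=20.0, seed=31)
        sim = Simulation(system, topo, ff_semirigid,
                         IntegratorParams(dt=0.002, seed=14))
        sim.step(2000)
        sim.params.dt = 0.005
        sim.params.tension_control = "zero_tension"
        sim.step(20000)
        sim.params.tension_control = "off"
        sim.step(20000)
        tails = np.concatenate([topo.lipids[:, 1], topo.lipids[:, 2]])
        pos = sim.system.positions[tails]
        tree = cKDTree(pos, boxsize=sim.system.box.lengths)
        pairs = tree.query_pairs(1.5)
        lipid_of = np.repeat(np.arange(len(topo.lipids)), 2).reshape(2, -1).T
        lipid_of = np.concatenate([np.arange(len(topo.lipids)),
                                   np.arange(len(topo.lipids))])
        g = nx.Graph()
        g.add_nodes_from(range(len(topo.lipids)))
        foreign = np.zeros(len(tails), dtype=bool)
        for a, b in pairs:
            if lipid_of[a] != lipid_of[b]:
                foreign[a] = foreign[b] = True
                g.add_edge(int(lipid_of[a]), int(lipid_of[b]))
        assert foreign.all()
        assert nx.number_connected_components(g) == 1
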