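import math

import numpy as np
import pytest

from memligkin import potentials as pot
from memligkin.builders import BuildRecipe, build_system
from memligkin.model import default_forcefield

RC = 2.0 ** (1.0 / 6.0)
rng = np.random.default_rng(20240915)


class TestClosedForms:
    @pytest.mark.parametrize("d", [0.95, 1.0])
    def test_repulsion_vanishes_at_cutoff(self, d):
        ef = pot.repulsion(RC * d, d)
        assert ef.energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ef.forces, 0.0, atol=1e-12)

    def test_repulsion_at_contact_equals_eps(self):
        # 4*eps*(1 - 1) + eps at r = d
        assert pot.repulsion(1.0, 1.0).energy == pytest.approx(1.0)

    def test_repulsion_matches_shifted_lj_form(self):
        r, d = 0.8 * 0.95, 0.95
        s6 = (d / r) ** 6
        expected = 4.0 * (s6 ** 2 - s6) + 1.0
        assert pot.repulsion(r, d).energy == pytest.approx(expected, rel=1e-12)

    def test_fene_zero_extension(self):
        ef = pot.fene_bond(0.0, 30.0, 1.5)
        assert ef.energy == 0.0 and np.all(ef.forces == 0.0)

    def test_fene_known_value(self):
        # -0.5*30*1.5^2*ln(1 - 1/1.5^2) at r = 1
        expected = -0.5 * 30 * 2.25 * math.log(1 - 1 / 2.25)
        assert pot.fene_bond(1.0, 30.0, 1.5).energy == pytest.approx(expected)
        assert expected == pytest.approx(19.84, abs=0.01)

    def test_fene_diverges_monotonically(self):
        es = [pot.fene_bond(r, 30.0, 1.5).energy
              for r in np.linspace(1.0, 1.499, 40)]
        assert np.all(np.diff(es) > 0)
        assert es[-1] > 200.0

    def test_fene_overstretch_raises(self):
        with pytest.raises(pot.FiniteExtensibilityError):
            pot.fene_bond(1.5, 30.0, 1.5)

    @pytest.mark.parametrize("delta", [0.0, 1.0, -1.0])
    def test_spring_is_symmetric_harmonic(self, delta):
        ef = pot.straightening_spring(4.0 + delta, 10.0, 4.0)
        assert ef.energy == pytest.approx(0.5 * 10.0 * delta ** 2)

    def test_attraction_plateau_taper_and_cutoff(self):
        eps, wc = 1.0, 1.5
        assert pot.tail_attraction(RC, eps, wc).energy == pytest.approx(-eps)
        mid = pot.tail_attraction(RC + wc / 2, eps, wc)
        assert mid.energy == pytest.approx(-eps / 2)
        end = pot.tail_attraction(RC + wc, eps, wc)
        assert end.energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(end.forces, 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta0", [math.pi, 2.0])
    def test_bending_minimum_at_preferred_angle(self, theta0):
        assert pot.bending(theta0, 10.0, theta0).energy == pytest.approx(0.0, abs=1e-12)

    def test_bending_quarter_turn_costs_k(self):
        assert pot.bending(math.pi / 2, 10.0, math.pi).energy == pytest.approx(10.0)

    def test_bending_full_reversal_costs_2k(self):
        # k_bend*[1 - cos(pi)] = 2*k_bend
        assert pot.bending(0.0, 10.0, math.pi).energy == pytest.approx(20.0)

    def test_binding_zero_at_cutoff_and_right_angle(self):
        assert pot.binding(1.5, 0.0, 0.0, 14.0, 1.5).energy == 0.0
        assert pot.binding(0.5, math.pi / 2, 0.0, 14.0, 1.5).energy == \
            pytest.approx(0.0, abs=1e-30)

    def test_binding_approaches_full_depth(self):
        e = pot.binding_profile(1e-6, 0.0, 0.0, 14.0, 1.5)
        assert e == pytest.approx(-14.0, rel=1e-5)

    def test_binding_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            pot.binding_profile(0.0, 0.0, 0.0, 14.0, 1.5)


def _fd_check(energy_of, x0, forces, tol=1e-5):
    """Central-difference gradient check: force = -dE/dx componentwise."""
    h = 1e-6
    for b in range(x0.shape[0]):
        for a in range(3):
            xp = x0.copy(); xp[b, a] += h
            xm = x0.copy(); xm[b, a] -= h
            fd = -(energy_of(xp) - energy_of(xm)) / (2 * h)
            scale = max(1.0, abs(fd))
            assert forces[b, a] == pytest.approx(fd, abs=tol * scale)


class TestGradients:
    """Central-difference agreement, 1e-5 relative, on random geometries."""

    @pytest.mark.parametrize("term,n_cfg", [
        ("repulsion", 40), ("fene", 40), ("spring", 40),
        ("attraction", 40),
    ])
    def test_pair_terms(self, term, n_cfg):
        local = np.random.default_rng(hash(term) % 2 ** 31)
        for _ in range(n_cfg):
            if term == "repulsion":
                r = local.uniform(0.75, RC * 1.05)
                fn = lambda rr: pot.repulsion_profile(rr, 1.0)[0]
                ef = pot.repulsion(r, 1.0)
            elif term == "fene":
                r = local.uniform(0.1, 1.4)
                fn = lambda rr: pot.fene_profile(rr, 30.0, 1.5)[0]
                ef = pot.fene_bond(r, 30.0, 1.5)
            elif term == "spring":
                r = local.uniform(2.0, 6.0)
                fn = lambda rr: pot.harmonic_profile(rr, 10.0, 4.0)[0]
                ef = pot.straightening_spring(r, 10.0, 4.0)
            else:
                r = local.uniform(RC + 0.01, RC + 1.49)
                fn = lambda rr: pot.attraction_profile(rr, 1.0, 1.5)[0]
                ef = pot.tail_attraction(r, 1.0, 1.5)
            x0 = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
            _fd_check(lambda x: fn(np.linalg.norm(x[1] - x[0])), x0, ef.forces)
            assert np.allclose(ef.forces.sum(axis=0), 0.0, atol=1e-12)

    def test_bending_gradients(self):
        for _ in range(40):
            x = rng.uniform(-1.5, 1.5, (3, 3))
            ef = pot.angle_energy_force(x[0], x[1], x[2], 10.0, math.pi)
            _fd_check(lambda xx: pot.angle_energy_force(
                xx[0], xx[1], xx[2], 10.0, math.pi).energy, x, ef.forces)
            assert np.allclose(ef.forces.sum(axis=0), 0.0, atol=1e-10)

    def test_binding_gradients(self):
        for _ in range(40):
            x = rng.uniform(-1.0, 1.0, (4, 3))
            x[2] = x[1] + rng.uniform(-0.9, 0.9, 3)
            ef = pot.binding_energy_force(x[0], x[1], x[2], x[3], 14.0, 1.5)
            _fd_check(lambda xx: pot.binding_energy_force(
                xx[0], xx[1], xx[2], xx[3], 14.0, 1.5).energy, x, ef.forces)
            assert np.allclose(ef.forces.sum(axis=0), 0.0, atol=1e-10)


def _random_rotation(local):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        local.integers(2 ** 31))).as_matrix()


class TestInvariance:
    def test_angle_term_rotation_translation_invariant(self):
        for _ in range(20):
            x = rng.uniform(-1.5, 1.5, (3, 3))
            e0 = pot.angle_energy_force(x[0], x[1], x[2], 10.0, 2.5).energy
            R = _random_rotation(rng)
            t = rng.uniform(-5, 5, 3)
            y = x @ R.T + t
            e1 = pot.angle_energy_force(y[0], y[1], y[2], 10.0, 2.5).energy
            assert e1 == pytest.approx(e0, abs=1e-9)

    def test_binding_term_rotation_translation_invariant(self):
        for _ in range(20):
            x = rng.uniform(-1.0, 1.0, (4, 3))
            x[2] = x[1] + rng.uniform(-0.9, 0.9, 3)
            e0 = pot.binding_energy_force(*x, 14.0, 1.5).energy
            R = _random_rotation(rng)
            t = rng.uniform(-5, 5, 3)
            y = x @ R.T + t
            e1 = pot.binding_energy_force(*y, 14.0, 1.5).energy
            assert e1 == pytest.approx(e0, abs=1e-9)


class TestPairingRule:
    def test_one_receptor_two_ligands_single_bond(self, ff_semirigid):
        """With two ligand sites inside the cutoff of one receptor site,
        the 1:1 registry activates exactly one (the lower-energy) bond."""
        from memligkin.dynamics import IntegratorParams, Simulation
        recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=2,
                             ecd_beads=4, box_height=20.0, seed=4)
        system, topo = build_system(recipe, ff_semirigid)
        # place both ligand sites near the receptor site, aligned head-on
        p = system.positions
        rsite = p[topo.receptors[0].site]
        axis = rsite - p[topo.receptors[0].ecd[-1]]
        axis /= np.linalg.norm(axis)
        for k, lig in enumerate(topo.ligands):
            offset = (0.8 + 0.3 * k) * axis
            chain = np.concatenate([lig.chain, [lig.site]])
            # site closest to the receptor, chain extending away head-on
            for m, bead in enumerate(chain):
                p[bead] = rsite + offset + axis * 0.95 * (len(chain) - 1 - m)
        system.positions = system.box.wrap(p)
        from memligkin.potentials import assign_binding_pairs
        pr, pl = assign_binding_pairs(system, topo, ff_semirigid)
        assert np.sum(pr >= 0) == 1
        assert np.sum(pl >= 0) == 1
        # bound partner is the closer (lower-energy) ligand
        assert pr[0] == 0
        _, energies, _ = pot.total_energy_forces(system, topo,
                                                 ff_semirigid, pr)
        assert energies["binding"] >= -ff_semirigid.eps_bind - 1e-9

    def test_pairs_persist_until_cutoff(self, ff_semirigid):
        """A bound pair stays assigned while within rcut even if a closer
        candidate appears (reassignment only after unbinding)."""
        from memligkin.potentials import assign_binding_pairs
        recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=2,
                             ecd_beads=4, box_height=20.0, seed=4)
        system, topo = build_system(recipe, ff_semirigid)
        p = system.positions
        rsite = p[topo.receptors[0].site]
        axis = rsite - p[topo.receptors[0].ecd[-1]]
        axis /= np.linalg.norm(axis)
        for k, lig in enumerate(topo.ligands):
            offset = (1.3 - 0.5 * k) * axis  # ligand 1 closer than ligand 0
            chain = np.concatenate([lig.chain, [lig.site]])
            for m, bead in enumerate(chain):
                p[bead] = rsite + offset + axis * 0.95 * (len(chain) - 1 - m)
        system.positions = system.box.wrap(p)
        current = np.array([0])  # receptor already bound to ligand 0
        pr, pl = assign_binding_pairs(system, topo, ff_semirigid, current)
        assert pr[0] == 0


class TestTotalEnergyForces:
    def test_isolated_bead_all_terms_zero(self, ff_semirigid):
        from memligkin.model import Box, ParticleSystem, Topology
        box = Box([20.0, 20.0, 20.0])
        system = ParticleSystem(np.array([[10.0, 10.0, 10.0]]),
                                np.zeros((1, 3)),
                                np.array([3], dtype=np.int8), box)
        # a single free chain bead: not a valid molecule, but the force
        # evaluation itself must return zeros everywhere
        topo = Topology(lipids=np.zeros((0, 3)))
        forces, energies, virial = pot.total_energy_forces(system, topo,
                                                           ff_semirigid)
        assert np.all(forces == 0.0)
        assert all(v == 0.0 for v in energies.values())

    def test_net_force_on_center_of_mass_vanishes(self, small_membrane):
        sim = small_membrane
        forces, _, _ = pot.total_energy_forces(sim.system, sim.topology,
                                               sim.ff, sim.partner_r)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-8)

    def test_lipid_bonded_terms_at_analytic_minimum(self, ff_semirigid):
        """A lipid placed at each bonded term's analytic minimum has zero
        bonded energy gradient along its axis (1-D minimization oracle)."""
        from scipy.optimize import minimize_scalar
        ff = ff_semirigid

        def fene_plus_wca(r):
            e, _ = pot.fene_profile(r, ff.fene_k, ff.fene_rmax)
            e2, _ = pot.repulsion_profile(r, ff.sigma_head)
            return e + e2

        res = minimize_scalar(fene_plus_wca, bounds=(0.5, 1.4),
                              method="bounded")
        r_min = res.x
        # numerical derivative at the 1-D minimizer is ~0
        h = 1e-5
        d = (fene_plus_wca(r_min + h) - fene_plus_wca(r_min - h)) / (2 * h)
        assert abs(d) < 1e-3
        assert 0.7 < r_min < 1.1
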