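import math

import numpy as np
import pytest
from scipy import stats

import memligkin as mk
from memligkin import analysis as ana
from memligkin.builders import BuildRecipe, build_system
from memligkin.dynamics import IntegratorParams, Simulation
from memligkin.model import Box

RC = 2.0 ** (1.0 / 6.0)


class TestHistogram:
    def test_density_normalized_with_errors(self):
        local = np.random.default_rng(3)
        h = ana.make_histogram(local.normal(size=5000), bins=30)
        assert h.integral() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.se >= 0)
        assert h.n_samples == 5000

    def test_empty_input_flagged(self):
        with pytest.raises(ana.EmptyResultError):
            ana.make_histogram(np.zeros(0))


class TestPairCorrelation2D:
    def test_ideal_gas_is_unity(self):
        """Uniformly random points give g(r) = 1 within 3 SE per bin."""
        local = np.random.default_rng(5)
        box = Box([30.0, 30.0, 10.0])
        frames = [np.column_stack([local.uniform(0, 30, (40, 2)),
                                   np.zeros(40)]) for _ in range(300)]
        res = ana.pair_correlation_2d(frames, np.arange(40), box, bins=25)
        assert np.all(np.abs(res.g - 1.0) <= 3.0 * res.se + 1e-12)

    def test_two_frozen_sites_single_bin(self):
        box = Box([20.0, 20.0, 10.0])
        frames = [np.array([[5.0, 5.0, 0.0], [8.0, 5.0, 0.0]])] * 10
        res = ana.pair_correlation_2d(frames, np.array([0, 1]), box, bins=20,
                                      r_max=10.0)
        occupied = res.g > 0
        assert occupied.sum() == 1
        assert res.r[occupied][0] == pytest.approx(3.0, abs=0.3)

    def test_hard_disks_depleted_below_diameter(self):
        """Low-density hard disks (rejection-sampled): g ~ 0 below the
        diameter and ~ 1 beyond."""
        local = np.random.default_rng(11)
        L, n, diam = 40.0, 30, 2.0
        frames = []
        while len(frames) < 150:
            pts = local.uniform(0, L, (n, 2))
            dv = pts[None] - pts[:, None]
            dv -= L * np.round(dv / L)
            rr = np.sqrt((dv ** 2).sum(-1))
            iu = np.triu_indices(n, 1)
            if np.all(rr[iu] > diam):
                frames.append(np.column_stack([pts, np.zeros(n)]))
        res = ana.pair_correlation_2d(frames, np.arange(n),
                                      Box([L, L, 10.0]), bins=40)
        below = res.r < diam
        beyond = (res.r > diam + 0.5)
        assert np.all(res.g[below] == 0.0)
        assert np.abs(res.g[beyond] - 1.0).mean() < 0.1

    def test_needs_two_sites(self):
        with pytest.raises(ValueError):
            ana.pair_correlation_2d([np.zeros((1, 3))], [0],
                                    Box([10.0, 10.0, 10.0]))


def _single_receptor_md(ff, n_steps, stride, seed=3, box_len=25.0):
    recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=0,
                         ecd_beads=6, box_height=box_len, seed=seed)
    system, topo = build_system(recipe, ff)
    sim = Simulation(system, topo, ff, IntegratorParams(seed=seed + 1))
    sim.step(5000)
    frames = []
    for _ in range(n_steps // stride):
        sim.step(stride)
        frames.append(sim.system.positions.copy())
    return sim, topo, frames


from tests_helpers_chain import chain_oracle_samples as _chain_oracle_samples


class TestEndToEnd:
    def test_rigid_rod_peaks_at_contour_length(self, ff_semirigid):
        """k_bend = 1000: R_e distribution collapses near the contour."""
        ff = ff_semirigid.replace(k_bend=1000.0)
        sim, topo, frames = _single_receptor_md(ff, 40000, 400)
        samples = ana.end_to_end_samples(frames, topo, sim.system.box)
        # 6 ECD beads + site = 6 bonds of ~0.97 (WCA-shifted)
        assert samples.mean() > 5.4
        assert samples.std() < 0.25

    def test_flexible_chain_matches_sampling_oracle(self, ff_semirigid):
        """k_bend = 0: MD R_e distribution matches the exact chain-sampling
        oracle (freely jointed directions + excluded volume) by KS test at
        the 1% level."""
        ff = ff_semirigid.replace(k_bend=0.0)
        sim, topo, frames = _single_receptor_md(ff, 1_200_000, 2000)
        md = ana.end_to_end_samples(frames, topo, sim.system.box)
        oracle = _chain_oracle_samples(3000, n_bonds=6)
        res = stats.ks_2samp(md, oracle)
        n_eff = len(md) * len(oracle) / (len(md) + len(oracle))
        critical_1pct = 1.63 / math.sqrt(n_eff)
        assert res.statistic < critical_1pct

    def test_selection_requires_known_state_labels(self, ff_semirigid):
        with pytest.raises(ValueError):
            ana.end_to_end_samples([], None, None, which="sideways")


class TestBindingGeometry:
    def test_clamped_sites_concentrate_mass(self):
        """Synthetic frames with sites frozen at r = 0.5, theta1 = theta2
        = 0 put all histogram mass in those bins."""
        from memligkin.model import Ligand, Receptor, Topology
        box = Box([20.0, 20.0, 20.0])
        # receptor beads 0-1 (axis bead 0? ecd chain [0], site 1)
        topo = Topology(lipids=np.zeros((0, 3)),
                        receptors=[Receptor(np.zeros(0), np.array([0]), 1)],
                        ligands=[Ligand(np.array([3]), 2)])
        pos = np.array([
            [5.0, 5.0, 5.0],    # receptor chain bead
            [6.0, 5.0, 5.0],    # receptor site (axis +x)
            [6.5, 5.0, 5.0],    # ligand site, r = 0.5
            [7.5, 5.0, 5.0],    # ligand chain bead (axis -x toward site)
        ])
        frames = [pos] * 5
        pair_bound = np.ones((5, 1, 1), dtype=bool)
        th1, th2, rr = ana.binding_geometry_samples(frames, topo, box,
                                                    pair_bound)
        assert np.allclose(th1, 0.0, atol=1e-9)
        assert np.allclose(th2, 0.0, atol=1e-9)
        assert np.allclose(rr, 0.5)
        h1, h2, hr = ana.binding_geometry(frames, topo, box, pair_bound)
        assert h1.integral() == pytest.approx(1.0, abs=1e-9)

    def test_no_bound_frames_flagged(self):
        from memligkin.model import Ligand, Receptor, Topology
        topo = Topology(lipids=np.zeros((0, 3)),
                        receptors=[Receptor(np.zeros(0), np.array([0]), 1)],
                        ligands=[Ligand(np.array([3]), 2)])
        box = Box([10.0, 10.0, 10.0])
        frames = [np.zeros((4, 3)) + 1.0]
        with pytest.raises(ana.EmptyResultError):
            ana.binding_geometry(frames, topo, box,
                                 np.zeros((1, 1, 1), dtype=bool))

    def test_bound_pair_radial_pmf_matches_quadrature(self, ff_rigid):
        """The radial distribution of a bound stiff pair agrees with a
        direct Boltzmann quadrature over (r, theta1, theta2) for rigid
        axes (independent numerical oracle), within 0.4 kBT on the PMF."""
        kBT = 1.1
        ff = ff_rigid.replace(k_bend=1000.0, eps_bind=40.0)
        recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=1,
                             ecd_beads=6, box_height=11.0, seed=6)
        system, topo = build_system(recipe, ff)
        # start in the bound configuration: ligand docked head-on
        p = system.positions
        rec, lig = topo.receptors[0], topo.ligands[0]
        axis = p[rec.site] - p[rec.ecd[-1]]
        axis /= np.linalg.norm(axis)
        chain = np.concatenate([lig.chain, [lig.site]])
        for m, bead in enumerate(chain):
            p[bead] = (p[rec.site] + 1.0 * axis
                       + axis * 0.97 * (len(chain) - 1 - m))
        system.positions = system.box.wrap(p)
        sim = Simulation(system, topo, ff, IntegratorParams(seed=8))
        sim.step(4000)
        from memligkin.kinetics import site_distances
        rr = []
        for _ in range(12000):
            sim.step(40)
            r = float(site_distances(sim.system, topo)[0, 0])
            if r < 1.45:
                rr.append(r)
        rr = np.array(rr)
        assert len(rr) > 1500
        # quadrature oracle: p(r) ~ r^2 exp(-WCA/kBT) I(r),
        # I(r) = <exp(eps*c1^2*c2^2*g(r)/kBT)> over isotropic axes
        r_grid = np.linspace(0.85, 1.45, 25)
        c = np.linspace(0, 1, 201)  # cos(theta) for the active quadrant
        env = (1 - (r_grid / ff.bind_rcut) ** 2) ** 2

        def wca(r):
            d = 0.95
            if r >= RC * d:
                return 0.0
            s6 = (d / r) ** 6
            return 4.0 * (s6 * s6 - s6) + 1.0

        p = np.zeros_like(r_grid)
        for i, r in enumerate(r_grid):
            boltz = np.exp(ff.eps_bind * env[i]
                           * np.outer(c ** 2, c ** 2) / kBT)
            # isotropic axis measure: uniform in cos(theta) over [-1, 1];
            # the inactive 3 quadrants contribute weight 3/4 * 1
            inner = (boltz.mean() + 3.0) / 4.0
            p[i] = r ** 2 * math.exp(-wca(r) / kBT) * inner
        p /= np.trapezoid(p, r_grid)
        hist, edges = np.histogram(rr, bins=np.linspace(0.85, 1.45, 26),
                                   density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # compare the well region, where both the sampling and the
        # rigid-axis assumption are solid; the PMF is defined up to an
        # additive constant
        good = (hist > 0) & (centers > 0.86) & (centers < 1.10)
        assert good.sum() >= 8
        pmf_md = -kBT * np.log(hist[good])
        pmf_or = -kBT * np.log(np.interp(centers[good], r_grid, p))
        shift = np.mean(pmf_md - pmf_or)
        assert np.max(np.abs(pmf_md - pmf_or - shift)) < 0.4


class TestUndulationSpectrum:
    def test_synthetic_recovery_within_10_percent(self):
        frames = ana.synthetic_undulation_frames(300, grid=64,
                                                 box_length=16.4,
                                                 kappa=13.0, seed=3)
        box = Box([16.4, 16.4, 20.0])
        res = ana.undulation_spectrum(frames, box, grid=16,
                                      head_indices=np.arange(64 * 64))
        assert res.kappa == pytest.approx(13.0, rel=0.10)

    def test_grid_resolution_independence(self):
        """kappa varies by < 15% between ~1 and ~2 sigma0 grid spacing."""
        frames = ana.synthetic_undulation_frames(250, grid=64,
                                                 box_length=16.0,
                                                 kappa=13.0, seed=9)
        box = Box([16.0, 16.0, 20.0])
        kappas = [ana.undulation_spectrum(frames, box, grid=g,
                                          head_indices=np.arange(64 * 64)
                                          ).kappa
                  for g in (8, 16)]
        assert abs(kappas[1] - kappas[0]) / kappas[0] < 0.15

    def test_flat_frames_flag_rigid_limit(self):
        xy = np.stack(np.meshgrid(np.arange(8), np.arange(8),
                                  indexing="ij"), -1).reshape(-1, 2) + 0.5
        flat = np.column_stack([xy, np.zeros(len(xy))])
        res = ana.undulation_spectrum([flat] * 5, Box([8.0, 8.0, 10.0]),
                                      grid=8, head_indices=np.arange(64))
        assert res.rigid_limit
        assert math.isinf(res.kappa)

    def test_vesicle_rejected(self):
        from memligkin.model import Topology
        topo = Topology(lipids=np.array([[0, 1, 2]]), shape="vesicle")
        with pytest.raises(ValueError):
            ana.undulation_spectrum([np.zeros((3, 3))],
                                    Box([10.0, 10.0, 10.0]), topology=topo)

    def test_fit_window_excludes_protrusion_scales(self):
        frames = ana.synthetic_undulation_frames(50, grid=32,
                                                 box_length=16.0,
                                                 kappa=13.0, seed=1)
        res = ana.undulation_spectrum(frames, Box([16.0, 16.0, 10.0]),
                                      grid=16,
                                      head_indices=np.arange(32 * 32))
        assert np.all(res.q <= 2.0 * math.pi / 5.0 + 1e-9)
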