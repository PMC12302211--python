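"""Shared chain-statistics helpers: an exact equilibrium sampler for a
free bead chain (the brute-force oracle) and the matching MD sampler."""

import math

import numpy as np

RC = 2.0 ** (1.0 / 6.0)


def chain_oracle_samples(n, n_bonds, kBT=1.1, k=100.0, r0=0.95, d=0.95,
                         seed=5):
    """Exact equilibrium R_e sampler for a free chain at k_bend = 0:
    bond lengths from the bonded Boltzmann marginal, directions uniform
    (freely jointed), then rejection on the non-adjacent excluded-volume
    energy."""
    rng = np.random.default_rng(seed)
    rc = RC * d

    def wca(r):
        if r >= rc:
            return 0.0
        s6 = (d / r) ** 6
        return 4.0 * (s6 * s6 - s6) + 1.0

    rs = np.linspace(0.5, 1.5, 2001)
    w = rs ** 2 * np.exp(-(0.5 * k * (rs - r0) ** 2
                           + np.array([wca(r) for r in rs])) / kBT)
    w /= w.sum()
    out = []
    while len(out) < n:
        b = rng.choice(rs, size=n_bonds, p=w)
        u = rng.normal(size=(n_bonds, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pos = np.vstack([np.zeros(3), np.cumsum(u * b[:, None], axis=0)])
        e = 0.0
        for i in range(len(pos)):
            for j in range(i + 2, len(pos)):
                e += wca(float(np.linalg.norm(pos[i] - pos[j])))
        if rng.random() <= math.exp(-e / kBT):
            out.append(float(np.linalg.norm(pos[-1] - pos[0])))
    return np.array(out)


def chain_md_samples(n_steps=600_000, stride=2000, seed=3, ecd_beads=6):
    """R_e samples of a single fully flexible soluble receptor from MD."""
    from memligkin.analysis import end_to_end_samples
    from memligkin.builders import BuildRecipe, build_system
    from memligkin.dynamics import IntegratorParams, Simulation
    from memligkin.model import default_forcefield

    ff = default_forcefield(k_bend=0.0, eps_bind=14.0)
    recipe = BuildRecipe(shape="soluble", n_receptors=1, n_ligands=0,
                         ecd_beads=ecd_beads, box_height=25.0, seed=seed)
    system, topo = build_system(recipe, ff)
    sim = Simulation(system, topo, ff, IntegratorParams(seed=seed + 1))
    sim.step(5000)
    frames = []
    for _ in range(n_steps // stride):
        sim.step(stride)
        frames.append(sim.system.positions.copy())
    return end_to_end_samples(frames, topo, sim.system.box)
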