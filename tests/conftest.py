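import numpy as np
import pytest

import memligkin as mk
from memligkin.builders import BuildRecipe, build_system
from memligkin.dynamics import IntegratorParams, Simulation


@pytest.fixture(scope="session")
def ff_semirigid():
    return mk.default_forcefield(k_bend=10.0, eps_bind=14.0)


@pytest.fixture(scope="session")
def ff_rigid():
    return mk.default_forcefield(k_bend=100.0, eps_bind=14.0)


@pytest.fixture(scope="session")
def small_membrane(ff_semirigid):
    """Small quasi-planar membrane with 2 receptors and 2 ligands,
    briefly relaxed; shared by validation/force/analysis tests."""
    recipe = BuildRecipe(shape="quasi_planar", membrane_area=100.0,
                         n_receptors=2, n_ligands=2, ecd_beads=6,
                         box_height=30.0, seed=3)
    system, topology = build_system(recipe, ff_semirigid)
    sim = Simulation(system, topology, ff_semirigid,
                     IntegratorParams(dt=0.002, seed=1))
    sim.step(300)
    return sim


@pytest.fixture(scope="session")
def soluble_md_trace():
    """Equilibrium binding/unbinding trajectory of a small soluble system:
    3 receptor ectodomains + 3 ligands in a 12^3 box, sampled densely.
    The binding strength (eps_bind = 25) puts the bound-state dwell well
    above the boundary-crossing time, the regime where two-threshold
    event counting is meaningful."""
    from memligkin.workflows import equilibrate, sample_binding_trace
    ff = mk.default_forcefield(k_bend=100.0, eps_bind=25.0)
    recipe = BuildRecipe(shape="soluble", n_receptors=3, n_ligands=3,
                         ecd_beads=6, box_height=12.0, seed=9)
    system, topology = build_system(recipe, ff)
    sim = Simulation(system, topology, ff, IntegratorParams(seed=23))
    equilibrate(sim, 3000, soft_steps=1000)
    trace = sample_binding_trace(sim, 1_000_000, frame_stride=25,
                                 keep_positions=True)
    return sim, trace
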