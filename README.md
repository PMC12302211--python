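# memligkin

Coarse-grained molecular dynamics of soluble ligands binding to membrane
receptors, with maximum-likelihood estimation of the binding equilibrium
and kinetic rate constants.

## The scientific problem

Binding affinities of membrane receptors (mR) for soluble ligands (sL) are
almost always measured with the receptor's soluble ectodomain (sR) — without
the transmembrane anchor or the lipid bilayer. Whether mR–sL binding is
actually equivalent to sR–sL binding is the question this package lets you
test in silico: it simulates a generic implicit-solvent coarse-grained model
of a fluid membrane with embedded receptors and free ligands, counts
binding/unbinding events, and compares the equilibrium constant
K = k_on/k_off of the membrane system against the matched soluble reference
system (K_3D).

The model:

* **Lipids** — the three-bead implicit-solvent model (1 hydrophilic head +
  2 hydrophobic tail beads): FENE bonds (k = 30 ε₀/σ₀², r_max = 1.5 σ₀), a
  head–second-tail straightening spring (k = 10 ε₀/σ₀², r₀ = 4 σ₀), WCA
  repulsion between all beads (head diameter 0.95 σ₀, tail 1.0 σ₀), and a
  cos²-tapered tail–tail cohesion of depth 1 ε₀ whose taper width w_c
  calibrates the membrane bending rigidity κ to ≈ 13 k_BT.
* **Receptors / ligands** — linear bead chains (harmonic bonds, rest length
  0.95 σ₀) with a bending potential V(θ) = k_bend[1 − cos(θ − θ₀)], θ₀ = π;
  k_bend = 10 ε₀ (semirigid) or 100 ε₀ (rigid). A receptor adds a stiff
  3-bead transmembrane rod; the ligand is identical to the receptor's
  ectodomain. Chains of 6 / 11 beads have contour lengths 6.65 / 11.4 σ₀.
* **Specific binding** — terminal site beads of receptor and ligand attract
  through a distance- and angle-dependent potential
  E = −ε_bind·cos²θ₁·cos²θ₂·[1 − (r/r_cut)²]², active only head-on, with an
  explicit 1:1 pairing registry enforcing one ligand per receptor.

Units: σ₀ = 1 nm, ε₀ the energy unit, bead mass 1, τ₀ = σ₀√(m/ε₀);
temperature k_BT = 1.1 ε₀.

Rate constants come from maximum likelihood for a continuously observed
birth–death process R + L ⇌ RL:

    k_on  = N_bind   / ∫ n_R(t)·n_L(t)/V dt
    k_off = N_unbind / ∫ n_RL(t) dt          K = k_on/k_off

with Poisson standard errors, two-threshold (r_on < r_off) hysteresis event
detection, and delta-method errors on the membrane/soluble ratios.

## Worked example

Estimate rate constants for a small soluble system, entirely in Python:

```python
import numpy as np
from memligkin import (BuildRecipe, IntegratorParams, Simulation,
                       build_system, default_forcefield, estimate_rates)
from memligkin.workflows import equilibrate, sample_binding_trace

ff = default_forcefield(k_bend=100.0, eps_bind=14.0)
recipe = BuildRecipe(shape="soluble", n_receptors=4, n_ligands=16,
                     ecd_beads=6, box_height=21.0, seed=1)
system, topology = build_system(recipe, ff)
sim = Simulation(system, topology, ff, IntegratorParams(seed=2))
equilibrate(sim, 5000)
trace = sample_binding_trace(sim, 400_000, frame_stride=25)
est = estimate_rates(trace.to_events(r_on=1.2, r_off=2.0))
print(f"kon  = {est.kon:.2f} sigma0^3/tau0  (+- {est.se_kon:.2f})")
print(f"koff = {est.koff:.3f} 1/tau0        (+- {est.se_koff:.3f})")
print(f"K    = {est.K:.2f} sigma0^3        "
      f"({est.n_bind_events} bind / {est.n_unbind_events} unbind events)")
```

Output (seeds as shown):

```
kon  = 4.79 sigma0^3/tau0  (+- 0.59)
koff = 0.533 1/tau0        (+- 0.066)
K    = 8.98 sigma0^3        (65 bind / 65 unbind events)
```

k_on is the association rate constant per unit volumetric ligand
concentration, k_off the inverse mean bound lifetime, and K their ratio —
the volumetric binding equilibrium constant. The same pipeline applied to a
quasi-planar membrane system and divided by these reference values yields
the rescaled constants K/K_3D, k_on/k_on,3D, k_off/k_off,3D (see
`memligkin.workflows.compare_membrane_vs_soluble` or `memligkin compare`).

There is also a CLI for shell-driven pipelines:

```bash
memligkin schema                       # all config keys, units, defaults
memligkin build   --config run.toml --out system.h5 --xyz snap.xyz
memligkin run     --config run.toml --out traj.h5 --seed 1
memligkin rates   --traj traj.h5 --r-on 1.2 --r-off 2.0 --out rates.json
memligkin analyze --traj traj.h5 --what gr,re,geometry,spectrum --out out/
memligkin compare --config mem.toml --events 300 --out ratios.json
memligkin potential-scan --out tables/
```

## Layout

```
src/memligkin/
  model.py        types, reduced units, force-field registry, validation
  potentials.py   all interaction terms (numpy reference implementation)
  _kernels.py     numba hot loops (neighbor lists, forces, integrator)
  dynamics.py     BAOAB Langevin integrator, zero-tension control, checkpoints
  builders.py     bilayer/vesicle/soluble builders, protein insertion,
                  Gillespie birth-death generator
  kinetics.py     event detection, ML rate estimation, rescaling
  analysis.py     g(r), end-to-end distance, binding geometry, undulation
                  spectrum rigidity
  workflows.py    equilibration/production pipelines and studies
  io.py, cli.py   trajectory formats, TOML configs, command line
```
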