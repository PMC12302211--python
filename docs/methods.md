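# Methods

This note records the model, the numerical choices, the estimators and
the desk-scale study designs implemented in `memligkin`, including the
places where the design was genuinely open and what was decided.

## Reduced units and temperature

All quantities are in reduced units: bead diameter σ₀ = 1 (mapped to
1 nm), energy ε₀ = 1, bead mass m = 1, time τ₀ = σ₀√(m/ε₀). The thermal
energy is k_BT = 1.1 ε₀ everywhere unless stated.

## The coarse-grained model

**Lipids.** Three beads (head + two tails). Bonded terms: FENE bonds
(k = 30 ε₀/σ₀², r_max = 1.5 σ₀) between head–tail1 and tail1–tail2, and a
harmonic "straightening" spring between head and tail2 (k = 10 ε₀/σ₀²,
rest length 4 σ₀ — deliberately unreachable, which keeps the lipid
extended). Nonbonded terms: WCA repulsion between **all** bead pairs
(diameter 1.0 σ₀ if both beads are hydrophobic — tail or TMD — and
0.95 σ₀ otherwise) and a cos²-tapered cohesion between hydrophobic beads:
−ε for r < r_c = 2^{1/6} σ₀, −ε·cos²(π(r−r_c)/2w_c) out to r_c + w_c.

**Attraction-width calibration.** w_c controls the bilayer's bending
rigidity. With the spectrum estimator described below, at k_BT = 1.1:
κ(w_c = 1.5) = 7.1 ± 0.2 k_BT, κ(1.6) = 8.6 ± 1.0, κ(1.7) = 13.5 ± 1.2.
The package default is therefore **w_c = 1.7 σ₀**, the value at which the
membrane reaches the target rigidity of ≈ 13 k_BT; the equilibrium area
per lipid there is 1.135 σ₀². The calibration is exposed (`attr_wc`), not
hard-coded.

**Receptors and ligands.** Linear bead chains with harmonic bonds
(k = 100 ε₀/σ₀², rest length 0.95 σ₀) and the bending potential
V(θ) = k_bend[1 − cos(θ − θ₀)] on every consecutive triple, θ₀ = π
(straight ground state). The contour-length convention counts beads of
diameter 0.95 σ₀ including the terminal binding-site bead: a chain of n
beads + site has l = 0.95·(n+1) σ₀, so n = 6 → 6.65 σ₀ and n = 11 →
11.4 σ₀. A membrane receptor adds a 3-bead transmembrane rod (bonds
k = 1000 ε₀/σ₀², rest length 1.5 σ₀; straight angle k = 1000 ε₀ —
"rigid" realized as very stiff springs rather than rigid-body dynamics).
TMD beads feel the hydrophobic cohesion with *tail* beads only, which
anchors the rod in the bilayer core; TMD–TMD pairs do not attract —
direct rod–rod cohesion would give receptors a clustering propensity the
model must not have.

**Specific binding.** Site beads of receptor and ligand interact through

    E(r, θ₁, θ₂) = −ε_bind · cos²θ₁ · cos²θ₂ · [1 − (r/r_cut)²]²,

active for r < r_cut = 1.5 σ₀ and both angles < π/2, where θ₁/θ₂ are the
angles between each molecule's terminal-bond axis (last chain bead → site
bead) and the inter-site vector. This smooth, short-ranged, head-on form
is this package's concrete choice for the distance- and angle-dependent
binding potential; it makes (θ₁, θ₂, r) the very observables the
binding-geometry histograms report. 1:1 stoichiometry is enforced by an
explicit pairing registry: each site has at most one active partner (the
energy-minimizing candidate within r_cut, assigned greedily), and
reassignment happens only after the pair separates beyond r_cut.
Because site beads also carry WCA repulsion (all pairs repel), the
accessible well depth at contact is roughly 0.31·ε_bind; at the study
value ε_bind = 14 ε₀ this produces reversible binding with thousands of
events per 10⁴ τ₀ in small boxes.

## Dynamics

BAOAB Langevin splitting of velocity Verlet; defaults dt = 0.005 τ₀,
γ = 1 τ₀⁻¹. With γ = 0 the step reduces exactly to symplectic Verlet
(tested: secular energy drift ~10⁻⁶ relative over 10⁴ steps). The largest
production runs (binding-event harvesting, receptor g(r)) use
dt = 0.0075 τ₀, which remains stable against the stiffest (TMD) bonds
and biases both systems of a ratio identically.

Thermostat noise for step s comes from a Philox counter-based stream
(key = seed, counter word 2 = s), so trajectories are bit-reproducible,
restart-exact, and independent of vectorization order. Checkpoints store
the complete mutable state (including the pairing registry and the
tension accumulator) with a SHA-256 checksum.

Neighbor search: linked-cell builds of a Verlet pair list (skin 0.4 σ₀,
rebuild when any bead has moved half a skin) with per-pair-type list
cutoffs — the long cohesion range only applies to hydrophobic pairs. The
cell-list forces equal the brute-force all-pairs reference to ~10⁻¹²
relative (tested on random configurations and after long runs).

**Zero-tension control.** The lateral (surface) tension
Σ = L_z(P_N − P_L) is accumulated from the kinetic + virial pressure
tensor; every 50 steps the lateral box is rescaled affinely by
1 − min(|g·Σ̄|, 10⁻⁴) toward zero mean tension (Berendsen-style; not a
barostat ensemble). Production phases freeze the box so the volume in the
concentration convention is constant; the spectrum fit absorbs the small
residual tension (below).

## Builders

Planar bilayers: two staggered-lattice leaflets, head-to-head thickness
4.7 σ₀, lipid count 2·round(area/area-per-lipid) with build-time area per
lipid 1.2 σ₀² (tension control relaxes it to equilibrium). Vesicles: two
Fibonacci-sphere leaflets with lipid numbers proportional to the leaflet
mid-surface areas at R ± t/2 (no built-in tension). Proteins are inserted
by rejection sampling (min site–site spacing 3 σ₀, min bead distance
0.85 σ₀); lipids overlapping a transmembrane rod are removed. Ligands go
into the solvent slab (planar; the slab is one connected compartment
through the periodic z boundary) or the vesicle exterior. All builders
are deterministic per seed and validated structurally.

## Event detection and rate estimation

A receptor–ligand site pair becomes bound when its distance first drops
below r_on = 1.2 σ₀ and unbound when it first exceeds r_off = 2.0 σ₀
(hysteresis suppresses recrossing flicker; see "Threshold sensitivity"
below for how the estimated k_off depends on r_off). Frames are treated as
continuous observation (trapezoidal integrals). The ML estimators for the
continuously observed birth–death process are k_on = N_b/∫n_R n_L/V dt
and k_off = N_u/∫n_RL dt with Poisson standard errors √N/∫ and a
delta-method error on K = k_on/k_off; membrane/soluble ratios propagate
errors in quadrature. A stationary block bootstrap is available for
correlated traces.

**Volume convention.** Concentrations use the full box volume in both
system types, so K carries volume units in both and the ratios are
dimensionless. In membrane boxes the bilayer slab (≈ 4.7·A) is excluded
from the ligand-accessible volume, which inflates the membrane-side k_on
and K by ≈ V_box/V_solvent; box heights are chosen (≥ 42 σ₀) to keep
this systematic near 10%, inside the comparison's 20% band.

## Undulation spectrum and rigidity

For a tensionless membrane in k_BT units, ⟨|h_q|²⟩ = 1/(A κ q⁴) (FFT/N
amplitude convention). Two estimator paths:

* **Dense surfaces** (synthetic oracle): gridded height field + FFT, with
  deconvolution of the cell-average pixel window; recovery of κ = 13 on
  synthetic q⁻⁴ surfaces is within a few percent and independent of grid
  spacing between ~0.5 and ~2 σ₀.
* **Membrane frames**: direct nonuniform Fourier sums over head beads,
  leaflet-resolved (a lipid is assigned by its own head-above-tail
  orientation; mixing leaflets would alias the ±2.35 σ₀ head offsets into
  noise). The reported spectrum is the **cross**-spectrum of two
  alternating half-samples of the heads: the finite-sampling white-noise
  floor (which otherwise exceeds the q⁻⁴ signal severalfold in the upper
  fit window) is independent between halves and cancels.

The inverse spectrum is fitted as 1/(A q² S) = σ + κ q² (weighted, two
passes), yielding the rigidity κ and the residual frame tension σ
jointly, so imperfect tension relaxation does not bias κ. The fit window
is q ≤ 1.0 σ₀⁻¹ for membrane data (bending dominates; protrusion modes
and statistical noise contaminate higher q — κ moves < 15% between
windows 0.9–1.26), and flat input is flagged as the rigid limit.

## What the synthetic generators emulate

* `gillespie_birth_death` is the exact stochastic simulation of
  R + L ⇌ RL with mass-action propensities — the independent oracle for
  the ML estimators (bias < 2% at ~5000 events, error bars calibrated
  within 25%). It has exponential waiting times and no spatial structure,
  so it validates the estimator, not diffusion physics.
* `synthetic_undulation_frames` draws Gaussian surfaces with exactly the
  q⁻⁴ spectrum — it validates the spectrum estimator's conventions and
  fit, not membrane dynamics.
* The chain-sampling oracle (tests) draws freely jointed directions with
  the model's bond-length distribution and re-weights by the non-adjacent
  excluded-volume energy — the exact equilibrium distribution of a free
  chain at k_bend = 0. Note the chain is *self-avoiding* (all bead pairs
  repel), so its end-to-end distribution differs strongly from an ideal
  freely jointed chain; the tests compare against the exact oracle.

Passing these tests shows the estimators and samplers are correct for
the model as defined; none of the generators emulate hydrodynamics,
explicit solvent, lipid mixtures or receptor clustering.

## Desk-scale study designs

The headline comparisons are statistical properties of large
simulations; this package runs them at sizes a single CPU handles in
minutes, with all force-field parameters at the study values
(ε_bind = 14 ε₀, k_bend = 100 ε₀, k_BT = 1.1 ε₀):

* **Membrane vs soluble** (`compare_membrane_vs_soluble`): quasi-planar
  membrane of 240 lipids (144 σ₀²) with 2 receptors + 36 ligands in a
  42 σ₀-tall box, against 2 ectodomains + 36 ligands in a 21³ σ₀³ box;
  ≥ 300 bind+unbind events per system, dt = 0.0075. Receptor surface
  density matters: at ~4 receptors per 100 σ₀² the membrane k_on is
  inflated ~1.7× by ligand rebinding to neighboring receptors — a
  crowding effect absent in dilute systems — so the study uses the
  lowest density the budget allows (2 per 144 σ₀²). Across seeds and
  ligand counts the rescaled constants land between ≈ 0.85 and ≈ 1.6;
  the Poisson standard errors understate this run-to-run scatter because
  rebinding makes successive events correlated (the block bootstrap in
  `memligkin.kinetics` quantifies this on a given trace). Together with
  the ≈ +10% volume systematic, a desk-scale run should be read as
  K/K_3D = 1 within a few tens of percent, which is the scaled version
  of the large-system statement.
* **Rigidity**: 326-lipid patch (196 σ₀²), 50k-step tensionless
  equilibration, 700 frames every 200 steps, (σ, κ) spectrum fit.
* **Receptor g(r)**: 540-lipid patch (324 σ₀²), 6 semirigid receptors of
  contour l = 6.65 σ₀, no ligands, 300 frames every 250 steps. The
  measured depletion (g ≈ 0.34 at contact, unity by r ≈ 4–5 σ₀) spans
  ~0.6–0.9·l; the periodic box compresses the depletion tail, so the
  larger-system crossover of ~1.5·l (≈ 10 σ₀) is not reached at this
  scale.

**Threshold sensitivity of k_off.** Because the angular alignment
factors cap the realized well depth at a few k_BT (increasing ε_bind
from 14 to 25 only doubles K — confirmed against the independent
Boltzmann quadrature, so this is the model, not the code), bound
intervals are short and part of each interval is diffusive lingering in
the hysteresis band. Estimated k_off therefore decreases smoothly by
~35–50% as r_off spans 1.8–2.5 σ₀ — not the <10% characteristic of
deep-well binders. Since both systems of a ratio are measured with the
same thresholds, this does not bias the membrane/soluble comparison.

## Known limitations

* The binding potential is this package's own concrete functional form
  for a "distance- and angle-dependent" site–site attraction; binding
  *geometry* histograms are therefore internally consistent but not
  quantitative predictions for any particular experimental pair.
* Because all bead pairs repel, the effective binding well is much
  shallower than ε_bind; absolute K values are model-specific. The
  membrane/soluble *ratios* are the meaningful observable.
* Rigidity estimation is planar-only (no spherical-harmonic analysis for
  vesicles); supported membranes are excluded from spectrum fits.
* No hydrodynamics (Langevin friction is local), no electrostatics, no
  lipid mixtures, no receptor clustering interactions.
* At the scaled receptor densities, residual neighbor-rebinding can bias
  k_on upward by O(10%); the scaled membrane boxes also carry an O(10%)
  ligand-accessible-volume systematic. Both shrink with system size.
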