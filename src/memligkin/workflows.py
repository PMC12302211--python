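"""High-level pipelines: equilibrate a built system, sample binding event
traces, and run the matched membrane-vs-soluble comparison that rescales
the membrane rate constants by the soluble-reference (3D) constants."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import (
    PairCorrelationResult,
    SpectrumResult,
    pair_correlation_2d,
    undulation_spectrum,
)
from .builders import BuildRecipe, build_planar_bilayer, build_system
from .dynamics import IntegratorParams, Simulation
from .kinetics import (
    EventTrace,
    RateEstimate,
    RateRatios,
    detect_events,
    estimate_rates,
    rescale_against_reference,
    site_distances,
)
from .model import ForceField


def make_simulation(recipe: BuildRecipe, ff: ForceField,
                    params: IntegratorParams | None = None) -> Simulation:
    if params is None:
        params = IntegratorParams(kBT=recipe.kBT, seed=recipe.seed)
    system, topology = build_system(recipe, ff)
    return Simulation(system, topology, ff, params)


def equilibrate(sim: Simulation, n_steps: int = 5000,
                soft_steps: int = 2000) -> None:
    """Relax a freshly built system: short small-dt phase to release build
    artifacts, then full-dt equilibration (with tension control if the
    integrator parameters enable it)."""
    dt = sim.params.dt
    tension = sim.params.tension_control
    sim.params.dt = min(dt, 0.002)
    sim.params.tension_control = "off"
    sim.step(soft_steps)
    sim.params.dt = dt
    sim.params.tension_control = tension
    sim.step(n_steps)


@dataclass
class BindingTrace:
    """Frame-sampled site-distance record of one production run."""

    times: np.ndarray
    distances: np.ndarray          # (M, nR, nL)
    volume: float
    positions: np.ndarray | None   # (M, N, 3) if requested
    box_lengths: np.ndarray

    def to_events(self, r_on: float = 1.2, r_off: float = 2.0) -> EventTrace:
        return detect_events(self.times, self.distances, r_on, r_off,
                             self.volume)


def sample_binding_trace(sim: Simulation, n_steps: int,
                         frame_stride: int = 50,
                         min_events: int = 0, max_steps: int | None = None,
                         r_on: float = 1.2, r_off: float = 2.0,
                         keep_positions: bool = False) -> BindingTrace:
    """Run production and record site-site distances every ``frame_stride``.

    Runs at least ``n_steps``; if ``min_events`` > 0, keeps extending the
    run (up to ``max_steps``) until the hysteresis detector has seen that
    many bind + unbind events.
    """
    topo = sim.topology
    times = [sim.system.time]
    dists = [site_distances(sim.system, topo)]
    frames = [sim.system.positions.copy()] if keep_positions else None
    steps_done = 0
    if max_steps is None:
        max_steps = n_steps
    while True:
        sim.step(frame_stride)
        steps_done += frame_stride
        times.append(sim.system.time)
        dists.append(site_distances(sim.system, topo))
        if keep_positions:
            frames.append(sim.system.positions.copy())
        if steps_done >= n_steps:
            if min_events <= 0 or steps_done >= max_steps:
                break
            if steps_done % (200 * frame_stride) < frame_stride:
                trace = detect_events(np.array(times), np.array(dists),
                                      r_on, r_off, sim.system.box.volume)
                if trace.n_bind_events + trace.n_unbind_events >= min_events:
                    break
    return BindingTrace(np.array(times), np.array(dists),
                        sim.system.box.volume,
                        np.array(frames) if keep_positions else None,
                        sim.system.box.lengths.copy())


@dataclass
class ComparisonResult:
    """Matched membrane-vs-soluble rate comparison (the central readout)."""

    membrane: RateEstimate
    soluble: RateEstimate
    ratios: RateRatios
    membrane_events: int
    soluble_events: int

    def to_dict(self) -> dict:
        r = self.ratios
        return {
            "K_ratio": r.K_ratio, "se_K_ratio": r.se_K_ratio,
            "kon_ratio": r.kon_ratio, "se_kon_ratio": r.se_kon_ratio,
            "koff_ratio": r.koff_ratio, "se_koff_ratio": r.se_koff_ratio,
            "membrane": _est_dict(self.membrane),
            "soluble": _est_dict(self.soluble),
        }


def _est_dict(e: RateEstimate) -> dict:
    return {"kon": e.kon, "koff": e.koff, "K": e.K,
            "se_kon": e.se_kon, "se_koff": e.se_koff, "se_K": e.se_K,
            "n_bind_events": e.n_bind_events,
            "n_unbind_events": e.n_unbind_events}


def compare_membrane_vs_soluble(
        membrane_recipe: BuildRecipe, soluble_recipe: BuildRecipe,
        ff: ForceField, seed: int = 0,
        min_events: int = 300, n_steps: int = 200_000,
        max_steps: int = 2_000_000, frame_stride: int = 25,
        equilibration_steps: int = 10_000,
        r_on: float = 1.2, r_off: float = 2.0,
        dt: float = 0.005) -> ComparisonResult:
    """Build, equilibrate and sample both systems; estimate and rescale.

    The membrane is equilibrated under zero-tension control; production
    runs with the box frozen so the volume entering the concentration
    convention is constant.
    """
    results = {}
    for label, recipe in (("membrane", membrane_recipe),
                          ("soluble", soluble_recipe)):
        params = IntegratorParams(kBT=recipe.kBT, seed=seed + recipe.seed,
                                  dt=dt)
        if recipe.shape in ("quasi_planar", "supported"):
            params.tension_control = "zero_tension"
        sim = make_simulation(recipe, ff, params)
        equilibrate(sim, equilibration_steps)
        sim.params.tension_control = "off"
        trace = sample_binding_trace(
            sim, n_steps, frame_stride, min_events=min_events,
            max_steps=max_steps, r_on=r_on, r_off=r_off)
        results[label] = trace.to_events(r_on, r_off)
    est_m = estimate_rates(results["membrane"])
    est_s = estimate_rates(results["soluble"])
    ratios = rescale_against_reference(est_m, est_s)
    return ComparisonResult(
        est_m, est_s, ratios,
        est_m.n_bind_events + est_m.n_unbind_events,
        est_s.n_bind_events + est_s.n_unbind_events)


def rigidity_study(area: float = 256.0, seed: int = 0,
                   ff: ForceField | None = None,
                   equilibration_steps: int = 80_000,
                   n_frames: int = 1000, frame_stride: int = 200,
                   fit_q_max: float = 1.0) -> SpectrumResult:
    """Bending rigidity of a tensionless quasi-planar patch.

    Builds a protein-free bilayer, relaxes it to zero lateral tension,
    then samples undulation frames with the box frozen and fits the
    (sigma, kappa) spectrum.  The fit window is kept below q = 1 sigma0^-1
    where the q^-4 bending signal dominates protrusion noise.
    """
    from .model import default_forcefield
    if ff is None:
        ff = default_forcefield(k_bend=100.0, eps_bind=14.0)
    system, topology = build_planar_bilayer(area, box_height=24.0,
                                            seed=seed)
    sim = Simulation(system, topology, ff,
                     IntegratorParams(seed=seed + 1,
                                      tension_control="zero_tension"))
    equilibrate(sim, equilibration_steps, soft_steps=3000)
    sim.params.tension_control = "off"
    frames = []
    for _ in range(n_frames):
        sim.step(frame_stride)
        frames.append(sim.system.positions.copy())
    return undulation_spectrum(frames, sim.system.box, topology=topology,
                               fit_q_max=fit_q_max)


def receptor_gr_study(area: float = 400.0, n_receptors: int = 6,
                      ecd_beads: int = 6, k_bend: float = 10.0,
                      seed: int = 0,
                      equilibration_steps: int = 30_000,
                      n_frames: int = 600, frame_stride: int = 250,
                      bins: int = 20, dt: float = 0.005
                      ) -> PairCorrelationResult:
    """In-plane pair correlation g(r) of membrane-receptor binding sites.

    Receptors diffuse freely in a tensionless quasi-planar membrane
    (no ligands: the unbound state); site positions are sampled and the
    x-y projected g(r) is accumulated.
    """
    from .model import default_forcefield
    ff = default_forcefield(k_bend=k_bend, eps_bind=14.0)
    recipe = BuildRecipe(shape="quasi_planar", membrane_area=area,
                         n_receptors=n_receptors, n_ligands=0,
                         ecd_beads=ecd_beads, box_height=30.0, seed=seed)
    params = IntegratorParams(seed=seed + 1, dt=dt,
                              tension_control="zero_tension")
    sim = make_simulation(recipe, ff, params)
    equilibrate(sim, equilibration_steps)
    sim.params.tension_control = "off"
    frames = []
    for _ in range(n_frames):
        sim.step(frame_stride)
        frames.append(sim.system.positions.copy())
    return pair_correlation_2d(frames, sim.topology.site_r_indices,
                               sim.system.box, bins=bins)
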