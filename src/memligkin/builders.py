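"""System construction: planar/supported bilayers, vesicles, soluble boxes,
protein insertion, and the Gillespie birth-death event generator used as
the independent oracle for the rate estimators.

Geometry conventions (sigma0): head-to-head bilayer thickness 4.7, lipid
bead spacing 0.95 along the lipid axis, fluid-phase area per lipid 1.2,
protein bond rest length 0.95.  Builders are deterministic for a fixed
seed; different seeds change protein placement but never bead counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dynamics import assign_velocities
from .kinetics import EventTrace
from .model import (
    ANGLE_PROTEIN,
    ANGLE_TMD,
    BOND_FENE,
    BOND_HARMONIC,
    BOND_LIPID_SPRING,
    BOND_TMD,
    Box,
    ECD,
    ForceField,
    HEAD,
    Ligand,
    ParticleSystem,
    Receptor,
    SITE_L,
    SITE_R,
    TAIL,
    TMD,
    Topology,
)

BILAYER_THICKNESS = 4.7       # head-to-head, sigma0
LIPID_BEAD_SPACING = 0.95
MIN_BUILD_DISTANCE = 0.85     # overlap guard during insertion
MEMBRANE_SLAB_MARGIN = 4.5    # half-thickness of the excluded slab for ligands
MIN_SITE_SPACING = 3.0        # receptor site-site rejection distance
MAX_INSERT_ATTEMPTS = 100_000


class InsertionError(RuntimeError):
    """Rejection sampling failed to place a molecule without overlap."""


class GeometryError(ValueError):
    """Requested geometry is too small to build."""


@dataclass
class BuildRecipe:
    """Everything needed to construct one simulated system."""

    shape: str = "quasi_planar"   # quasi_planar | supported | vesicle | soluble
    membrane_area: float = 270.0  # sigma0^2 (planar shapes)
    vesicle_radius: float = 15.0  # sigma0 (vesicle shape)
    n_receptors: int = 0
    n_ligands: int = 0
    ecd_beads: int = 6            # chain beads per protein (site bead extra)
    box_height: float = 30.0      # sigma0; soluble: cubic box edge
    area_per_lipid: float = 1.2   # sigma0^2
    seed: int = 0
    kBT: float = 1.1

    def __post_init__(self) -> None:
        if self.shape not in ("quasi_planar", "supported", "vesicle", "soluble"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_receptors < 0 or self.n_ligands < 0:
            raise ValueError("protein counts must be non-negative")
        if self.ecd_beads < 2:
            raise ValueError("need at least 2 chain beads per protein")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# membrane builders
# ---------------------------------------------------------------------------

def _lipid_bonds(i0: int) -> list[tuple[int, int, int]]:
    """head-tail1 FENE, tail1-tail2 FENE, head-tail2 straightening spring."""
    return [(i0, i0 + 1, BOND_FENE), (i0 + 1, i0 + 2, BOND_FENE),
            (i0, i0 + 2, BOND_LIPID_SPRING)]


def planar_lipid_count(area: float, area_per_lipid: float = 1.2) -> int:
    """Total lipid count of a planar bilayer: 2*round(area/area_per_lipid)."""
    return 2 * int(round(area / area_per_lipid))


def vesicle_lipid_count(radius: float, area_per_lipid: float = 1.2,
                        thickness: float = BILAYER_THICKNESS) -> tuple[int, int]:
    """(outer, inner) leaflet lipid counts, proportional to the leaflet
    mid-surface areas at R +- t/2."""
    t = thickness
    n_out = int(round(4.0 * math.pi * (radius + t / 2.0) ** 2 / area_per_lipid))
    n_in = int(round(4.0 * math.pi * (radius - t / 2.0) ** 2 / area_per_lipid))
    return n_out, n_in


def build_planar_bilayer(area: float, area_per_lipid: float = 1.2,
                         box_height: float = 30.0, seed: int = 0,
                         kBT: float = 1.1, supported: bool = False
                         ) -> tuple[ParticleSystem, Topology]:
    """Two flat leaflets on a staggered lattice spanning x-y, tails inward.

    The lipid count is 2*round(area / area_per_lipid); the box is
    sqrt(area) x sqrt(area) x box_height with the bilayer midplane at
    box_height/2.
    """
    if area < 100.0:
        raise GeometryError(f"membrane area {area} < 100 sigma0^2")
    L = math.sqrt(area)
    n_leaf = planar_lipid_count(area, area_per_lipid) // 2
    nx = max(1, int(math.ceil(math.sqrt(n_leaf))))
    ny = max(1, int(math.ceil(n_leaf / nx)))
    z0 = box_height / 2.0
    dz = LIPID_BEAD_SPACING
    z_head = BILAYER_THICKNESS / 2.0

    positions = []
    types = []
    lipids = []
    bonds = []
    for leaflet, sign in ((0, +1.0), (1, -1.0)):
        placed = 0
        for j in range(ny):
            for i in range(nx):
                if placed >= n_leaf:
                    break
                x = (i + 0.5 + 0.25 * (j % 2) + 0.33 * leaflet) * L / nx
                y = (j + 0.5 + 0.33 * leaflet) * L / ny
                i0 = len(positions)
                positions.append([x % L, y % L, z0 + sign * z_head])
                positions.append([x % L, y % L, z0 + sign * (z_head - dz)])
                positions.append([x % L, y % L, z0 + sign * (z_head - 2 * dz)])
                types += [HEAD, TAIL, TAIL]
                lipids.append([i0, i0 + 1, i0 + 2])
                bonds += _lipid_bonds(i0)
                placed += 1
    positions = np.array(positions)
    box = Box([L, L, box_height])
    system = ParticleSystem(box.wrap(positions), np.zeros_like(positions),
                            np.array(types), box)
    topology = Topology(lipids=np.array(lipids), bonds=np.array(bonds),
                        shape="supported" if supported else "quasi_planar")
    if supported:
        # pin lower-leaflet heads to their build plane
        heads = topology.lipids[:, 0]
        lower = heads[system.positions[heads, 2] < z0]
        topology.restrained = lower
        topology.restraint_z0 = z0 - z_head
    assign_velocities(system, kBT, seed)
    return system, topology


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly distributed unit vectors."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_vesicle(radius: float, area_per_lipid: float = 1.2,
                  box_margin: float = 8.0, seed: int = 0, kBT: float = 1.1
                  ) -> tuple[ParticleSystem, Topology]:
    """Two concentric spherical leaflets, heads outward/inward.

    Leaflet lipid numbers are proportional to the leaflet mid-surface
    areas at R +- t/2 (t = 4.7), which builds in no tension.
    """
    t = BILAYER_THICKNESS
    if radius < 8.0:
        raise GeometryError(f"vesicle radius {radius} < 8 sigma0")
    n_out, n_in = vesicle_lipid_count(radius, area_per_lipid)
    L = 2.0 * (radius + t / 2.0 + box_margin)
    center = np.array([L / 2.0] * 3)
    dz = LIPID_BEAD_SPACING
    z_head = t / 2.0

    positions = []
    types = []
    lipids = []
    bonds = []
    for n_leaf, sign in ((n_out, +1.0), (n_in, -1.0)):
        dirs = fibonacci_sphere(n_leaf)
        for u in dirs:
            i0 = len(positions)
            for k in range(3):
                rr = radius + sign * (z_head - k * dz)
                positions.append(center + rr * u)
            types += [HEAD, TAIL, TAIL]
            lipids.append([i0, i0 + 1, i0 + 2])
            bonds += _lipid_bonds(i0)
    positions = np.array(positions)
    box = Box([L, L, L])
    system = ParticleSystem(box.wrap(positions), np.zeros_like(positions),
                            np.array(types), box)
    topology = Topology(lipids=np.array(lipids), bonds=np.array(bonds),
                        shape="vesicle")
    assign_velocities(system, kBT, seed)
    return system, topology


def build_soluble_box(box_length: float = 30.0, kBT: float = 1.1,
                      seed: int = 0) -> tuple[ParticleSystem, Topology]:
    """Empty periodic cube for the soluble reference system."""
    box = Box([box_length] * 3)
    system = ParticleSystem(np.zeros((0, 3)), np.zeros((0, 3)),
                            np.zeros(0, dtype=np.int8), box)
    return system, Topology(lipids=np.zeros((0, 3)), shape="soluble")


# ---------------------------------------------------------------------------
# protein insertion
# ---------------------------------------------------------------------------

def _protein_chain_coords(start: np.ndarray, direction: np.ndarray,
                          n_chain: int, spacing: float) -> np.ndarray:
    """Chain beads + site bead from ``start`` along ``direction``."""
    steps = np.arange(n_chain + 1)[:, None]
    return start[None, :] + steps * spacing * direction[None, :]


def _receptor_entities(chain_xyz: np.ndarray, tmd_xyz: np.ndarray,
                       i0: int) -> tuple[Receptor, list, list, np.ndarray, list]:
    """Index bookkeeping for one receptor appended at global offset i0."""
    n_tmd = len(tmd_xyz)
    n_chain = len(chain_xyz) - 1  # last row is the site bead
    tmd_idx = np.arange(i0, i0 + n_tmd)
    ecd_idx = np.arange(i0 + n_tmd, i0 + n_tmd + n_chain)
    site_idx = i0 + n_tmd + n_chain
    rec = Receptor(tmd_idx, ecd_idx, site_idx)
    types = [TMD] * n_tmd + [ECD] * n_chain + [SITE_R]
    seq = list(tmd_idx) + list(ecd_idx) + [site_idx]
    bonds = []
    for a, b in zip(seq[:-1], seq[1:]):
        kind = BOND_TMD if (a in tmd_idx[:-1] and b in tmd_idx) else BOND_HARMONIC
        bonds.append((a, b, kind))
    angles = []
    for a, b, c in zip(seq[:-2], seq[1:-1], seq[2:]):
        kind = ANGLE_TMD if c in tmd_idx else ANGLE_PROTEIN
        angles.append((a, b, c, kind))
    xyz = np.vstack([tmd_xyz, chain_xyz]) if n_tmd else chain_xyz
    return rec, bonds, angles, xyz, types


def _ligand_entities(chain_xyz: np.ndarray, i0: int):
    n_chain = len(chain_xyz) - 1
    chain_idx = np.arange(i0, i0 + n_chain)
    site_idx = i0 + n_chain
    lig = Ligand(chain_idx, site_idx)
    types = [ECD] * n_chain + [SITE_L]
    seq = list(chain_idx) + [site_idx]
    bonds = [(a, b, BOND_HARMONIC) for a, b in zip(seq[:-1], seq[1:])]
    angles = [(a, b, c, ANGLE_PROTEIN)
              for a, b, c in zip(seq[:-2], seq[1:-1], seq[2:])]
    return lig, bonds, angles, chain_xyz, types


def _remove_lipids_near(system: ParticleSystem, topology: Topology,
                        points: np.ndarray, cutoff: float = 1.2) -> None:
    """Delete lipids with any bead within ``cutoff`` of any given point
    (carving space for a transmembrane rod).  Re-indexes everything."""
    if len(topology.lipids) == 0 or len(points) == 0:
        return
    pos = system.positions
    box = system.box
    doomed = []
    for li, trip in enumerate(topology.lipids):
        dv = box.min_image(
            (pos[trip][:, None, :] - points[None, :, :]).reshape(-1, 3))
        if np.any(np.linalg.norm(dv, axis=1) < cutoff):
            doomed.append(li)
    if not doomed:
        return
    dead_beads = sorted(int(b) for li in doomed for b in topology.lipids[li])
    keep = np.ones(system.n_beads, dtype=bool)
    keep[dead_beads] = False
    remap = np.cumsum(keep) - 1
    system.positions = system.positions[keep]
    system.velocities = system.velocities[keep]
    system.bead_types = system.bead_types[keep]
    kept_lipids = [topology.lipids[li] for li in range(len(topology.lipids))
                   if li not in set(doomed)]
    topology.lipids = (remap[np.array(kept_lipids)] if kept_lipids
                       else np.zeros((0, 3), dtype=np.int64))
    dead = set(dead_beads)
    topology.bonds = np.array(
        [(remap[i], remap[j], k) for (i, j, k) in topology.bonds
         if i not in dead and j not in dead], dtype=np.int64).reshape(-1, 3)
    topology.angles = np.array(
        [(remap[i], remap[j], remap[k], kk) for (i, j, k, kk) in topology.angles
         if i not in dead and j not in dead and k not in dead],
        dtype=np.int64).reshape(-1, 4)
    if len(topology.restrained):
        topology.restrained = remap[
            topology.restrained[~np.isin(topology.restrained, dead_beads)]]
    for r in topology.receptors:
        r.tmd = remap[r.tmd]
        r.ecd = remap[r.ecd]
        r.site = int(remap[r.site])
    for l in topology.ligands:
        l.chain = remap[l.chain]
        l.site = int(remap[l.site])


def _append_molecules(system: ParticleSystem, topology: Topology,
                      new_xyz: list, new_types: list, new_bonds: list,
                      new_angles: list, new_receptors: list,
                      new_ligands: list, kBT: float, seed: int) -> None:
    if not new_xyz:
        return
    xyz = system.box.wrap(np.vstack(new_xyz))
    rng = np.random.default_rng(seed + 7919)
    vel = rng.normal(0.0, math.sqrt(kBT), size=xyz.shape)
    system.positions = np.vstack([system.positions, xyz])
    system.velocities = np.vstack([system.velocities, vel])
    system.bead_types = np.concatenate(
        [system.bead_types, np.array(new_types, dtype=np.int8)])
    topology.receptors.extend(new_receptors)
    topology.ligands.extend(new_ligands)
    if new_bonds:
        topology.bonds = np.vstack(
            [topology.bonds, np.array(new_bonds, dtype=np.int64)])
    if new_angles:
        topology.angles = np.vstack(
            [topology.angles, np.array(new_angles, dtype=np.int64)])


def insert_proteins(system: ParticleSystem, topology: Topology,
                    recipe: BuildRecipe, ff: ForceField
                    ) -> tuple[ParticleSystem, Topology]:
    """Place receptors (TMD spanning the bilayer for membrane shapes) and
    ligands (uniform in the solvent region) by rejection sampling.

    Receptors keep a minimum site-site spacing of 3 sigma0; every new bead
    keeps at least 0.85 sigma0 from all existing beads.  Lipids overlapping
    a transmembrane rod are removed.
    """
    rng = np.random.default_rng(recipe.seed)
    box = system.box
    L = box.lengths
    b0 = ff.bond_r0
    n_chain = recipe.ecd_beads
    shape = recipe.shape
    z0 = L[2] / 2.0
    center = L / 2.0

    # --- receptors ---------------------------------------------------------
    new_xyz, new_types, new_bonds, new_angles = [], [], [], []
    new_receptors, new_ligands = [], []
    site_positions = []
    tmd_points = []
    i0 = system.n_beads

    for _ in range(recipe.n_receptors):
        for attempt in range(MAX_INSERT_ATTEMPTS):
            if shape in ("quasi_planar", "supported"):
                xy = rng.uniform(0.0, [L[0], L[1]])
                axis = np.array([0.0, 0.0, 1.0])
                tmd_xyz = np.array([[xy[0], xy[1], z0 + s * ff.tmd_bond_r0]
                                    for s in (-1.0, 0.0, 1.0)])
                start = np.array([xy[0], xy[1], z0 + ff.tmd_bond_r0 + b0])
            elif shape == "vesicle":
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                axis = u
                tmd_xyz = np.array([
                    center + (recipe.vesicle_radius + s * ff.tmd_bond_r0) * u
                    for s in (-1.0, 0.0, 1.0)])
                start = center + (recipe.vesicle_radius
                                  + ff.tmd_bond_r0 + b0) * u
            else:  # soluble: ectodomain only, free in the box
                start = rng.uniform(0.0, L)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                tmd_xyz = np.zeros((0, 3))
            chain_xyz = _protein_chain_coords(start, axis, n_chain, b0)
            site = chain_xyz[-1]
            ok = True
            for sp in site_positions:
                if np.linalg.norm(box.min_image(site - sp)) < MIN_SITE_SPACING:
                    ok = False
                    break
            if ok and shape == "soluble":
                ok = _clear_of_existing(system, new_xyz, chain_xyz, box)
            if ok:
                break
        else:
            raise InsertionError(
                f"receptor insertion failed after {MAX_INSERT_ATTEMPTS} attempts")
        rec, bonds, angles, xyz, types = _receptor_entities(
            chain_xyz, tmd_xyz, i0)
        new_xyz.append(xyz)
        new_types += types
        new_bonds += bonds
        new_angles += angles
        new_receptors.append(rec)
        site_positions.append(site)
        tmd_points.extend(tmd_xyz)
        i0 += len(xyz)

    # carve lipids away from the transmembrane rods, then re-index and append
    if tmd_points:
        _remove_lipids_near(system, topology, np.array(tmd_points))
        offset = system.n_beads - (i0 - sum(len(x) for x in new_xyz))
        for rec in new_receptors:
            rec.tmd = rec.tmd + offset
            rec.ecd = rec.ecd + offset
            rec.site += offset
        new_bonds = [(i + offset, j + offset, k) for (i, j, k) in new_bonds]
        new_angles = [(i + offset, j + offset, k + offset, kk)
                      for (i, j, k, kk) in new_angles]
        i0 = system.n_beads + sum(len(x) for x in new_xyz)

    # --- ligands -----------------------------------------------------------
    for _ in range(recipe.n_ligands):
        for attempt in range(MAX_INSERT_ATTEMPTS):
            start = rng.uniform(0.0, L)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            chain_xyz = _protein_chain_coords(start, axis, n_chain, b0)
            if not _in_solvent_region(chain_xyz, shape, z0, center,
                                      recipe.vesicle_radius, L):
                continue
            if _clear_of_existing(system, new_xyz, chain_xyz, box):
                break
        else:
            raise InsertionError(
                f"ligand insertion failed after {MAX_INSERT_ATTEMPTS} attempts")
        lig, bonds, angles, xyz, types = _ligand_entities(chain_xyz, i0)
        new_xyz.append(xyz)
        new_types += types
        new_bonds += bonds
        new_angles += angles
        new_ligands.append(lig)
        i0 += len(xyz)

    _append_molecules(system, topology, new_xyz, new_types, new_bonds,
                      new_angles, new_receptors, new_ligands,
                      recipe.kBT, recipe.seed)
    return system, topology


def _in_solvent_region(chain_xyz: np.ndarray, shape: str, z0: float,
                       center: np.ndarray, radius: float,
                       L: np.ndarray) -> bool:
    if shape in ("quasi_planar", "supported"):
        z = chain_xyz[:, 2] % L[2]
        return bool(np.all(np.abs(z - z0) > MEMBRANE_SLAB_MARGIN))
    if shape == "vesicle":
        rr = np.linalg.norm(chain_xyz - center, axis=1)
        return bool(np.all(rr > radius + BILAYER_THICKNESS / 2.0 + 1.0)
                    and np.all(chain_xyz >= 0.0)
                    and np.all(chain_xyz <= L))
    return True


def _clear_of_existing(system: ParticleSystem, new_xyz: list,
                       candidate: np.ndarray, box) -> bool:
    """True if candidate beads keep MIN_BUILD_DISTANCE from all beads."""
    others = [system.positions] + [np.asarray(x) for x in new_xyz]
    existing = np.vstack(others) if others else np.zeros((0, 3))
    if len(existing) == 0:
        return True
    wrapped = box.wrap(candidate)
    if np.all(box.periodic):
        tree = cKDTree(box.wrap(existing), boxsize=box.lengths)
        d, _ = tree.query(wrapped, k=1)
        return bool(np.min(d) >= MIN_BUILD_DISTANCE)
    for c in wrapped:
        dv = box.min_image(existing - c)
        if np.min(np.linalg.norm(dv, axis=1)) < MIN_BUILD_DISTANCE:
            return False
    return True


def build_system(recipe: BuildRecipe, ff: ForceField
                 ) -> tuple[ParticleSystem, Topology]:
    """One-stop builder: membrane (or empty box) + proteins per the recipe."""
    if recipe.shape in ("quasi_planar", "supported"):
        system, topology = build_planar_bilayer(
            recipe.membrane_area, recipe.area_per_lipid, recipe.box_height,
            recipe.seed, recipe.kBT, supported=(recipe.shape == "supported"))
    elif recipe.shape == "vesicle":
        system, topology = build_vesicle(
            recipe.vesicle_radius, recipe.area_per_lipid,
            seed=recipe.seed, kBT=recipe.kBT)
    else:
        system, topology = build_soluble_box(
            recipe.box_height, recipe.kBT, recipe.seed)
    return insert_proteins(system, topology, recipe, ff)


# ---------------------------------------------------------------------------
# Gillespie birth-death oracle
# ---------------------------------------------------------------------------

def gillespie_birth_death(kon: float, koff: float, nR0: int, nL0: int,
                          V: float, t_end: float, seed: int = 0
                          ) -> EventTrace:
    """Exact stochastic simulation of R + L <=> RL.

    Propensities kon*nR*nL/V for binding and koff*nRL for unbinding;
    returns the exact piecewise-constant complex-count trace.
    """
    if kon < 0 or koff < 0 or nR0 < 0 or nL0 < 0 or V <= 0 or t_end <= 0:
        raise ValueError("rates, counts, volume and duration must be positive")
    rng = np.random.default_rng(seed)
    t = 0.0
    n_rl = 0
    times = [0.0]
    counts = [0]
    n_bind = n_unbind = 0
    while True:
        a_on = kon * (nR0 - n_rl) * (nL0 - n_rl) / V
        a_off = koff * n_rl
        a_tot = a_on + a_off
        if a_tot <= 0.0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t >= t_end:
            break
        if rng.random() < a_on / a_tot:
            n_rl += 1
            n_bind += 1
        else:
            n_rl -= 1
            n_unbind += 1
        times.append(t)
        counts.append(n_rl)
    times.append(t_end)
    counts.append(n_rl)
    return EventTrace(np.array(times), np.array(counts, dtype=float),
                      nR0, nL0, V, n_bind, n_unbind, kind="events")
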