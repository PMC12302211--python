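"""Interaction energies and forces of the coarse-grained model.

Terms
-----
repulsion            truncated-and-shifted 12-6 (WCA) between every bead pair
fene_bond            finitely extensible bond linking lipid beads
straightening_spring harmonic head <-> second-tail spring of each lipid
tail_attraction      cos^2-tapered cohesion between hydrophobic beads
bending              k_bend*[1 - cos(theta - theta0)] on chain triples
binding              distance- and angle-dependent site-site attraction

This module is the readable numpy reference; :mod:`memligkin._kernels`
mirrors it with numba for the integrator hot loop and is tested for exact
agreement against the functions here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    ANGLE_PROTEIN,
    ANGLE_TMD,
    BOND_FENE,
    BOND_HARMONIC,
    BOND_LIPID_SPRING,
    BOND_TMD,
    ForceField,
    ParticleSystem,
    Topology,
)

RC_WCA_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass
class EnergyForce:
    """Energy of one interaction plus forces on the involved beads.

    Forces sum to zero over the interacting set (translation invariance)
    and equal the negative gradient of the energy.
    """

    energy: float
    forces: np.ndarray  # (n_involved, 3)


class FiniteExtensibilityError(ValueError):
    """A FENE bond was stretched to or beyond its maximum length."""

    def __init__(self, r: float, rmax: float):
        super().__init__(f"FENE bond length r = {r} >= rmax = {rmax}")
        self.r = r
        self.rmax = rmax


# ---------------------------------------------------------------------------
# scalar radial profiles: return (energy, dE/dr)
# ---------------------------------------------------------------------------

def repulsion_profile(r: float, d: float, eps: float = 1.0) -> tuple[float, float]:
    """WCA energy and radial derivative at separation r, diameter d."""
    rc = RC_WCA_FACTOR * d
    if r >= rc:
        return 0.0, 0.0
    s6 = (d / r) ** 6
    e = 4.0 * eps * (s6 * s6 - s6) + eps
    dedr = -24.0 * eps * (2.0 * s6 * s6 - s6) / r
    return e, dedr


def fene_profile(r: float, k: float, rmax: float) -> tuple[float, float]:
    if r >= rmax:
        raise FiniteExtensibilityError(r, rmax)
    x = (r / rmax) ** 2
    e = -0.5 * k * rmax * rmax * math.log(1.0 - x)
    dedr = k * r / (1.0 - x)
    return e, dedr


def harmonic_profile(r: float, k: float, r0: float) -> tuple[float, float]:
    return 0.5 * k * (r - r0) ** 2, k * (r - r0)


def attraction_profile(r: float, eps: float, wc: float,
                       rc: float = RC_WCA_FACTOR) -> tuple[float, float]:
    """cos^2-tapered attraction: -eps for r < rc, smooth decay to 0 at rc+wc."""
    if r < rc:
        return -eps, 0.0
    if r >= rc + wc:
        return 0.0, 0.0
    arg = math.pi * (r - rc) / (2.0 * wc)
    c = math.cos(arg)
    e = -eps * c * c
    dedr = eps * math.pi / (2.0 * wc) * math.sin(2.0 * arg)
    return e, dedr


def bending_profile(theta: float, k_bend: float,
                    theta0: float) -> tuple[float, float]:
    """Energy k_bend*[1-cos(theta-theta0)] and dE/dtheta."""
    return k_bend * (1.0 - math.cos(theta - theta0)), k_bend * math.sin(theta - theta0)


def binding_profile(r: float, theta1: float, theta2: float,
                    eps_bind: float, rcut: float) -> float:
    """Site-site binding energy at separation r and terminal-axis angles.

    -eps_bind * cos^2(theta1) * cos^2(theta2) * [1 - (r/rcut)^2]^2 inside
    the cutoff with both angles below pi/2; zero otherwise.
    """
    if r <= 0:
        raise ValueError(f"site-site distance must be positive, got {r}")
    if r >= rcut:
        return 0.0
    c1, c2 = math.cos(theta1), math.cos(theta2)
    if c1 <= 0.0 or c2 <= 0.0:
        return 0.0
    env = 1.0 - (r / rcut) ** 2
    return -eps_bind * c1 * c1 * c2 * c2 * env * env


# ---------------------------------------------------------------------------
# pairwise / multi-body EnergyForce ops on canonical or explicit geometries
# ---------------------------------------------------------------------------

def _pair_ef(r: float, profile_args, profile) -> EnergyForce:
    """EnergyForce for two beads at separation r along x (canonical geometry)."""
    e, dedr = profile(r, *profile_args)
    f = np.zeros((2, 3))
    f[0, 0] = dedr   # force on bead 0 = -dE/dx0; x0 = -r direction
    f[1, 0] = -dedr
    return EnergyForce(e, f)


def repulsion(r: float, pair_diameter: float, eps: float = 1.0) -> EnergyForce:
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    return _pair_ef(r, (pair_diameter, eps), repulsion_profile)


def fene_bond(r: float, k: float, rmax: float) -> EnergyForce:
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r == 0.0:
        return EnergyForce(0.0, np.zeros((2, 3)))
    return _pair_ef(r, (k, rmax), fene_profile)


def straightening_spring(r: float, k: float, r0: float) -> EnergyForce:
    if r < 0:
        raise ValueError("distance must be non-negative")
    if r == 0.0:
        return EnergyForce(0.5 * k * r0 * r0, np.zeros((2, 3)))
    return _pair_ef(r, (k, r0), harmonic_profile)


def tail_attraction(r: float, eps: float, wc: float) -> EnergyForce:
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    return _pair_ef(r, (eps, wc), attraction_profile)


def angle_energy_force(ri: np.ndarray, rj: np.ndarray, rk: np.ndarray,
                       k_bend: float, theta0: float) -> EnergyForce:
    """Three-body bending term on explicit coordinates (j is the vertex)."""
    rij = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    rkj = np.asarray(rk, dtype=float) - np.asarray(rj, dtype=float)
    nij = np.linalg.norm(rij)
    nkj = np.linalg.norm(rkj)
    cos_t = float(np.dot(rij, rkj) / (nij * nkj))
    cos_t = max(-1.0, min(1.0, cos_t))
    theta = math.acos(cos_t)
    e = k_bend * (1.0 - math.cos(theta - theta0))
    # dE/dcos(theta) = -k*sin(theta-theta0)/sin(theta)
    #              = -k*cos(theta0) + k*cos(theta)*sin(theta0)/sin(theta)
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-16))
    dedcos = -k_bend * math.cos(theta0) + k_bend * cos_t * math.sin(theta0) / sin_t
    gi = dedcos * (rkj / (nij * nkj) - cos_t * rij / (nij * nij))
    gk = dedcos * (rij / (nij * nkj) - cos_t * rkj / (nkj * nkj))
    forces = np.empty((3, 3))
    forces[0] = -gi
    forces[2] = -gk
    forces[1] = gi + gk
    return EnergyForce(e, forces)


def bending(theta: float, k_bend: float, theta0: float) -> EnergyForce:
    """Bending term on a canonical planar triple with unit bonds and angle theta."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError(f"theta must lie in [0, pi], got {theta}")
    rj = np.zeros(3)
    ri = np.array([1.0, 0.0, 0.0])
    rk = np.array([math.cos(theta), math.sin(theta), 0.0])
    return angle_energy_force(ri, rj, rk, k_bend, theta0)


def binding_energy_force(x_axis_r: np.ndarray, x_site_r: np.ndarray,
                         x_site_l: np.ndarray, x_axis_l: np.ndarray,
                         eps_bind: float, rcut: float) -> EnergyForce:
    """Site-site binding on explicit coordinates of the four involved beads.

    ``x_axis_r``/``x_axis_l`` are the last chain beads defining the terminal
    bond axes; theta1/theta2 are measured between each axis and the
    inter-site vector pointing from the own site to the partner site.
    Displacements must already be minimum-imaged by the caller.
    """
    a = np.asarray(x_site_r, float) - np.asarray(x_axis_r, float)
    b = np.asarray(x_site_l, float) - np.asarray(x_axis_l, float)
    dv = np.asarray(x_site_l, float) - np.asarray(x_site_r, float)
    r = float(np.linalg.norm(dv))
    if r <= 0:
        raise ValueError("site-site distance must be positive")
    zero = EnergyForce(0.0, np.zeros((4, 3)))
    if r >= rcut:
        return zero
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    c1 = float(np.dot(a, dv) / (na * r))
    c2 = float(-np.dot(b, dv) / (nb * r))
    if c1 <= 0.0 or c2 <= 0.0:
        return zero
    u = 1.0 - (r / rcut) ** 2
    g = u * u
    e = -eps_bind * c1 * c1 * c2 * c2 * g
    dedc1 = -2.0 * eps_bind * c1 * c2 * c2 * g
    dedc2 = -2.0 * eps_bind * c1 * c1 * c2 * g
    dedr = -eps_bind * c1 * c1 * c2 * c2 * 2.0 * u * (-2.0 * r / (rcut * rcut))
    dc1_da = dv / (na * r) - c1 * a / (na * na)
    dc1_dd = a / (na * r) - c1 * dv / (r * r)
    dc2_db = -dv / (nb * r) - c2 * b / (nb * nb)
    dc2_dd = -b / (nb * r) - c2 * dv / (r * r)
    ge_a = dedc1 * dc1_da
    ge_b = dedc2 * dc2_db
    ge_d = dedc1 * dc1_dd + dedc2 * dc2_dd + dedr * dv / r
    forces = np.empty((4, 3))
    forces[0] = ge_a                 # -grad wrt axis_r:  a = site_r - axis_r
    forces[1] = -(ge_a) + ge_d       # site_r appears in a (+) and d (-)
    forces[2] = -(ge_b + ge_d)       # site_l appears in b (+) and d (+)
    forces[3] = ge_b                 # axis_l: b = site_l - axis_l
    return EnergyForce(e, forces)


def binding(r: float, theta1: float, theta2: float,
            eps_bind: float, rcut: float) -> EnergyForce:
    """Binding term on a canonical planar 4-bead geometry at (r, theta1, theta2)."""
    x_site_r = np.zeros(3)
    x_site_l = np.array([r, 0.0, 0.0])
    # receptor axis tilted by theta1 from +x, ligand axis by theta2 from -x
    x_axis_r = x_site_r - np.array([math.cos(theta1), math.sin(theta1), 0.0])
    x_axis_l = x_site_l + np.array([math.cos(theta2), math.sin(theta2), 0.0])
    return binding_energy_force(x_axis_r, x_site_r, x_site_l, x_axis_l,
                                eps_bind, rcut)


# ---------------------------------------------------------------------------
# 1:1 binding-site pairing registry
# ---------------------------------------------------------------------------

def pair_binding_energy(positions: np.ndarray, box, topology: Topology,
                        ff: ForceField, i_rec: int, j_lig: int) -> float:
    """Binding energy of receptor i_rec with ligand j_lig at the current frame."""
    rec = topology.receptors[i_rec]
    lig = topology.ligands[j_lig]
    p = positions
    a = box.min_image(p[rec.site] - p[rec.ecd[-1]])
    b = box.min_image(p[lig.site] - p[lig.chain[-1]])
    dv = box.min_image(p[lig.site] - p[rec.site])
    r = float(np.linalg.norm(dv))
    if r >= ff.bind_rcut or r <= 0:
        return 0.0
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    c1 = float(np.dot(a, dv) / (na * r))
    c2 = float(-np.dot(b, dv) / (nb * r))
    if c1 <= 0 or c2 <= 0:
        return 0.0
    env = 1.0 - (r / ff.bind_rcut) ** 2
    return -ff.eps_bind * c1 * c1 * c2 * c2 * env * env


def assign_binding_pairs(system: ParticleSystem, topology: Topology,
                         ff: ForceField,
                         partner_of_r: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Update the 1:1 site-pair registry.

    Each binding site has at most one active partner.  Existing pairs
    persist until their site-site distance exceeds ``bind_rcut``
    (unbinding); freed sites are then re-assigned greedily to the
    energy-minimizing available candidate within the cutoff.

    Returns (partner_of_r, partner_of_l) index arrays with -1 for unbound.
    """
    n_r = len(topology.receptors)
    n_l = len(topology.ligands)
    if partner_of_r is None:
        partner_of_r = np.full(n_r, -1, dtype=np.int64)
    partner_of_r = partner_of_r.copy()
    partner_of_l = np.full(n_l, -1, dtype=np.int64)
    p = system.positions
    box = system.box
    sites_r = topology.site_r_indices
    sites_l = topology.site_l_indices
    # dissolve pairs out of range
    for i in range(n_r):
        j = partner_of_r[i]
        if j < 0:
            continue
        dv = box.min_image(p[sites_l[j]] - p[sites_r[i]])
        if np.linalg.norm(dv) >= ff.bind_rcut:
            partner_of_r[i] = -1
        else:
            partner_of_l[j] = i
    # greedy energy-minimizing assignment among free sites
    candidates = []
    for i in range(n_r):
        if partner_of_r[i] >= 0:
            continue
        for j in range(n_l):
            if partner_of_l[j] >= 0:
                continue
            dv = box.min_image(p[sites_l[j]] - p[sites_r[i]])
            if np.linalg.norm(dv) < ff.bind_rcut:
                e = pair_binding_energy(p, box, topology, ff, i, j)
                candidates.append((e, i, j))
    for e, i, j in sorted(candidates):
        if partner_of_r[i] < 0 and partner_of_l[j] < 0:
            partner_of_r[i] = j
            partner_of_l[j] = i
    return partner_of_r, partner_of_l


# ---------------------------------------------------------------------------
# brute-force total energy / forces (reference implementation)
# ---------------------------------------------------------------------------

TERM_NAMES = ("repulsion", "fene", "spring", "attraction", "bending",
              "binding", "restraint")


def total_energy_forces(system: ParticleSystem, topology: Topology,
                        ff: ForceField,
                        partner_of_r: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, dict[str, float], np.ndarray]:
    """All-pairs reference evaluation of every term.

    Returns (forces (N,3), per-term energy dict, virial diagonal (3,)).
    The per-axis virial is sum over interactions of f_x*dx etc., needed for
    the lateral-tension estimate of the zero-tension box control.
    """
    n = system.n_beads
    p = system.positions
    box = system.box
    forces = np.zeros((n, 3))
    energies = {name: 0.0 for name in TERM_NAMES}
    virial = np.zeros(3)
    sig = ff.sigma_matrix()
    attr = ff.attraction_matrix()
    types = system.bead_types
    rc_attr_in = RC_WCA_FACTOR * ff.sigma_tail

    def accumulate_pair(i, j, dedr, r, dv, term, e):
        # dv = p[j] - p[i], minimum image; force on j along +dv for dedr < 0
        fvec = -dedr * dv / r
        forces[j] += fvec
        forces[i] -= fvec
        virial[:] += fvec * dv
        energies[term] += e

    # nonbonded: WCA everywhere + hydrophobic cohesion
    for i in range(n - 1):
        dv_all = box.min_image(p[i + 1:] - p[i])
        rr = np.linalg.norm(dv_all, axis=1)
        for jj, r in enumerate(rr):
            j = i + 1 + jj
            d = sig[types[i], types[j]]
            if r < RC_WCA_FACTOR * d:
                e, dedr = repulsion_profile(r, d, ff.eps_rep)
                accumulate_pair(i, j, dedr, r, dv_all[jj], "repulsion", e)
            if attr[types[i], types[j]] and r < rc_attr_in + ff.attr_wc:
                e, dedr = attraction_profile(r, ff.attr_eps, ff.attr_wc, rc_attr_in)
                accumulate_pair(i, j, dedr, r, dv_all[jj], "attraction", e)

    # bonds
    for (i, j, kind) in topology.bonds:
        dv = box.min_image(p[j] - p[i])
        r = float(np.linalg.norm(dv))
        if kind == BOND_FENE:
            e, dedr = fene_profile(r, ff.fene_k, ff.fene_rmax)
            term = "fene"
        elif kind == BOND_LIPID_SPRING:
            e, dedr = harmonic_profile(r, ff.spring_k, ff.spring_r0)
            term = "spring"
        elif kind == BOND_HARMONIC:
            e, dedr = harmonic_profile(r, ff.bond_k, ff.bond_r0)
            term = "spring"
        elif kind == BOND_TMD:
            e, dedr = harmonic_profile(r, ff.tmd_bond_k, ff.tmd_bond_r0)
            term = "spring"
        else:
            raise ValueError(f"unknown bond kind {kind}")
        accumulate_pair(int(i), int(j), dedr, r, dv, term, e)

    # angles
    for (i, j, k, kind) in topology.angles:
        kk = ff.k_bend if kind == ANGLE_PROTEIN else ff.tmd_angle_k
        th0 = ff.theta0 if kind == ANGLE_PROTEIN else math.pi
        rij = box.min_image(p[i] - p[j])
        rkj = box.min_image(p[k] - p[j])
        ef = angle_energy_force(rij, np.zeros(3), rkj, kk, th0)
        forces[i] += ef.forces[0]
        forces[j] += ef.forces[1]
        forces[k] += ef.forces[2]
        energies["bending"] += ef.energy
        virial[:] += ef.forces[0] * rij + ef.forces[2] * rkj

    # specific binding for active pairs
    if partner_of_r is not None:
        for i_rec, j_lig in enumerate(partner_of_r):
            if j_lig < 0:
                continue
            rec = topology.receptors[i_rec]
            lig = topology.ligands[int(j_lig)]
            idx = (rec.ecd[-1], rec.site, lig.site, lig.chain[-1])
            # build a locally unwrapped geometry around the receptor site
            base = p[rec.site]
            xs = [base + box.min_image(p[ix] - base) for ix in idx]
            ef = binding_energy_force(xs[0], xs[1], xs[2], xs[3],
                                      ff.eps_bind, ff.bind_rcut)
            for bead, f, x in zip(idx, ef.forces, xs):
                forces[bead] += f
                virial[:] += f * (x - base)
            energies["binding"] += ef.energy

    # plane restraint (supported membranes)
    for i in topology.restrained:
        dz = p[i, 2] - topology.restraint_z0
        energies["restraint"] += 0.5 * ff.support_k * dz * dz
        forces[i, 2] -= ff.support_k * dz
        virial[2] += -ff.support_k * dz * dz

    return forces, energies, virial
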