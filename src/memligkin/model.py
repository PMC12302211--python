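"""Core domain types and reduced-unit conventions.

Everything in the package is expressed in reduced units: the bead
diameter ``sigma0 = 1`` (mapped to 1 nm), the energy scale ``epsilon0 = 1``,
bead mass ``m = 1`` and the derived time unit ``tau0 = sigma0*sqrt(m/epsilon0)``.
The thermal energy defaults to ``kBT = 1.1 epsilon0``.

Bead types
----------
``HEAD``/``TAIL``  lipid head and tail beads (three-bead implicit-solvent lipid)
``TMD``            transmembrane-domain beads of a receptor (rigid rod)
``ECD``            ectodomain chain beads (receptors) / chain beads (ligands)
``SITE_R``/``SITE_L`` terminal binding-site beads of receptors and ligands
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

# bead type codes (array-friendly small ints)
HEAD, TAIL, TMD, ECD, SITE_R, SITE_L = 0, 1, 2, 3, 4, 5
BEAD_TYPE_NAMES = ("HEAD", "TAIL", "TMD", "ECD", "SITE_R", "SITE_L")
N_BEAD_TYPES = 6
HYDROPHOBIC_TYPES = (TAIL, TMD)

# bond kinds
BOND_FENE = 0          # lipid head-tail1, tail1-tail2
BOND_LIPID_SPRING = 1  # lipid straightening spring head <-> tail2
BOND_HARMONIC = 2      # protein backbone bond
BOND_TMD = 3           # stiff bond inside the transmembrane rod

# angle kinds
ANGLE_PROTEIN = 0      # k_bend, theta0
ANGLE_TMD = 1          # very stiff straight angle inside the TMD rod


@dataclass(frozen=True)
class Units:
    """Reduced-unit system; all other modules quote quantities in these."""

    sigma0: float = 1.0    # length unit, = 1 nm
    epsilon0: float = 1.0  # energy unit
    tau0: float = 1.0      # time unit sigma0*sqrt(m/epsilon0), m = 1
    kBT: float = 1.1       # thermal energy in epsilon0

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError(f"kBT must be positive, got {self.kBT}")

    def to_nm(self, length: float) -> float:
        return length * self.sigma0


@dataclass
class Box:
    """Orthorhombic simulation box with per-axis periodicity."""

    lengths: np.ndarray
    periodic: np.ndarray = field(
        default_factory=lambda: np.array([True, True, True])
    )

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64).copy()
        self.periodic = np.asarray(self.periodic, dtype=bool).copy()
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ValueError("box needs 3 positive lengths")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def area_xy(self) -> float:
        return float(self.lengths[0] * self.lengths[1])

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) along periodic axes."""
        pos = np.array(positions, dtype=np.float64)
        for ax in range(3):
            if self.periodic[ax]:
                pos[:, ax] = np.mod(pos[:, ax], self.lengths[ax])
        return pos

    def min_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image convention for displacement vectors."""
        dr = np.array(dr, dtype=np.float64)
        vec = dr.reshape(-1, 3)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                vec[:, ax] -= L * np.round(vec[:, ax] / L)
        return vec.reshape(dr.shape)

    def copy(self) -> "Box":
        return Box(self.lengths.copy(), self.periodic.copy())


@dataclass
class ParticleSystem:
    """The single mutable simulation state: coordinates, velocities, labels."""

    positions: np.ndarray      # (N, 3) in sigma0
    velocities: np.ndarray     # (N, 3) in sigma0/tau0
    bead_types: np.ndarray     # (N,) small ints from the codes above
    box: Box
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.bead_types = np.asarray(self.bead_types, dtype=np.int8)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(),
            self.velocities.copy(),
            self.bead_types.copy(),
            self.box.copy(),
            self.time,
        )


@dataclass
class Receptor:
    """A membrane receptor: rigid TMD rod + semiflexible ectodomain + site bead.

    Soluble receptors (ectodomain only) simply have an empty ``tmd`` array.
    """

    tmd: np.ndarray    # bead indices of the transmembrane rod (may be empty)
    ecd: np.ndarray    # bead indices of the ectodomain chain
    site: int          # index of the binding-site bead

    def __post_init__(self) -> None:
        self.tmd = np.asarray(self.tmd, dtype=np.int64)
        self.ecd = np.asarray(self.ecd, dtype=np.int64)

    @property
    def beads(self) -> np.ndarray:
        return np.concatenate([self.tmd, self.ecd, [self.site]])


@dataclass
class Ligand:
    """A soluble ligand: bead chain + terminal binding-site bead."""

    chain: np.ndarray
    site: int

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=np.int64)

    @property
    def beads(self) -> np.ndarray:
        return np.concatenate([self.chain, [self.site]])


@dataclass
class Topology:
    """Molecules as bead-index lists plus bond/angle/binding-site registries."""

    lipids: np.ndarray                      # (n_lipids, 3) head, tail1, tail2
    receptors: list[Receptor] = field(default_factory=list)
    ligands: list[Ligand] = field(default_factory=list)
    bonds: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.int64)
    )                                       # (i, j, kind)
    angles: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 4), dtype=np.int64)
    )                                       # (i, j, k, kind)
    # optional plane restraint (supported membranes): bead indices pinned in z
    restrained: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64)
    )
    restraint_z0: float = 0.0
    # set by the builders: quasi_planar | supported | vesicle | soluble
    shape: str = ""

    def __post_init__(self) -> None:
        self.lipids = np.asarray(self.lipids, dtype=np.int64).reshape(-1, 3)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 3)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 4)
        self.restrained = np.asarray(self.restrained, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        n = 3 * len(self.lipids)
        n += sum(len(r.tmd) + len(r.ecd) + 1 for r in self.receptors)
        n += sum(len(l.chain) + 1 for l in self.ligands)
        return n

    @property
    def site_r_indices(self) -> np.ndarray:
        return np.array([r.site for r in self.receptors], dtype=np.int64)

    @property
    def site_l_indices(self) -> np.ndarray:
        return np.array([l.site for l in self.ligands], dtype=np.int64)

    @property
    def axis_r_indices(self) -> np.ndarray:
        """Last ectodomain bead of each receptor (defines the terminal-bond axis)."""
        return np.array([r.ecd[-1] for r in self.receptors], dtype=np.int64)

    @property
    def axis_l_indices(self) -> np.ndarray:
        return np.array([l.chain[-1] for l in self.ligands], dtype=np.int64)

    def molecule_membership(self) -> dict[int, list[int]]:
        """Map bead index -> list of molecule ids that claim it."""
        members: dict[int, list[int]] = {}
        mol = 0
        for trip in self.lipids:
            for i in trip:
                members.setdefault(int(i), []).append(mol)
            mol += 1
        for r in self.receptors:
            for i in r.beads:
                members.setdefault(int(i), []).append(mol)
            mol += 1
        for l in self.ligands:
            for i in l.beads:
                members.setdefault(int(i), []).append(mol)
            mol += 1
        return members

    def to_dict(self) -> dict:
        return {
            "lipids": self.lipids.tolist(),
            "receptors": [
                {"tmd": r.tmd.tolist(), "ecd": r.ecd.tolist(), "site": int(r.site)}
                for r in self.receptors
            ],
            "ligands": [
                {"chain": l.chain.tolist(), "site": int(l.site)}
                for l in self.ligands
            ],
            "bonds": self.bonds.tolist(),
            "angles": self.angles.tolist(),
            "restrained": self.restrained.tolist(),
            "restraint_z0": float(self.restraint_z0),
            "shape": self.shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            lipids=np.asarray(d["lipids"], dtype=np.int64).reshape(-1, 3),
            receptors=[
                Receptor(np.asarray(r["tmd"]), np.asarray(r["ecd"]), int(r["site"]))
                for r in d["receptors"]
            ],
            ligands=[
                Ligand(np.asarray(l["chain"]), int(l["site"]))
                for l in d["ligands"]
            ],
            bonds=np.asarray(d["bonds"], dtype=np.int64).reshape(-1, 3),
            angles=np.asarray(d["angles"], dtype=np.int64).reshape(-1, 4),
            restrained=np.asarray(d["restrained"], dtype=np.int64),
            restraint_z0=float(d["restraint_z0"]),
            shape=d.get("shape", ""),
        )


# protein bead diameter; also fixes the chain contour-length convention:
# a chain of n beads plus its site bead has contour length 0.95*(n+1) sigma0,
# so 6 and 11 chain beads give l = 6.65 and 11.4 sigma0.
PROTEIN_BEAD_DIAMETER = 0.95


def contour_length(n_chain_beads: int) -> float:
    """Contour length of a receptor ectodomain / ligand with ``n_chain_beads``
    chain beads plus one terminal site bead, in sigma0.

    Convention: beads of diameter 0.95 sigma0 laid end to end, counting the
    site bead — l = 0.95*(n+1).  This reproduces l = 6.65 sigma0 for 6-bead
    and l = 11.4 sigma0 for 11-bead chains.
    """
    return PROTEIN_BEAD_DIAMETER * (n_chain_beads + 1)


@dataclass
class ForceField:
    """Every interaction constant of the coarse-grained model.

    Lipid constants are the canonical implicit-solvent three-bead
    parameterization (FENE k = 30, rmax = 1.5; head/tail repulsion
    diameters 0.95/1.0 sigma0; straightening spring k = 10, r0 = 4 sigma0;
    tail attraction depth 1 epsilon0 with tunable taper width ``attr_wc``).
    The two protein knobs exposed by :func:`default_forcefield` are the
    chain bending stiffness ``k_bend`` and the site-site binding strength
    ``eps_bind``.
    """

    # pairwise repulsion (truncated-shifted 12-6, zero beyond 2^(1/6) d)
    eps_rep: float = 1.0
    sigma_head: float = 0.95    # diameter when either bead is non-hydrophobic
    sigma_tail: float = 1.0     # diameter when both beads are hydrophobic
    # lipid bonded terms
    fene_k: float = 30.0
    fene_rmax: float = 1.5
    spring_k: float = 10.0
    spring_r0: float = 4.0
    # lipid tail cohesion
    attr_eps: float = 1.0
    attr_wc: float = 1.7
    # protein chain terms
    bond_k: float = 100.0
    bond_r0: float = PROTEIN_BEAD_DIAMETER
    tmd_bond_k: float = 1000.0
    tmd_bond_r0: float = 1.5
    tmd_angle_k: float = 1000.0
    k_bend: float = 10.0
    theta0: float = math.pi
    # specific site-site binding
    eps_bind: float = 14.0
    bind_rcut: float = 1.5
    # supported-membrane plane restraint
    support_k: float = 30.0

    def __post_init__(self) -> None:
        if self.k_bend < 0:
            raise ValueError(f"k_bend must be >= 0, got {self.k_bend}")
        if self.eps_bind < 0:
            raise ValueError(f"eps_bind must be >= 0, got {self.eps_bind}")
        if self.bind_rcut <= 0:
            raise ValueError("bind_rcut must be positive")
        if self.fene_rmax <= self.sigma_tail:
            raise ValueError("fene_rmax must exceed the bonded bead diameter")

    def attraction_matrix(self) -> np.ndarray:
        """(6, 6) bool: which type pairs feel the cos^2-tapered cohesion.

        Tail-tail cohesion stabilizes the bilayer; tail-TMD cohesion
        anchors the transmembrane rod in the hydrophobic core.  TMD-TMD
        pairs do NOT attract: direct rod-rod cohesion would give the
        receptors a clustering propensity the model must not have.
        """
        attr = np.zeros((N_BEAD_TYPES, N_BEAD_TYPES), dtype=bool)
        attr[TAIL, TAIL] = True
        attr[TAIL, TMD] = True
        attr[TMD, TAIL] = True
        return attr

    def sigma_matrix(self) -> np.ndarray:
        """(6, 6) repulsion diameter per bead-type pair: sigma_tail for
        cohesion-carrying pairs, sigma_head (protein/head size) otherwise."""
        sig = np.full((N_BEAD_TYPES, N_BEAD_TYPES), self.sigma_head)
        sig[self.attraction_matrix()] = self.sigma_tail
        return sig

    @property
    def max_cutoff(self) -> float:
        """Largest interaction range of any pair term."""
        rc_wca = 2.0 ** (1.0 / 6.0) * max(self.sigma_head, self.sigma_tail)
        rc_attr = 2.0 ** (1.0 / 6.0) * self.sigma_tail + self.attr_wc
        return max(rc_wca, rc_attr, self.bind_rcut)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**d)

    def replace(self, **kwargs) -> "ForceField":
        return replace(self, **kwargs)


def default_forcefield(k_bend: float, eps_bind: float, **overrides) -> ForceField:
    """Full parameter set: fixed lipid constants + caller-chosen protein knobs.

    Parameters
    ----------
    k_bend : float
        Chain bending stiffness in epsilon0 (10 for semirigid multidomain
        proteins, 100 for rigid rod-like proteins).
    eps_bind : float
        Depth of the site-site binding potential in epsilon0.
    """
    if k_bend < 0 or eps_bind < 0:
        raise ValueError("k_bend and eps_bind must be non-negative")
    return ForceField(k_bend=k_bend, eps_bind=eps_bind, **overrides)


def validate_system(system: ParticleSystem,
                    topology: Topology,
                    ff: ForceField) -> list[str]:
    """Check every structural invariant; violations are data, not exceptions.

    Returns an empty list iff the (system, topology, ff) triple is
    internally consistent: bead counts match, each bead belongs to exactly
    one molecule, each protein has exactly one site bead, type labels agree
    with the topology, bonds/angles are duplicate-free and chain-consecutive,
    positions are wrapped and finite, and the box is large enough for the
    interaction cutoffs.
    """
    v: list[str] = []
    n_top = topology.n_beads
    n_sys = system.n_beads
    if n_top != n_sys:
        v.append(f"bead count mismatch: topology implies {n_top}, system has {n_sys}")
        return v  # index-based checks below would be unsafe

    if not np.all(np.isfinite(system.positions)):
        bad = np.where(~np.isfinite(system.positions).all(axis=1))[0]
        v.append(f"non-finite positions at beads {bad.tolist()[:10]}")

    members = topology.molecule_membership()
    for i in range(n_sys):
        mols = members.get(i, [])
        if len(mols) == 0:
            v.append(f"bead {i} belongs to no molecule")
        elif len(mols) > 1:
            v.append(f"bead {i} belongs to multiple molecules {mols}")

    # type labels
    types = system.bead_types
    for trip in topology.lipids:
        h, t1, t2 = (int(x) for x in trip)
        if types[h] != HEAD or types[t1] != TAIL or types[t2] != TAIL:
            v.append(f"lipid {trip.tolist()} has wrong bead types")
    for k, r in enumerate(topology.receptors):
        if r.site < 0 or r.site >= n_sys:
            v.append(f"receptor {k} has invalid site index {r.site}")
            continue
        if types[r.site] != SITE_R:
            v.append(f"receptor {k} site bead {r.site} not labelled SITE_R")
        if len(r.ecd) == 0:
            v.append(f"receptor {k} has an empty ectodomain")
        if np.any(types[r.tmd] != TMD) or np.any(types[r.ecd] != ECD):
            v.append(f"receptor {k} has mislabelled TMD/ECD beads")
    for k, l in enumerate(topology.ligands):
        if l.site < 0 or l.site >= n_sys:
            v.append(f"ligand {k} has invalid site index {l.site}")
            continue
        if types[l.site] != SITE_L:
            v.append(f"ligand {k} site bead {l.site} not labelled SITE_L")
        if np.any(types[l.chain] != ECD):
            v.append(f"ligand {k} has mislabelled chain beads")

    # bonds: valid indices, no duplicates
    if len(topology.bonds):
        ij = np.sort(topology.bonds[:, :2], axis=1)
        if np.any(topology.bonds[:, :2] < 0) or np.any(topology.bonds[:, :2] >= n_sys):
            v.append("bond with out-of-range bead index")
        keys = ij[:, 0] * n_sys + ij[:, 1]
        if len(np.unique(keys)) != len(keys):
            v.append("duplicate bonds present")
    bond_set = {
        (min(int(b[0]), int(b[1])), max(int(b[0]), int(b[1])))
        for b in topology.bonds
    }

    # angles: no duplicates, consecutive within one chain (both legs bonded)
    if len(topology.angles):
        seen = set()
        for (i, j, k, _kind) in topology.angles:
            key = (min(int(i), int(k)), int(j), max(int(i), int(k)))
            if key in seen:
                v.append(f"duplicate angle {key}")
            seen.add(key)
            for a, b in ((i, j), (j, k)):
                if (min(int(a), int(b)), max(int(a), int(b))) not in bond_set:
                    v.append(f"angle ({i},{j},{k}) spans a non-bonded pair ({a},{b})")

    # positions wrapped along periodic axes
    for ax in range(3):
        if system.box.periodic[ax]:
            x = system.positions[:, ax]
            if np.any(x < -1e-9) or np.any(x >= system.box.lengths[ax] + 1e-9):
                v.append(f"positions not wrapped along axis {ax}")

    # box comfortably larger than twice the largest cutoff
    if np.any(system.box.lengths <= 2.0 * ff.max_cutoff):
        v.append(
            f"box lengths {system.box.lengths.tolist()} not all > "
            f"2 x max cutoff ({2 * ff.max_cutoff:.3f})"
        )
    return v
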