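"""Time evolution: Langevin (BAOAB) integrator, Verlet neighbor list with
linked-cell builds, zero-tension lateral box control, and checkpointing.

Reproducibility contract: the thermostat noise for step ``s`` is drawn from
a counter-based Philox stream keyed by the run seed with the step index in
the counter, so a restarted run continues the exact same noise sequence and
``run(a); run(b)`` is bit-identical to ``run(a+b)``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import _kernels as K
from .model import (
    ANGLE_PROTEIN,
    ForceField,
    HYDROPHOBIC_TYPES,
    ParticleSystem,
    Box,
    Topology,
)
from .potentials import TERM_NAMES

RC_WCA_FACTOR = 2.0 ** (1.0 / 6.0)


class IntegrationBlowUpError(RuntimeError):
    """Raised when coordinates or forces become non-finite or a FENE bond
    exceeds its maximum extension."""


class ConfigurationError(ValueError):
    """Raised when an operation is applied to an incompatible system."""


class CheckpointCorruptionError(RuntimeError):
    """Checkpoint checksum mismatch."""


@dataclass
class IntegratorParams:
    """Langevin + box-control settings, all in reduced units."""

    dt: float = 0.005            # tau0
    gamma: float = 1.0           # 1/tau0 friction
    kBT: float = 1.1             # epsilon0
    seed: int = 0
    tension_control: str = "off"  # "off" | "zero_tension"
    barostat_interval: int = 50   # steps between lateral rescalings
    barostat_gain: float = 2e-3   # scale response per unit tension
    max_lateral_scale: float = 1e-4  # bound on |scale-1| per update
    skin: float = 0.4            # Verlet skin, sigma0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.tension_control not in ("off", "zero_tension"):
            raise ValueError(f"unknown tension_control {self.tension_control!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IntegratorParams":
        return cls(**d)


@dataclass
class NeighborList:
    """Verlet pair list + rebuild bookkeeping."""

    pairs: np.ndarray            # (M, 2) int32
    skin: float
    displacement: np.ndarray     # (N, 3) since last build
    n_builds: int = 0


def _pack_topology(topology: Topology, ff: ForceField):
    """Flatten topology + force field into kernel-ready arrays."""
    bonds = topology.bonds
    bond_ij = np.ascontiguousarray(bonds[:, :2].astype(np.int64))
    bond_kind = np.ascontiguousarray(bonds[:, 2].astype(np.int64))
    angles = topology.angles
    angle_ijk = np.ascontiguousarray(angles[:, :3].astype(np.int64))
    angle_k = np.where(angles[:, 3] == ANGLE_PROTEIN, ff.k_bend, ff.tmd_angle_k)
    angle_th0 = np.where(angles[:, 3] == ANGLE_PROTEIN, ff.theta0, math.pi)
    return dict(
        sig66=ff.sigma_matrix(),
        attr66=ff.attraction_matrix().astype(np.uint8),
        bond_ij=bond_ij,
        bond_kind=bond_kind,
        angle_ijk=angle_ijk,
        angle_k=np.ascontiguousarray(angle_k, dtype=np.float64),
        angle_th0=np.ascontiguousarray(angle_th0, dtype=np.float64),
        sites_r=topology.site_r_indices,
        sites_l=topology.site_l_indices,
        axis_r=(topology.axis_r_indices if len(topology.receptors)
                else np.zeros(0, dtype=np.int64)),
        axis_l=(topology.axis_l_indices if len(topology.ligands)
                else np.zeros(0, dtype=np.int64)),
        restrained=topology.restrained,
    )


class Simulation:
    """Owns the mutable run state and advances it step by step."""

    def __init__(self, system: ParticleSystem, topology: Topology,
                 ff: ForceField, params: IntegratorParams):
        self.system = system
        self.topology = topology
        self.ff = ff
        self.params = params
        self.step_index = 0
        n = system.n_beads
        self._pack = _pack_topology(topology, ff)
        self._hydrophobic = np.isin(
            system.bead_types, HYDROPHOBIC_TYPES).astype(np.uint8)
        from .model import TMD as _TMD
        self._is_tmd = (system.bead_types == _TMD).astype(np.uint8)
        self._cut_short = RC_WCA_FACTOR * max(ff.sigma_head, ff.sigma_tail)
        self._cut_long = RC_WCA_FACTOR * ff.sigma_tail + ff.attr_wc
        self.partner_r = np.full(len(topology.receptors), -1, dtype=np.int64)
        self.partner_l = np.full(len(topology.ligands), -1, dtype=np.int64)
        self.forces = np.zeros((n, 3))
        self.energies = np.zeros(7)
        self.virial = np.zeros(3)
        self._zero_noise = np.zeros((n, 3))
        self._pair_capacity = max(64, 40 * n)
        self._n_pairs = 0
        self._pairs_h = np.zeros((0, 2), dtype=np.int32)
        self._pairs_o = np.zeros((0, 2), dtype=np.int32)
        self.nlist = NeighborList(
            pairs=np.zeros((0, 2), dtype=np.int32),
            skin=params.skin,
            displacement=np.zeros((n, 3)),
        )
        # zero-tension accumulators
        self._tension_sum = 0.0
        self._tension_n = 0
        self.last_tension = 0.0
        self._rebuild_neighbors()
        self._update_pairs()
        self._compute_forces()

    # -- internals ----------------------------------------------------------

    @property
    def _box_l(self) -> np.ndarray:
        return self.system.box.lengths

    @property
    def _periodic(self) -> np.ndarray:
        return self.system.box.periodic

    def _rebuild_neighbors(self) -> None:
        while True:
            pairs, count = K.build_pair_list(
                self.system.positions, self._box_l, self._periodic,
                self._hydrophobic, self._cut_short, self._cut_long,
                self.nlist.skin, self._pair_capacity)
            if count <= self._pair_capacity:
                break
            self._pair_capacity = int(1.3 * count) + 64
        self.nlist.pairs = pairs[:count]
        self._n_pairs = count
        self._pairs_h, self._pairs_o = K.partition_pairs(
            pairs, count, self._hydrophobic, self._is_tmd)
        self.nlist.displacement[:] = 0.0
        self.nlist.n_builds += 1
        if not np.all(np.isfinite(self.system.positions)):
            raise IntegrationBlowUpError(
                f"non-finite coordinates at step {self.step_index}")

    def _update_pairs(self) -> None:
        if len(self.partner_r) == 0 or len(self.partner_l) == 0:
            return
        K.update_binding_pairs(
            self.system.positions, self._box_l, self._periodic,
            self._pack["sites_r"], self._pack["sites_l"],
            self._pack["axis_r"], self._pack["axis_l"],
            self.partner_r, self.partner_l,
            self.ff.eps_bind, self.ff.bind_rcut)

    def _compute_forces(self) -> None:
        p = self._pack
        ff = self.ff
        status = K.compute_forces(
            self.system.positions, self._pairs_h, self._pairs_o,
            self._box_l, self._periodic,
            ff.sigma_tail, ff.sigma_head,
            ff.eps_rep, ff.attr_eps, ff.attr_wc,
            p["bond_ij"], p["bond_kind"],
            ff.fene_k, ff.fene_rmax, ff.spring_k, ff.spring_r0,
            ff.bond_k, ff.bond_r0, ff.tmd_bond_k, ff.tmd_bond_r0,
            p["angle_ijk"], p["angle_k"], p["angle_th0"],
            p["sites_r"], p["sites_l"], p["axis_r"], p["axis_l"],
            self.partner_r, ff.eps_bind, ff.bind_rcut,
            p["restrained"], ff.support_k, self.topology.restraint_z0,
            self.forces, self.energies, self.virial)
        if status == K.STATUS_FENE_OVERSTRETCH:
            raise IntegrationBlowUpError(
                f"FENE bond overstretched at step {self.step_index}")

    def _noise(self) -> np.ndarray:
        if self.params.gamma == 0.0:
            return self._zero_noise
        bit = np.random.Philox(
            key=np.uint64(self.params.seed),
            counter=[0, 0, np.uint64(self.step_index), 0])
        return np.random.Generator(bit).standard_normal(
            (self.system.n_beads, 3))

    # -- public API ---------------------------------------------------------

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.system.velocities ** 2))

    @property
    def potential_energy(self) -> float:
        return float(self.energies.sum())

    @property
    def energy_terms(self) -> dict[str, float]:
        return dict(zip(TERM_NAMES, self.energies.tolist()))

    @property
    def n_bound(self) -> int:
        return int(np.sum(self.partner_r >= 0))

    def instantaneous_tension(self) -> float:
        """Lateral (surface) tension Sigma = Lz*(P_N - P_L) in epsilon0/sigma0^2."""
        kin = K.kinetic_tensor(self.system.velocities)
        v = self.system.box.volume
        p_ax = (kin + self.virial) / v
        return float(self._box_l[2] * (p_ax[2] - 0.5 * (p_ax[0] + p_ax[1])))

    def step(self, n_steps: int = 1) -> None:
        """Advance ``n_steps`` BAOAB Langevin steps."""
        params = self.params
        dt = params.dt
        c1 = math.exp(-params.gamma * dt)
        c2 = math.sqrt(params.kBT * max(0.0, 1.0 - c1 * c1))
        half_skin2 = (self.nlist.skin / 2.0) ** 2
        zero_tension = params.tension_control == "zero_tension"
        if zero_tension and self.topology.shape not in (
                "quasi_planar", "supported"):
            raise ConfigurationError(
                "zero-tension control requires a planar membrane system, "
                f"got shape {self.topology.shape!r}")
        for _ in range(n_steps):
            self.step_index += 1
            noise = self._noise()
            max_d2 = K.baoab_bao_a(
                self.system.positions, self.system.velocities, self.forces,
                self.nlist.displacement, dt, c1, c2, noise,
                self._box_l, self._periodic)
            if max_d2 > half_skin2:
                self._rebuild_neighbors()
            self._update_pairs()
            self._compute_forces()
            K.kick(self.system.velocities, self.forces, 0.5 * dt)
            self.system.time += dt
            if zero_tension:
                self.last_tension = self.instantaneous_tension()
                self._tension_sum += self.last_tension
                self._tension_n += 1
                if self.step_index % params.barostat_interval == 0:
                    self._apply_zero_tension()

    def _apply_zero_tension(self) -> None:
        """Berendsen-style lateral rescaling driving mean tension to zero."""
        if self._tension_n == 0:
            return
        mean_tension = self._tension_sum / self._tension_n
        self._tension_sum = 0.0
        self._tension_n = 0
        delta = self.params.barostat_gain * mean_tension
        delta = max(-self.params.max_lateral_scale,
                    min(self.params.max_lateral_scale, delta))
        # positive tension (stretched): shrink the lateral box
        scale = 1.0 - delta
        K.scale_lateral(self.system.positions, self._box_l, scale)
        self._rebuild_neighbors()
        self._compute_forces()

    def run(self, n_steps: int, observers=None,
            checkpoint_path=None, checkpoint_every: int = 0) -> None:
        """Advance ``n_steps``, invoking each (stride, callback) observer.

        Observers fire at the start (current step) and then every ``stride``
        steps; callbacks receive this Simulation.  With ``n_steps = 0`` the
        system is untouched and observers fire exactly once.
        """
        observers = observers or []
        for _, cb in observers:
            cb(self)
        done = 0
        while done < n_steps:
            strides = [s for s, _ in observers if s > 0]
            if checkpoint_every > 0:
                strides.append(checkpoint_every)
            to_next = [
                s - (self.step_index % s) if self.step_index % s else s
                for s in strides]
            chunk = min([n_steps - done] + to_next)
            self.step(chunk)
            done += chunk
            for stride, cb in observers:
                if stride > 0 and self.step_index % stride == 0:
                    cb(self)
            if (checkpoint_every > 0 and checkpoint_path is not None
                    and self.step_index % checkpoint_every == 0):
                self.checkpoint(checkpoint_path)

    # -- checkpointing ------------------------------------------------------

    def checkpoint(self, path) -> None:
        """Write the full mutable state; restart reproduces the continued
        trajectory bit-exactly for the same seed."""
        sha = hashlib.sha256()
        sha.update(np.ascontiguousarray(self.system.positions).tobytes())
        sha.update(np.ascontiguousarray(self.system.velocities).tobytes())
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.system.positions)
            f.create_dataset("velocities", data=self.system.velocities)
            f.create_dataset("bead_types", data=self.system.bead_types)
            f.create_dataset("box_lengths", data=self._box_l)
            f.create_dataset("box_periodic",
                             data=self._periodic.astype(np.uint8))
            f.create_dataset("partner_r", data=self.partner_r)
            f.create_dataset("partner_l", data=self.partner_l)
            f.attrs["time"] = self.system.time
            f.attrs["step_index"] = self.step_index
            f.attrs["tension_sum"] = self._tension_sum
            f.attrs["tension_n"] = self._tension_n
            f.attrs["checksum"] = sha.hexdigest()
            f.attrs["topology"] = json.dumps(self.topology.to_dict())
            f.attrs["forcefield"] = json.dumps(self.ff.to_dict())
            f.attrs["params"] = json.dumps(self.params.to_dict())

    @classmethod
    def restore(cls, path) -> "Simulation":
        with h5py.File(path, "r") as f:
            pos = f["positions"][:]
            vel = f["velocities"][:]
            types = f["bead_types"][:]
            box = Box(f["box_lengths"][:],
                      f["box_periodic"][:].astype(bool))
            sha = hashlib.sha256()
            sha.update(np.ascontiguousarray(pos).tobytes())
            sha.update(np.ascontiguousarray(vel).tobytes())
            if sha.hexdigest() != f.attrs["checksum"]:
                raise CheckpointCorruptionError(f"checksum mismatch in {path}")
            topology = Topology.from_dict(json.loads(f.attrs["topology"]))
            ff = ForceField.from_dict(json.loads(f.attrs["forcefield"]))
            params = IntegratorParams.from_dict(json.loads(f.attrs["params"]))
            system = ParticleSystem(pos, vel, types, box,
                                    time=float(f.attrs["time"]))
            sim = cls(system, topology, ff, params)
            sim.step_index = int(f.attrs["step_index"])
            sim.partner_r[:] = f["partner_r"][:]
            sim.partner_l[:] = f["partner_l"][:]
            sim._tension_sum = float(f.attrs["tension_sum"])
            sim._tension_n = int(f.attrs["tension_n"])
            sim._compute_forces()
        return sim


# -- functional wrappers matching the operation-level API --------------------

def langevin_step(system: ParticleSystem, topology: Topology, ff: ForceField,
                  params: IntegratorParams, nlist=None) -> Simulation:
    """One Langevin step; returns the Simulation carrying the updated state.

    Convenience wrapper; loops should construct a :class:`Simulation` once
    and call :meth:`Simulation.step`.
    """
    sim = nlist if isinstance(nlist, Simulation) else Simulation(
        system, topology, ff, params)
    sim.step(1)
    return sim


def zero_tension_update(sim: Simulation) -> None:
    """Force one lateral box update from the accumulated tension samples."""
    if sim.topology.shape not in ("quasi_planar", "supported"):
        raise ConfigurationError(
            "zero-tension control requires a planar membrane system")
    if sim._tension_n == 0:
        sim.last_tension = sim.instantaneous_tension()
        sim._tension_sum += sim.last_tension
        sim._tension_n += 1
    sim._apply_zero_tension()


def assign_velocities(system: ParticleSystem, kBT: float, seed: int) -> None:
    """Draw Maxwell-Boltzmann velocities (m = 1) in place."""
    rng = np.random.default_rng(seed)
    system.velocities = rng.normal(
        0.0, math.sqrt(kBT), size=(system.n_beads, 3))
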