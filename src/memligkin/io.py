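"""File formats and configuration: XYZ/PDB writers for visualization, a
native HDF5 trajectory container, and the TOML run-configuration dialect
(keys carry their units in the name, e.g. ``k_bend_eps0``)."""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path

import h5py
import numpy as np

from .builders import BuildRecipe
from .dynamics import IntegratorParams
from .model import BEAD_TYPE_NAMES, Box, ForceField, ParticleSystem, Topology


class UnknownFormatError(ValueError):
    pass


class ConfigKeyError(ValueError):
    """An unrecognized key was found in a configuration file."""


# ---------------------------------------------------------------------------
# trajectory writers
# ---------------------------------------------------------------------------

def write_xyz(path, frames_positions, bead_types, comment: str = "") -> None:
    """Multi-frame XYZ with bead-type labels as element columns."""
    names = [BEAD_TYPE_NAMES[t] for t in bead_types]
    with open(path, "w") as f:
        for pos in frames_positions:
            f.write(f"{len(pos)}\n{comment}\n")
            for name, (x, y, z) in zip(names, pos):
                f.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


_PDB_ATOM_NAMES = {0: "HD", 1: "TL", 2: "TM", 3: "EC", 4: "SR", 5: "SL"}


def write_pdb(path, positions, topology: Topology, box: Box) -> None:
    """Single-frame PDB: one residue per molecule, CRYST1 box record."""
    pos = np.asarray(positions)
    lines = ["CRYST1" + "".join(f"{l:9.3f}" for l in box.lengths)
             + "  90.00  90.00  90.00 P 1           1"]
    serial = 1
    res = 1

    def atom(i, resname):
        nonlocal serial
        x, y, z = pos[i]
        name = _PDB_ATOM_NAMES[int(types[i])]
        lines.append(
            f"ATOM  {serial % 100000:5d} {name:<4s}{resname:<4s}A{res % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00")
        serial += 1

    types = topology_types(topology, len(pos))
    for trip in topology.lipids:
        for i in trip:
            atom(int(i), "LIP")
        res += 1
    for r in topology.receptors:
        for i in r.beads:
            atom(int(i), "REC")
        res += 1
    for l in topology.ligands:
        for i in l.beads:
            atom(int(i), "LIG")
        res += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def topology_types(topology: Topology, n: int) -> np.ndarray:
    """Reconstruct per-bead type labels from the topology."""
    from .model import ECD, HEAD, SITE_L, SITE_R, TAIL, TMD
    types = np.zeros(n, dtype=np.int8)
    for (h, t1, t2) in topology.lipids:
        types[h] = HEAD
        types[t1] = TAIL
        types[t2] = TAIL
    for r in topology.receptors:
        types[r.tmd] = TMD
        types[r.ecd] = ECD
        types[r.site] = SITE_R
    for l in topology.ligands:
        types[l.chain] = ECD
        types[l.site] = SITE_L
    return types


def write_native_trajectory(path, times, frames_positions, topology: Topology,
                            ff: ForceField, box: Box,
                            pair_bound=None) -> None:
    """Lossless container: positions, box, times, bound-pair registry."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=np.asarray(times, dtype=np.float64))
        f.create_dataset("positions",
                         data=np.asarray(frames_positions, dtype=np.float64))
        f.create_dataset("box_lengths", data=box.lengths)
        f.create_dataset("box_periodic", data=box.periodic.astype(np.uint8))
        if pair_bound is not None:
            f.create_dataset("pair_bound",
                             data=np.asarray(pair_bound, dtype=np.uint8))
        f.attrs["topology"] = json.dumps(topology.to_dict())
        f.attrs["forcefield"] = json.dumps(ff.to_dict())


def read_native_trajectory(path):
    """Returns (times, positions, topology, ff, box, pair_bound-or-None)."""
    with h5py.File(path, "r") as f:
        times = f["times"][:]
        positions = f["positions"][:]
        box = Box(f["box_lengths"][:], f["box_periodic"][:].astype(bool))
        topology = Topology.from_dict(json.loads(f.attrs["topology"]))
        ff = ForceField.from_dict(json.loads(f.attrs["forcefield"]))
        pair_bound = (f["pair_bound"][:].astype(bool)
                      if "pair_bound" in f else None)
    return times, positions, topology, ff, box, pair_bound


def write_trajectory(path, times, frames_positions, topology: Topology,
                     ff: ForceField, box: Box, format: str = "native",
                     pair_bound=None) -> None:
    """Dispatch on format in {xyz, pdb, native}."""
    if format == "xyz":
        types = topology_types(topology, np.asarray(frames_positions[0]).shape[0])
        write_xyz(path, frames_positions, types)
    elif format == "pdb":
        write_pdb(path, frames_positions[-1], topology, box)
    elif format == "native":
        write_native_trajectory(path, times, frames_positions, topology, ff,
                                box, pair_bound)
    else:
        raise UnknownFormatError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# section -> key -> (target field, default, description with units)
CONFIG_SCHEMA: dict[str, dict[str, tuple[str, object, str]]] = {
    "recipe": {
        "shape": ("shape", "quasi_planar",
                  "quasi_planar | supported | vesicle | soluble"),
        "membrane_area_sigma0sq": ("membrane_area", 270.0,
                                   "projected membrane area [sigma0^2]"),
        "vesicle_radius_sigma0": ("vesicle_radius", 15.0,
                                  "vesicle mid-bilayer radius [sigma0]"),
        "n_receptors": ("n_receptors", 0, "receptor count"),
        "n_ligands": ("n_ligands", 0, "ligand count"),
        "ecd_beads": ("ecd_beads", 6,
                      "chain beads per protein (site bead extra): 6 or 11"),
        "box_height_sigma0": ("box_height", 30.0,
                              "box height (planar) or cube edge (soluble) [sigma0]"),
        "area_per_lipid_sigma0sq": ("area_per_lipid", 1.2,
                                    "fluid-phase area per lipid [sigma0^2]"),
        "seed": ("seed", 0, "build RNG seed"),
        "kbt_eps0": ("kBT", 1.1, "thermal energy [epsilon0]"),
    },
    "forcefield": {
        "k_bend_eps0": ("k_bend", 10.0,
                        "chain bending stiffness [epsilon0]: 10 semirigid, 100 rigid"),
        "eps_bind_eps0": ("eps_bind", 14.0,
                          "site-site binding strength [epsilon0]"),
        "attr_wc_sigma0": ("attr_wc", 1.7,
                           "tail-attraction taper width [sigma0]"),
        "bind_rcut_sigma0": ("bind_rcut", 1.5,
                             "binding potential cutoff [sigma0]"),
        "theta0_rad": ("theta0", math.pi,
                       "preferred bond angle [rad] (pi = straight)"),
    },
    "integrator": {
        "dt_tau0": ("dt", 0.005, "time step [tau0]"),
        "gamma_invtau0": ("gamma", 1.0, "Langevin friction [1/tau0]"),
        "kbt_eps0": ("kBT", 1.1, "thermostat temperature [epsilon0]"),
        "seed": ("seed", 0, "thermostat RNG seed"),
        "tension_control": ("tension_control", "off", "off | zero_tension"),
        "barostat_interval_steps": ("barostat_interval", 50,
                                    "steps between lateral rescalings"),
        "barostat_gain": ("barostat_gain", 2e-3,
                          "rescaling response per unit tension"),
        "skin_sigma0": ("skin", 0.4, "Verlet skin [sigma0]"),
    },
    "run": {
        "n_steps": (None, 10000, "production steps"),
        "equilibration_steps": (None, 5000, "discarded steps before sampling"),
        "frame_stride": (None, 100, "steps between recorded frames"),
        "checkpoint_every": (None, 0, "steps between checkpoints (0 = off)"),
    },
    "rates": {
        "r_on_sigma0": (None, 1.2, "binding hysteresis threshold [sigma0]"),
        "r_off_sigma0": (None, 2.0, "unbinding hysteresis threshold [sigma0]"),
    },
}


def load_config(path) -> dict:
    """Parse and validate a TOML config against the schema; returns nested
    plain dicts with defaults filled in."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    out: dict[str, dict] = {}
    for section, content in raw.items():
        if section not in CONFIG_SCHEMA:
            raise ConfigKeyError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ConfigKeyError(f"section [{section}] must be a table")
        for key in content:
            if key not in CONFIG_SCHEMA[section]:
                raise ConfigKeyError(f"unknown key {key!r} in [{section}]")
        out[section] = dict(content)
    for section, keys in CONFIG_SCHEMA.items():
        out.setdefault(section, {})
        for key, (_field, default, _desc) in keys.items():
            out[section].setdefault(key, default)
    return out


def recipe_from_config(cfg: dict) -> BuildRecipe:
    kw = {CONFIG_SCHEMA["recipe"][k][0]: v for k, v in cfg["recipe"].items()}
    return BuildRecipe(**kw)


def forcefield_from_config(cfg: dict) -> ForceField:
    from .model import default_forcefield
    kw = {CONFIG_SCHEMA["forcefield"][k][0]: v
          for k, v in cfg["forcefield"].items()}
    return default_forcefield(**kw)


def integrator_from_config(cfg: dict) -> IntegratorParams:
    kw = {CONFIG_SCHEMA["integrator"][k][0]: v
          for k, v in cfg["integrator"].items()}
    return IntegratorParams(**kw)


def schema_lines() -> list[str]:
    """Human-readable listing of every config key with default and units."""
    lines = []
    for section, keys in CONFIG_SCHEMA.items():
        lines.append(f"[{section}]")
        for key, (_field, default, desc) in keys.items():
            lines.append(f"  {key} = {default!r}  # {desc}")
    return lines
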