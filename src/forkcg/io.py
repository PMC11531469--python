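"""Readers/writers and run configuration.

Structures come in as PDB (via Bio.PDB); coarse-grained models go out as a
documented JSON topology plus a pseudo-atom PDB (one atom per bead, bead
kind in the atom-name field).  Trajectories are DCD (via mdtraj) with a JSON
metadata sidecar.  All tables are TSV; iso-surface meshes are OBJ.
Coordinates are Å throughout; bead indices are 0-based internally and
residue/nucleotide numbering is 1-based in user-facing tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .dynamics import Trajectory
from .model import Bead, ChainRecord, Topology

logger = logging.getLogger("forkcg")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}: truncated record at line {ln}")
                try:
                    [float(line[c:c + 8]) for c in (30, 38, 46)]
                except ValueError as err:
                    raise ValueError(
                        f"{path}: unparseable coordinates at line {ln}") from err
                if line[26] != " ":
                    raise ValueError(
                        f"{path}: insertion code {line[26]!r} at line {ln} "
                        "not supported; renumber the structure")


def read_pdb(path, selection=None):
    """Parse a PDB file into a Bio.PDB structure.

    Alternate locations resolve to the highest-occupancy conformer; models
    beyond the first are ignored with a logged notice; insertion codes are
    rejected.  ``selection`` optionally restricts to a set of chain ids.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure.get_models())
    if len(models) > 1:
        logger.info("%s: %d models present; using the first", path, len(models))
        for m in models[1:]:
            structure.detach_child(m.id)
    if selection is not None:
        keep = set(selection)
        model = models[0]
        for ch in list(model.get_chains()):
            if ch.id not in keep:
                model.detach_child(ch.id)
    return structure


# ---------------------------------------------------------------------------
# CG topology JSON + pseudo-atom PDB
# ---------------------------------------------------------------------------

def topology_to_dict(top: Topology) -> dict:
    md = {}
    for k, v in top.metadata.items():
        md[k] = v.tolist() if isinstance(v, np.ndarray) else _plain(v)
    return {
        "format": "forkcg-topology",
        "version": 1,
        "beads": [{"index": b.index, "chain": b.chain_id, "kind": b.site_kind,
                   "name": b.name, "charge": b.charge, "radius": b.radius,
                   "resid": b.resid, "tags": sorted(b.group_tags)}
                  for b in top.beads],
        "chains": [{"id": c.chain_id, "class": c.molecule_class,
                    "start": c.start, "stop": c.stop} for c in top.chains],
        "bonds": [list(t) for t in top.bonds],
        "angles": [list(t) for t in top.angles],
        "dihedrals": [list(t) for t in top.dihedrals],
        "idr_ranges": {k: [list(s) for s in v]
                       for k, v in top.idr_ranges.items()},
        "metadata": md,
    }


def _plain(v):
    if isinstance(v, dict):
        return {k: _plain(x) for k, x in v.items()}
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    return v


def topology_from_dict(d: dict) -> Topology:
    if d.get("format") != "forkcg-topology":
        raise ValueError("not a forkcg topology document")
    top = Topology()
    for bd in d["beads"]:
        top.beads.append(Bead(bd["index"], bd["chain"], bd["kind"], bd["name"],
                              bd["charge"], bd["radius"], bd["resid"],
                              set(bd["tags"])))
    top.chains = [ChainRecord(c["id"], c["class"], c["start"], c["stop"])
                  for c in d["chains"]]
    top.bonds = [tuple(t) for t in d["bonds"]]
    top.angles = [tuple(t) for t in d["angles"]]
    top.dihedrals = [tuple(t) for t in d["dihedrals"]]
    top.idr_ranges = {k: [tuple(s) for s in v]
                      for k, v in d.get("idr_ranges", {}).items()}
    md = dict(d.get("metadata", {}))
    if "nt_from_junction" in md:
        md["nt_from_junction"] = np.asarray(md["nt_from_junction"], dtype=int)
    top.metadata = md
    top.validate()
    return top


def write_topology(top: Topology, path):
    Path(path).write_text(json.dumps(topology_to_dict(top), indent=1))


def read_topology(path) -> Topology:
    return topology_from_dict(json.loads(Path(path).read_text()))


_ATOM_NAME = {"residue": "CA", "base": "DB", "sugar": "DS", "phosphate": "DP"}
_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


def write_cg_pdb(top: Topology, coords, path):
    """One pseudo-atom per bead; bead kind in the atom-name field."""
    coords = np.asarray(coords, dtype=float)
    chain_map = {c.chain_id: _CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)]
                 for i, c in enumerate(top.chains)}
    lines = []
    serial = 1
    for b in top.beads:
        x, y, z = coords[b.index]
        resname = (b.name if len(b.name) <= 3 else b.name[:3]).rjust(3)
        lines.append(
            f"ATOM  {serial % 100000:5d} {_ATOM_NAME[b.site_kind]:<4s}"
            f"{resname} {chain_map[b.chain_id]}{b.resid % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories (DCD + JSON sidecar)
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path):
    """DCD (coordinates, Å) plus a ``<path>.json`` metadata sidecar."""
    from mdtraj.formats import DCDTrajectoryFile

    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(np.asarray(traj.frames, dtype=np.float32))
    sidecar = {"n_frames": int(traj.n_frames), "n_beads": int(traj.n_beads),
               "step_ids": traj.step_ids.tolist(),
               "metadata": _plain(traj.metadata)}
    if traj.potential_energies is not None:
        sidecar["potential_energies"] = np.asarray(traj.potential_energies).tolist()
    if traj.kinetic_energies is not None:
        sidecar["kinetic_energies"] = np.asarray(traj.kinetic_energies).tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trajectory(path, expected_n_beads=None) -> Trajectory:
    from mdtraj.formats import DCDTrajectoryFile

    path = Path(path)
    with DCDTrajectoryFile(str(path)) as fh:
        xyz, _, _ = fh.read()
    sidecar_path = path.with_suffix(path.suffix + ".json")
    md = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if md and md.get("n_frames") != len(xyz):
        raise ValueError("frame count mismatch between DCD and sidecar")
    if expected_n_beads is not None and xyz.shape[1] != expected_n_beads:
        raise ValueError(
            f"bead count mismatch: file has {xyz.shape[1]}, "
            f"expected {expected_n_beads}")
    step_ids = np.asarray(md.get("step_ids", np.arange(1, len(xyz) + 1)))
    pot = np.asarray(md["potential_energies"]) if "potential_energies" in md else None
    kin = np.asarray(md["kinetic_energies"]) if "kinetic_energies" in md else None
    return Trajectory(xyz.astype(float), step_ids, pot, kin,
                      md.get("metadata", {}))


def write_obj_mesh(vertices, faces, path):
    lines = [f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}" for v in vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "toy"                       # "toy" | "fork"
    toy: dict = Field(default_factory=dict)  # ToySpec overrides
    fork: dict = Field(default_factory=dict)
    sigma: dict = Field(default_factory=dict)      # contact label -> σ
    neutralize_tags: list = Field(default_factory=list)
    charge_overrides: list = Field(default_factory=list)


class DynamicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    timestep: float = 0.3
    temperature: float = 300.0
    friction: float = 0.843
    n_steps: int = 10000
    save_interval: int = 100
    replica_temperatures: list = Field(
        default_factory=lambda: [300.0 + 10 * i for i in range(4)])
    exchange_interval: int = 1000
    confinement_radius: float | None = None


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    contact_cutoff: float = 10.0
    n_dep: int = 30
    t_dep: int = 50
    n_tail: int = 5
    n_car: int = 10
    window: int = 200
    grid_spacing: float = 5.0
    iso_level: float = 1e-4


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "forkcg_out"


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    system: SystemConfig = Field(default_factory=SystemConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".toml"):
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def write_resolved(self, directory):
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        (out / "resolved_config.json").write_text(
            json.dumps(self.model_dump(), indent=1, sort_keys=True))
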