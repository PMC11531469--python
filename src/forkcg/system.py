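"""Packed simulation system: arrays compiled from a Topology for the kernels.

The per-pair nonbonded status is precomputed into a dense N×N mask (0 =
interacting, 1 = excluded from all nonbonded terms, 2 = excluded from the
excluded-volume term only).  1-2 and 1-3 bonded neighbours are fully
excluded; native-contact pairs are excluded from excluded volume because the
Gō well already encodes their short-range repulsion.  Dense masks keep the
kernels simple at the desk scale this package targets (≲ a few thousand
beads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .model import ChargeTable, ContactSet, Topology, assign_charges


@dataclass
class ElectrostaticParams:
    """Debye-Hückel settings (monovalent salt)."""

    ionic_strength: float = 0.3   # mol/L
    dielectric: float = 78.0
    temperature: float = 300.0    # K
    cutoff: float | None = 50.0   # Å; None disables truncation

    def __post_init__(self):
        if min(self.ionic_strength, self.dielectric, self.temperature) <= 0:
            raise ValueError("electrostatic parameters must be positive")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive (or None)")

    @property
    def debye_length(self) -> float:
        return units.debye_length(self.ionic_strength, self.dielectric,
                                  self.temperature)


@dataclass
class SphericalConfinement:
    """Half-harmonic wall outside a sphere, applied to all beads."""

    radius: float = 100.0
    k: float = 10.0  # kcal/mol/Å²
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class System:
    """Everything the force kernels need, as flat arrays."""

    topology: Topology
    coords0: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    # bonded
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_idx: np.ndarray
    ang_t0: np.ndarray
    ang_k: np.ndarray
    dih_idx: np.ndarray
    dih_p0: np.ndarray
    dih_k: np.ndarray
    # Gō contacts, packed over all sets
    contact_sets: list
    con_idx: np.ndarray
    con_r0: np.ndarray
    con_eps: np.ndarray
    con_set: np.ndarray
    con_sigma: np.ndarray  # one entry per set
    # nonbonded
    charges: ChargeTable
    nb_mask: np.ndarray
    eps_ev: float
    electrostatics: ElectrostaticParams
    # optional extras
    confinement: SphericalConfinement | None = None
    restraint_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    restraint_x0: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    restraint_k: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def set_sigma(self, label: str, sigma: float) -> "System":
        """Return a copy of self with the σ of one contact-set label changed."""
        import copy

        out = copy.copy(self)
        out.contact_sets = [cs.with_sigma(sigma) if cs.label == label else cs
                            for cs in self.contact_sets]
        out.con_sigma = np.array([cs.sigma for cs in out.contact_sets])
        return out

    def add_restraints(self, indices, x0, k):
        indices = np.atleast_1d(np.asarray(indices, dtype=np.int64))
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        k = np.broadcast_to(np.asarray(k, dtype=float), indices.shape).copy()
        self.restraint_idx = np.concatenate([self.restraint_idx, indices])
        self.restraint_x0 = np.vstack([self.restraint_x0, x0])
        self.restraint_k = np.concatenate([self.restraint_k, k])


def compile_system(topology: Topology, coords, contact_sets=(),
                   charges: ChargeTable | None = None,
                   electrostatics: ElectrostaticParams | None = None,
                   eps_ev: float = 0.6, masses=None,
                   confinement: SphericalConfinement | None = None,
                   neutralize_tags=()) -> System:
    """Build a :class:`System` from a topology plus contact sets and charges."""
    topology.validate()
    n = topology.n_beads
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n, 3):
        raise ValueError("coordinate array shape does not match topology")
    if charges is None:
        charges = assign_charges(topology, neutralize_tags=neutralize_tags)
    if masses is None:
        masses = np.full(n, units.DEFAULT_MASS)
    else:
        masses = np.broadcast_to(np.asarray(masses, dtype=float), (n,)).copy()

    def packed(terms, width):
        if not terms:
            return (np.zeros((0, width), dtype=np.int64), np.zeros(0), np.zeros(0))
        arr = np.asarray([t[:width] for t in terms], dtype=np.int64)
        ref = np.asarray([t[width] for t in terms], dtype=float)
        kk = np.asarray([t[width + 1] for t in terms], dtype=float)
        return arr, ref, kk

    bond_idx, bond_r0, bond_k = packed(topology.bonds, 2)
    ang_idx, ang_t0, ang_k = packed(topology.angles, 3)
    dih_idx, dih_p0, dih_k = packed(topology.dihedrals, 4)

    contact_sets = list(contact_sets)
    con = [(i, j, r0, e, s) for s, cs in enumerate(contact_sets)
           for i, j, r0, e in cs.pairs]
    if con:
        con_idx = np.asarray([c[:2] for c in con], dtype=np.int64)
        con_r0 = np.asarray([c[2] for c in con])
        con_eps = np.asarray([c[3] for c in con])
        con_set = np.asarray([c[4] for c in con], dtype=np.int64)
    else:
        con_idx = np.zeros((0, 2), dtype=np.int64)
        con_r0 = con_eps = np.zeros(0)
        con_set = np.zeros(0, dtype=np.int64)
    con_sigma = np.array([cs.sigma for cs in contact_sets]) if contact_sets \
        else np.zeros(0)

    nb_mask = _build_mask(n, bond_idx, ang_idx, con_idx)
    return System(
        topology=topology, coords0=coords, masses=masses,
        radii=topology.radii(),
        bond_idx=bond_idx, bond_r0=bond_r0, bond_k=bond_k,
        ang_idx=ang_idx, ang_t0=ang_t0, ang_k=ang_k,
        dih_idx=dih_idx, dih_p0=dih_p0, dih_k=dih_k,
        contact_sets=contact_sets, con_idx=con_idx, con_r0=con_r0,
        con_eps=con_eps, con_set=con_set, con_sigma=con_sigma,
        charges=charges, nb_mask=nb_mask, eps_ev=float(eps_ev),
        electrostatics=electrostatics or ElectrostaticParams(),
        confinement=confinement)


def _build_mask(n, bond_idx, ang_idx, con_idx):
    mask = np.zeros((n, n), dtype=np.int8)
    for i, j in bond_idx:
        mask[i, j] = mask[j, i] = 1
    for i, j, k in ang_idx:
        mask[i, k] = mask[k, i] = 1
    for i, j in con_idx:
        if mask[i, j] == 0:
            mask[i, j] = mask[j, i] = 2  # skip excluded volume only
    np.fill_diagonal(mask, 1)
    return mask
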