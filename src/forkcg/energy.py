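"""Potential-energy terms and exact analytic forces.

The structure-based (Gō-like) attraction between bead pairs ``(i, j)`` with
native distance ``r0`` is

    V = σ Σ_ij ε_ij [5 (r0/r)^12 − 6 (r0/r)^10],

minimised at the native distance (value −σ ε per pair).  Electrostatics are
screened-Coulomb (Debye-Hückel) with context-dependent DNA phosphate charges;
excluded volume is a purely repulsive (d/r)^12 term truncated and shifted at
the contact distance d = r_i + r_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, units
from .model import ChargeTable, ContactSet
from .system import ElectrostaticParams, System

_EMPTY_I = np.zeros((0, 2), dtype=np.int64)
_EMPTY_I3 = np.zeros((0, 3), dtype=np.int64)
_EMPTY_I4 = np.zeros((0, 4), dtype=np.int64)
_EMPTY_F = np.zeros(0)
_EMPTY_R = np.zeros(0, dtype=np.int64)
_EMPTY_X = np.zeros((0, 3))
_ZERO3 = np.zeros(3)


@dataclass
class EnergyBreakdown:
    """Per-term potential energies, kcal/mol.  ``go_native`` is keyed by
    contact-set label; ``total`` equals the sum of all components."""

    bonded: float = 0.0
    go_native: dict = field(default_factory=dict)
    excluded_volume: float = 0.0
    electrostatic: float = 0.0
    confinement: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bonded + sum(self.go_native.values())
                + self.excluded_volume + self.electrostatic
                + self.confinement + self.restraint)

    def as_rows(self):
        rows = [("bonded", self.bonded)]
        rows += [(f"go_native[{k}]", v) for k, v in self.go_native.items()]
        rows += [("excluded_volume", self.excluded_volume),
                 ("electrostatic", self.electrostatic),
                 ("confinement", self.confinement),
                 ("restraint", self.restraint),
                 ("total", self.total)]
        return rows

    def to_table(self) -> str:
        lines = ["term\tenergy_kcal_mol"]
        lines += [f"{name}\t{val:.10g}" for name, val in self.as_rows()]
        return "\n".join(lines) + "\n"


def go_energy(coords, contact_set: ContactSet):
    """Gō energy and forces of one contact set."""
    coords = np.ascontiguousarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    if len(contact_set) == 0:
        return 0.0, forces
    idx = np.asarray([p[:2] for p in contact_set.pairs], dtype=np.int64)
    r0 = np.asarray([p[2] for p in contact_set.pairs])
    eps = np.asarray([p[3] for p in contact_set.pairs])
    setid = np.zeros(len(idx), dtype=np.int64)
    e_go = np.zeros(1)
    _kernels._go_forces(coords, forces, idx, r0, eps, setid,
                        np.array([contact_set.sigma]), e_go)
    return float(e_go[0]), forces


def debye_huckel_energy(coords, charges: ChargeTable,
                        params: ElectrostaticParams | None = None,
                        exclusion_mask=None, shift=True):
    """Screened-Coulomb energy and forces.

    ``U = Σ C q_i q_j exp(−r/λ_D)/(ε_r r)`` with the phosphate charge chosen
    per interaction-partner class, over all pairs not excluded by
    ``exclusion_mask`` (an N×N int8 array; nonzero entries skipped).  With
    ``params.cutoff`` set, interactions beyond the cutoff vanish and, if
    ``shift``, the energy is shifted to zero there.
    """
    params = params or ElectrostaticParams()
    coords = np.ascontiguousarray(coords, dtype=float)
    n = len(coords)
    forces = np.zeros_like(coords)
    mask = (np.zeros((n, n), dtype=np.int8) if exclusion_mask is None
            else np.where(np.asarray(exclusion_mask) != 0, 1, 0).astype(np.int8))
    np.fill_diagonal(mask, 1)
    kappa = 1.0 / params.debye_length
    ke_eff = units.COULOMB / params.dielectric
    cutoff = -1.0 if params.cutoff is None else float(params.cutoff)
    _, e_dh = _kernels._nonbonded_forces(
        coords, forces, charges.q_intra, charges.q_cross,
        charges.is_dna.astype(np.int8), np.zeros(n), mask,
        kappa, ke_eff, cutoff, shift, 0.0)
    return float(e_dh), forces


def excluded_volume_energy(coords, radii, eps_ev=0.6, exclusion_mask=None):
    """Purely repulsive excluded-volume energy and forces."""
    coords = np.ascontiguousarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    n = len(coords)
    forces = np.zeros_like(coords)
    mask = (np.zeros((n, n), dtype=np.int8) if exclusion_mask is None
            else np.asarray(exclusion_mask, dtype=np.int8).copy())
    np.fill_diagonal(mask, 1)
    e_ev, _ = _kernels._nonbonded_forces(
        coords, forces, np.zeros(n), np.zeros(n), np.zeros(n, dtype=np.int8),
        radii, mask, 1.0, 0.0, -1.0, False, float(eps_ev))
    return float(e_ev), forces


def _kernel_args(system: System):
    es = system.electrostatics
    conf = system.confinement
    return dict(
        bond_idx=system.bond_idx, bond_r0=system.bond_r0, bond_k=system.bond_k,
        ang_idx=system.ang_idx, ang_t0=system.ang_t0, ang_k=system.ang_k,
        dih_idx=system.dih_idx, dih_p0=system.dih_p0, dih_k=system.dih_k,
        con_idx=system.con_idx, con_r0=system.con_r0, con_eps=system.con_eps,
        con_set=system.con_set,
        con_sigma=system.con_sigma if len(system.con_sigma) else _EMPTY_F,
        q_intra=system.charges.q_intra, q_cross=system.charges.q_cross,
        is_dna=system.charges.is_dna.astype(np.int8),
        radii=system.radii, nb_mask=system.nb_mask,
        kappa=1.0 / es.debye_length, ke_eff=units.COULOMB / es.dielectric,
        dh_cutoff=-1.0 if es.cutoff is None else float(es.cutoff),
        dh_shift=True, eps_ev=system.eps_ev,
        conf_on=conf is not None,
        conf_center=np.asarray(conf.center, dtype=float) if conf else _ZERO3,
        conf_radius=conf.radius if conf else 0.0,
        conf_k=conf.k if conf else 0.0,
        restraint_idx=system.restraint_idx,
        restraint_x0=system.restraint_x0,
        restraint_k=system.restraint_k,
    )


def total_energy_forces(coords, system: System):
    """Total potential energy (broken down by term) and its exact negative
    gradient.  Raises if any term evaluates to a non-finite value."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError("coordinate shape does not match system")
    forces = np.zeros_like(coords)
    n_sets = max(len(system.contact_sets), 1)
    e_go = np.zeros(n_sets)
    args = _kernel_args(system)
    terms = _kernels.compute_forces(coords, forces, e_go=e_go, **args)
    names = ("bond", "angle", "dihedral", "excluded_volume", "electrostatic",
             "confinement", "restraint")
    for name, val in zip(names, terms):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite energy in term {name!r}")
    go = {}
    for s, cs in enumerate(system.contact_sets):
        if not np.isfinite(e_go[s]):
            raise FloatingPointError(
                f"non-finite energy in contact set {cs.label!r}")
        go[cs.label] = go.get(cs.label, 0.0) + float(e_go[s])
    if not np.isfinite(forces).all():
        bad = np.argwhere(~np.isfinite(forces))[0]
        raise FloatingPointError(f"non-finite force on bead {int(bad[0])}")
    breakdown = EnergyBreakdown(
        bonded=float(terms[0] + terms[1] + terms[2]), go_native=go,
        excluded_volume=float(terms[3]), electrostatic=float(terms[4]),
        confinement=float(terms[5]), restraint=float(terms[6]))
    return breakdown, forces


def numerical_gradient(coords, system: System, h=1e-4):
    """Central-difference gradient of the total energy (test oracle)."""
    coords = np.array(coords, dtype=float)
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            coords[i, d] += h
            ep, _ = total_energy_forces(coords, system)
            coords[i, d] -= 2 * h
            em, _ = total_energy_forces(coords, system)
            coords[i, d] += h
            grad[i, d] = (ep.total - em.total) / (2 * h)
    return grad
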