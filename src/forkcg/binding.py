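"""Q-scores, bound-state classification, binding free energies and σ
calibration.

The fraction of native contacts Q counts a pair as formed when its distance
is within 1.2× the native distance.  The bound state is Q > 0 (even partial
native-contact formation implies binding) or, alternatively, a minimum
inter-molecular distance below a cutoff.  The standard-state binding free
energy from a run confined to a sphere is

    ΔG° = −k_B T ln[(P_b/P_u) · (V_free/V°)],

with V° = 1661 Å³ (1 M) and V_free the confinement volume accessible to the
unbound ligand; the volume correction is reported separately so either
convention is recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .dynamics import LangevinParams, REMDResult, ReplicaSchedule, Trajectory, run_remd
from .model import ContactSet


@dataclass
class BoundStateCriterion:
    mode: str = "q_positive"          # or "min_distance"
    distance_cutoff: float = 10.0     # Å, used in min_distance mode

    def __post_init__(self):
        if self.mode not in ("q_positive", "min_distance"):
            raise ValueError(f"unknown bound-state mode {self.mode!r}")
        if self.mode == "min_distance" and self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass
class BindingEstimate:
    delta_G: float                 # kcal/mol, standard state
    standard_error: float
    bound_fraction: float
    n_effective: int               # frames analysed
    volume_correction: float       # −k_BT ln(V_free/V°), included in delta_G
    n_transitions: int = 0
    few_transitions: bool = False

    def __post_init__(self):
        if not (0.0 <= self.bound_fraction <= 1.0):
            raise ValueError("bound fraction must lie in [0, 1]")
        if self.standard_error < 0:
            raise ValueError("standard error must be non-negative")


def q_score(coords, native_cross_contacts: ContactSet,
            formed_ratio: float = 1.2) -> float:
    """Fraction of native contacts formed (r < ``formed_ratio`` × r0)."""
    if len(native_cross_contacts) == 0:
        raise ValueError("native contact set is empty")
    coords = np.asarray(coords, dtype=float)
    formed = 0
    for i, j, r0, _ in native_cross_contacts.pairs:
        r = np.linalg.norm(coords[i] - coords[j])
        if r < formed_ratio * r0:
            formed += 1
    return formed / len(native_cross_contacts)


def min_intermolecular_distance(coords, groups) -> float:
    from scipy.spatial import cKDTree

    a, b = (np.asarray(g, dtype=int) for g in groups)
    coords = np.asarray(coords, dtype=float)
    d, _ = cKDTree(coords[a]).query(coords[b])
    return float(d.min())


def _groups_from_contacts(contacts: ContactSet):
    a = sorted({i for i, _, _, _ in contacts.pairs})
    b = sorted({j for _, j, _, _ in contacts.pairs})
    return np.asarray(a), np.asarray(b)


def classify_bound(coords, criterion: BoundStateCriterion,
                   contacts: ContactSet, groups=None) -> bool:
    """Bound iff Q > 0 (``q_positive``) or the minimum inter-molecular bead
    distance is below the cutoff (``min_distance``)."""
    if criterion.mode == "q_positive":
        return q_score(coords, contacts) > 0.0
    if groups is None:
        groups = _groups_from_contacts(contacts)
    return min_intermolecular_distance(coords, groups) < criterion.distance_cutoff


def accessible_volume(sphere_radius: float, receptor_coords=None) -> float:
    """Confinement volume accessible to the unbound ligand: the sphere minus
    an excluded core from the receptor's bounding sphere about its COM."""
    v_sphere = 4.0 / 3.0 * math.pi * sphere_radius**3
    if receptor_coords is None or len(receptor_coords) == 0:
        return v_sphere
    rc = np.asarray(receptor_coords, dtype=float)
    core = float(np.linalg.norm(rc - rc.mean(axis=0), axis=1).max())
    core = min(core, sphere_radius)
    return v_sphere - 4.0 / 3.0 * math.pi * core**3


def estimate_binding_free_energy(remd_output, criterion: BoundStateCriterion,
                                 contacts: ContactSet,
                                 analysis_temperature: float = 300.0,
                                 sphere_radius: float = 100.0,
                                 standard_volume: float = units.STANDARD_VOLUME,
                                 groups=None, receptor_indices=None,
                                 v_free=None, n_blocks=10) -> BindingEstimate:
    """Binding free energy from the bound/unbound populations of the replica
    at (or nearest to) the analysis temperature.

    Errors are estimated by block averaging over ``n_blocks`` blocks with a
    half-count continuity correction inside each block; the number of
    bound↔unbound transitions is counted and, below 5, flagged.
    """
    if isinstance(remd_output, REMDResult):
        temps = np.asarray(remd_output.schedule.temperatures)
        t_idx = int(np.argmin(np.abs(temps - analysis_temperature)))
        traj = remd_output.trajectories[t_idx]
        temperature = float(temps[t_idx])
    elif isinstance(remd_output, Trajectory):
        traj = remd_output
        temperature = analysis_temperature
    else:
        raise TypeError("expected REMDResult or Trajectory")

    bound = np.array([classify_bound(f, criterion, contacts, groups)
                      for f in traj.frames])
    n = len(bound)
    n_b = int(bound.sum())
    n_u = n - n_b
    if n_b == 0 or n_u == 0:
        raise ValueError("state unsampled: need both bound and unbound frames")
    transitions = int(np.sum(bound[1:] != bound[:-1]))

    if v_free is None:
        rec = (traj.frames[0][np.asarray(receptor_indices, dtype=int)]
               if receptor_indices is not None else None)
        v_free = accessible_volume(sphere_radius, rec)
    kbt = units.KB * temperature
    vol_corr = -kbt * math.log(v_free / standard_volume)
    dg = -kbt * math.log(n_b / n_u) + vol_corr

    block_vals = []
    for blk in np.array_split(bound, n_blocks):
        bb = blk.sum() + 0.5
        bu = (len(blk) - blk.sum()) + 0.5
        block_vals.append(-kbt * math.log(bb / bu) + vol_corr)
    se = float(np.std(block_vals, ddof=1) / math.sqrt(len(block_vals)))
    return BindingEstimate(delta_G=float(dg), standard_error=se,
                           bound_fraction=n_b / n, n_effective=n,
                           volume_correction=float(vol_corr),
                           n_transitions=transitions,
                           few_transitions=transitions < 5)


@dataclass
class CalibrationProtocol:
    """REMD + estimation settings reused for every σ on the grid."""

    schedule: ReplicaSchedule
    langevin: LangevinParams
    criterion: BoundStateCriterion = field(default_factory=BoundStateCriterion)
    analysis_temperature: float = 300.0
    sphere_radius: float = 100.0
    standard_volume: float = units.STANDARD_VOLUME


def calibrate_sigma(system_builder, sigma_grid, target_delta_G,
                    protocol: CalibrationProtocol):
    """Scan σ: run the REMD + free-energy protocol per grid value and select
    the σ whose ΔG lies closest to the target.

    ``system_builder(sigma)`` must return ``(system, cross_contacts, groups,
    receptor_indices)``.  Returns ``(selected_sigma, table)`` where ``table``
    is a DataFrame with one row per σ (ΔG, SE, bound fraction, transitions).
    """
    sigma_grid = list(sigma_grid)
    if not sigma_grid:
        raise ValueError("sigma grid is empty")
    rows = []
    for sigma in sigma_grid:
        system, contacts, groups, receptor = system_builder(sigma)
        result = run_remd(system, protocol.schedule, protocol.langevin)
        est = estimate_binding_free_energy(
            result, protocol.criterion, contacts,
            analysis_temperature=protocol.analysis_temperature,
            sphere_radius=protocol.sphere_radius,
            standard_volume=protocol.standard_volume,
            groups=groups, receptor_indices=receptor)
        rows.append({"sigma": sigma, "delta_G": est.delta_G,
                     "standard_error": est.standard_error,
                     "bound_fraction": est.bound_fraction,
                     "n_transitions": est.n_transitions,
                     "few_transitions": est.few_transitions})
    table = pd.DataFrame(rows)
    best = int((table["delta_G"] - target_delta_G).abs().idxmin())
    return float(table.loc[best, "sigma"]), table
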