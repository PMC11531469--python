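"""Desk-scale synthetic systems carrying the statistical structure the fork
analyses assume.

The toy replisome is *not* a structural model of the real machine: it is a
ring-shaped multi-chain hub with a flexible positively charged tail carrying
a basic globular cargo, a carrier chain with an acidic loop, forked DNA with
configurable arms/gaps, and optional ssDNA-occluding binders.  Tags mirror
the real-system labels (hub_ring, donor_tail, carrier, cargo, *_duplex,
*_ssDNA) so every analysis runs unchanged on toy and real systems.

Labeled trajectories are scripted (kinematic, not dynamical): the cargo
follows piecewise paths that satisfy or violate the recycling classifier's
defining events by construction with ≥20% margin, so classifier tests are
exact and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import ClassifierThresholds, RecyclingOutcome
from .dynamics import Trajectory
from .model import (CGStructure, ChainRecord, ContactSet, Topology,
                    assemble_fork, derive_native_contacts,
                    duplex_stabilization_contacts, PROTEIN_RADIUS,
                    K_BOND, K_ANGLE, K_ANGLE_IDR, THETA0_IDR, _angle)
from .system import ElectrostaticParams, SphericalConfinement, System, compile_system

RING_RADIUS = 53.0        # mean hub-ring radius, Å
RING_ROW_OFFSET = 3.0     # radial/axial half-spacing of the bead rows


@dataclass
class ToySpec:
    ring_chains: int = 6
    chain_length: int = 60
    tail_length: int = 80
    carrier_length: int = 30       # includes the acidic loop
    carrier_loop_length: int = 16
    cargo_helices: int = 4
    cargo_helix_length: int = 15
    fork_parental_bp: int = 10
    fork_arm_bp: int = 14
    leading_gap_nt: int = 5
    lagging_gap_nt: int = 4        # lengthened by 5 nt per binder
    binder_count: int = 0
    binder_length: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("ring_chains", "chain_length", "tail_length",
                     "carrier_length", "cargo_helices", "cargo_helix_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.binder_count <= 2):
            raise ValueError("binder_count must be 0, 1 or 2")


@dataclass
class ToyReplisome:
    topology: Topology
    coords: np.ndarray
    contact_sets: list
    spec: ToySpec

    def system(self, neutralize_tags=(), confinement=None,
               electrostatics=None) -> System:
        return compile_system(self.topology, self.coords, self.contact_sets,
                              electrostatics=electrostatics,
                              confinement=confinement,
                              neutralize_tags=neutralize_tags)


def _tail_residue_name(i):
    if i % 5 == 0:
        return "K"
    if i % 11 == 0:
        return "E"
    return "S"


def _add_native_chain(top, coords, points, chain_id, names, tags,
                      molecule_class="protein", flexible=False):
    """Append a protein chain with native-anchored (or flexible) local terms."""
    start = top.n_beads
    for i, p in enumerate(points):
        top.add_bead(chain_id, "residue", names[i], 0.0, PROTEIN_RADIUS,
                     i + 1, tags)
        coords.append(np.asarray(p, dtype=float))
    top.chains.append(ChainRecord(chain_id, molecule_class, start, top.n_beads))
    pts = np.asarray(points)
    for i in range(len(pts) - 1):
        r0 = float(np.linalg.norm(pts[i + 1] - pts[i]))
        top.add_bond(start + i, start + i + 1, r0, K_BOND)
    for i in range(len(pts) - 2):
        if flexible:
            top.add_angle(start + i, start + i + 1, start + i + 2,
                          THETA0_IDR, K_ANGLE_IDR)
        else:
            t0 = _angle(pts[i], pts[i + 1], pts[i + 2])
            top.add_angle(start + i, start + i + 1, start + i + 2, t0, K_ANGLE)
    return start


def _ring_points(n_chains, chain_length):
    """Annular hub: each chain fills one angular sector, serpentining
    through four bead rows (two radii × two z levels) so no non-bonded
    pair comes closer than the bead contact distance."""
    d = RING_ROW_OFFSET
    rows = [(RING_RADIUS - d, -d), (RING_RADIUS + d, -d),
            (RING_RADIUS + d, d), (RING_RADIUS - d, d)]
    per_row = max(chain_length // 4, 1)
    sector = 2 * math.pi / n_chains
    pts = []
    for c in range(n_chains):
        theta0 = c * sector
        k = 0
        for r, (rho, z) in enumerate(rows):
            n_here = per_row if r < 3 else chain_length - 3 * per_row
            for s in range(n_here):
                frac = (s + 0.5) / n_here if r % 2 == 0 \
                    else (n_here - 0.5 - s) / n_here
                a = theta0 + frac * sector * 0.96
                pts.append((rho * math.cos(a), rho * math.sin(a), z))
                k += 1
    return np.asarray(pts)


def _helix(n, origin, axis_z=True, radius=2.3, rise=1.5, turn_deg=100.0,
           phase=0.0):
    pts = []
    for i in range(n):
        a = math.radians(turn_deg * i + phase)
        pts.append((radius * math.cos(a), radius * math.sin(a), rise * i))
    pts = np.asarray(pts)
    return pts + np.asarray(origin, dtype=float)


def _cargo_points(spec):
    """A compact 4-helix-bundle mimic centred at the origin."""
    offsets = [(4.5, 4.5), (-4.5, 4.5), (-4.5, -4.5), (4.5, -4.5)]
    segs = []
    for h in range(spec.cargo_helices):
        ox, oy = offsets[h % 4]
        seg = _helix(spec.cargo_helix_length, (ox, oy, 0.0),
                     phase=90.0 * h)
        if h % 2 == 1:
            seg = seg[::-1]  # antiparallel packing
        segs.append(seg)
    pts = np.concatenate(segs)
    return pts - pts.mean(axis=0)


def _cargo_names(n):
    names = []
    for i in range(n):
        if i % 3 == 0:
            names.append("K")
        elif i % 7 == 0:
            names.append("R")
        else:
            names.append("A")
    return names


def _rising_coil(anchor, n, step=3.8, dz=1.8, radius=6.0):
    """Deterministic gentle coil rising in +z from an anchor point."""
    chord = math.sqrt(step**2 - dz**2)
    omega = 2.0 * math.asin(min(1.0, chord / (2 * radius)))
    pts = []
    for i in range(1, n + 1):
        a = omega * i
        pts.append((anchor[0] + radius * (math.cos(a) - 1.0),
                    anchor[1] + radius * math.sin(a),
                    anchor[2] + dz * i))
    return np.asarray(pts)


def build_toy_replisome(spec: ToySpec | None = None) -> ToyReplisome:
    """Deterministic toy replisome; same seed ⇒ identical coordinates."""
    spec = spec or ToySpec()
    rng = np.random.default_rng(spec.seed)
    top = Topology()
    coords: list = []

    # hub ring: n_chains consecutive arcs of a solenoid in the z≈0 plane
    ring = _ring_points(spec.ring_chains, spec.chain_length)
    for c in range(spec.ring_chains):
        seg = ring[c * spec.chain_length:(c + 1) * spec.chain_length]
        tags = {"hub_ring"}
        if c == 0:
            tags = {"hub_ring", "donor_hub"}
        _add_native_chain(top, coords, seg, f"RING{c}",
                          ["A"] * len(seg), tags)

    # donor tail: flexible charged coil anchored on the donor hub chain
    anchor = ring[spec.chain_length // 2] + np.array([0.0, 0.0, 4.0])
    tail_pts = _rising_coil(anchor, spec.tail_length)
    tail_names = [_tail_residue_name(i) for i in range(spec.tail_length)]
    tail_start = _add_native_chain(top, coords, tail_pts, "TAIL", tail_names,
                                   {"donor_tail"}, flexible=True)
    n_tip = min(20, spec.tail_length)
    tip = np.arange(tail_start + spec.tail_length - n_tip,
                    tail_start + spec.tail_length)
    top.tag_beads(tip, "donor_tail_tip")
    anchor_bead = spec.chain_length // 2
    r0 = float(np.linalg.norm(tail_pts[0] - ring[anchor_bead]))
    top.add_bond(anchor_bead, tail_start, r0, K_BOND)

    # carrier: small folded knob plus an acidic flexible loop, off to +x
    carrier_origin = np.array([RING_RADIUS + 22.0, 0.0, 14.0])
    knob_n = spec.carrier_length - spec.carrier_loop_length
    knob = _helix(knob_n, carrier_origin)
    loop = _rising_coil(knob[-1], spec.carrier_loop_length, dz=1.2, radius=4.0)
    carrier_pts = np.vstack([knob, loop])
    names = (["A"] * knob_n
             + [("D" if i % 2 else "E") for i in range(spec.carrier_loop_length)])
    cstart = _add_native_chain(top, coords, carrier_pts, "CARR", names,
                               {"carrier"}, flexible=False)
    top.tag_beads(np.arange(cstart + knob_n, cstart + spec.carrier_length),
                  "carrier_loop")

    # cargo: basic 4-helix bundle docked at the tail tip
    cargo_local = _cargo_points(spec)
    cargo_pose = tail_pts[-1] + np.array([6.0, 0.0, 6.0])
    cargo_pts = cargo_local + cargo_pose
    cargo_start = _add_native_chain(
        top, coords, cargo_pts, "CARGO",
        _cargo_names(len(cargo_pts)), {"cargo"})

    # forked DNA hanging below the ring
    lag_gap = spec.lagging_gap_nt + 5 * spec.binder_count
    fork = assemble_fork(spec.fork_parental_bp, spec.fork_arm_bp,
                         spec.fork_arm_bp, spec.leading_gap_nt, lag_gap,
                         seed=spec.seed)
    # junction far enough below the hub that the upward-tilted daughter
    # arms clear the ring annulus
    shift = np.array([0.0, 0.0, -60.0])
    fork_off = top.n_beads
    protein = CGStructure(top, np.asarray(coords))
    merged = protein.topology.merge(fork.topology)
    merged_coords = np.vstack([protein.coords, fork.coords + shift])
    merged.metadata["junction_bead"] = fork.topology.metadata["junction_bead"] + fork_off
    ntj = np.full(merged.n_beads, -1, dtype=int)
    ntj[fork_off:] = fork.topology.metadata["nt_from_junction"]
    merged.metadata["nt_from_junction"] = ntj
    top, coords = merged, merged_coords

    # optional ssDNA-occluding binders on the lagging gap
    if spec.binder_count:
        ss = top.select("lagging_ssDNA")
        order = np.argsort([top.beads[i].resid for i in ss])
        sites = coords[ss[order]]
        for b in range(spec.binder_count):
            seg = sites[len(sites) * b // spec.binder_count:
                        len(sites) * (b + 1) // spec.binder_count]
            centre = seg.mean(axis=0) + np.array([0.0, 8.0, 0.0])
            pts = _helix(spec.binder_length, centre)
            cl: list = list(coords)
            _add_native_chain(top, cl, pts, f"BND{b}", ["R", "K"] * (spec.binder_length // 2),
                              {"binder"})
            coords = np.asarray(cl)
        ntj = np.concatenate([top.metadata["nt_from_junction"],
                              np.full(top.n_beads - len(top.metadata["nt_from_junction"]), -1, dtype=int)])
        top.metadata["nt_from_junction"] = ntj

    coords = np.asarray(coords)
    # native contact sets: ring fold, cargo fold, carrier knob, cargo↔tail tip
    sets = []
    ring_idx = top.select("hub_ring")
    sets.append(derive_native_contacts(top, coords, cutoff=6.5, label="ring_fold",
                                       groups=(ring_idx, ring_idx)))
    cargo_idx = top.select("cargo")
    sets.append(derive_native_contacts(top, coords, cutoff=6.5,
                                       label="cargo_fold",
                                       groups=(cargo_idx, cargo_idx)))
    tip_idx = top.select("donor_tail_tip")
    cross = derive_native_contacts(top, coords, cutoff=10.0,
                                   label="cargo_tail",
                                   groups=(cargo_idx, tip_idx), min_seq_sep=0)
    sets.append(cross)
    sets.extend(cs.shifted(fork_off) for cs in fork.contact_sets)
    top.validate()
    return ToyReplisome(top, coords, sets, spec)


def build_toy_ring(n_chains=6, chain_length=60) -> System:
    """Hub ring alone, compiled: the standard small system for integrator /
    thermostat validation runs."""
    top = Topology()
    coords: list = []
    ring = _ring_points(n_chains, chain_length)
    for c in range(n_chains):
        seg = ring[c * chain_length:(c + 1) * chain_length]
        _add_native_chain(top, coords, seg, f"RING{c}", ["A"] * len(seg),
                          {"hub_ring"})
    coords = np.asarray(coords)
    idx = np.arange(top.n_beads)
    cs = derive_native_contacts(top, coords, cutoff=6.5, label="ring_fold",
                                groups=(idx, idx))
    return compile_system(top, coords, [cs])


# ---------------------------------------------------------------------------
# dimer benchmark
# ---------------------------------------------------------------------------

@dataclass
class DimerBenchmark:
    system: System
    contacts: ContactSet
    receptor_indices: np.ndarray
    ligand_indices: np.ndarray
    native_coords: np.ndarray

    def with_sigma(self, sigma) -> "DimerBenchmark":
        return replace(self, system=self.system.set_sigma("cross", sigma))


def build_dimer_benchmark(n_contacts=6, well_geometry="face", seed=0,
                          sigma=1.0, eps=1.5, sphere_radius=30.0,
                          mass=None) -> DimerBenchmark:
    """A designed two-chain binding system whose ΔG(σ) is measurable in
    minutes of REMD.

    The receptor is an open octahedral cage tethered at the confinement
    centre; the single-bead ligand chain docks at the cage centre, where all
    ``n_contacts`` designed contacts form simultaneously (well depth
    σ·n·ε).  At σ = 0 the chains are free; large σ (≥ 2) pins the bound
    state.
    """
    if n_contacts < 1:
        raise ValueError("need at least one contact")
    rng = np.random.default_rng(seed)
    top = Topology()
    coords: list = []
    # receptor: an open dish pocket (5-bead ring plus a bottom bead).  The
    # docked pose sits on the dish axis where every designed contact forms
    # at once, and the approach from above crosses no repulsive core.
    ring_r, dock = 5.0, np.array([0.0, 0.0, 1.0])
    ang = 2 * math.pi * np.arange(5) / 5
    rec = np.concatenate([
        np.stack([ring_r * np.cos(ang), ring_r * np.sin(ang),
                  np.zeros(5)], axis=1),
        [[0.0, 0.0, -4.0]]])
    if well_geometry != "face":  # wider, shallower dish
        rec[:5, :2] *= 1.4
    rec += rng.normal(scale=0.05, size=rec.shape)
    rec_start = _add_native_chain(top, coords, rec, "REC", ["A"] * len(rec),
                                  {"receptor"})
    lig = dock + rng.normal(scale=0.05, size=3)
    lig_start = top.add_bead("LIG", "residue", "A", 0.0, PROTEIN_RADIUS, 1,
                             {"ligand"})
    coords.append(lig)
    top.chains.append(ChainRecord("LIG", "protein", lig_start, lig_start + 1))
    coords = np.asarray(coords)
    rec_idx = np.arange(rec_start, rec_start + len(rec))
    lig_idx = np.array([lig_start])
    cross = derive_native_contacts(top, coords, cutoff=15.0, label="cross",
                                   groups=(rec_idx, lig_idx), min_seq_sep=0,
                                   eps_rule=lambda x, y: eps)
    order = np.argsort([p[2] for p in cross.pairs])[:n_contacts]
    cross = ContactSet([cross.pairs[i] for i in order], sigma=sigma,
                       label="cross")
    system = compile_system(
        top, coords, [cross],
        electrostatics=ElectrostaticParams(),
        confinement=SphericalConfinement(radius=sphere_radius,
                                         center=coords[rec_idx].mean(axis=0)),
        masses=mass)
    system.add_restraints(rec_idx, coords[rec_idx], 2.0)
    return DimerBenchmark(system, cross, rec_idx, lig_idx, coords)


def build_carrier_cargo_system(neutralize_loop=False, masses=30.0,
                               sphere_radius=30.0, separation=22.0):
    """Carrier (knob + acidic loop) and basic cargo alone in a small sphere:
    the minimal system for probing the electrostatic capture of the cargo by
    the acidic loop.  Returns ``(topology, system)``.

    The bead mass is reduced below the production default so the cargo
    explores the confinement within short smoke runs; equilibrium populations
    are mass-independent.
    """
    spec = ToySpec()
    top = Topology()
    coords: list = []
    knob_n, loop_n = 14, 16
    knob = _helix(knob_n, (0.0, 0.0, 0.0))
    loop = _rising_coil(knob[-1], loop_n, dz=1.2, radius=4.0)
    names = ["A"] * knob_n + [("D" if i % 2 else "E") for i in range(loop_n)]
    cstart = _add_native_chain(top, coords, np.vstack([knob, loop]), "CARR",
                               names, {"carrier"})
    top.tag_beads(np.arange(cstart + knob_n, cstart + knob_n + loop_n),
                  "carrier_loop")
    cargo = _cargo_points(spec) + np.array([separation, 0.0, 0.0])
    _add_native_chain(top, coords, cargo, "CARGO", _cargo_names(len(cargo)),
                      {"cargo"})
    coords = np.asarray(coords)
    cidx, ridx = top.select("cargo"), top.select("carrier")
    sets = [derive_native_contacts(top, coords, cutoff=6.5, label="cargo_fold",
                                   groups=(cidx, cidx)),
            derive_native_contacts(top, coords, cutoff=6.5,
                                   label="carrier_fold", groups=(ridx, ridx))]
    system = compile_system(
        top, coords, sets,
        confinement=SphericalConfinement(radius=sphere_radius,
                                         center=coords.mean(axis=0)),
        neutralize_tags=({"carrier_loop"} if neutralize_loop else ()),
        masses=masses)
    system.add_restraints(np.arange(cstart, cstart + knob_n),
                          coords[cstart:cstart + knob_n], 2.0)
    return top, system


# ---------------------------------------------------------------------------
# scripted labeled trajectories
# ---------------------------------------------------------------------------

SCENARIOS = ("leading-mediated", "lagging-mediated", "leading-unmediated",
             "lagging-unmediated", "parental", "none")


def _strand_site(topology, coords, tag, n_needed):
    idx = topology.select(tag)
    order = np.argsort([topology.beads[i].resid for i in idx])
    idx = idx[order]
    mid = len(idx) // 2
    lo = max(0, mid - n_needed // 2)
    return idx[lo:lo + n_needed]


def _cargo_on(points, cargo_n, rng, offset):
    """Map cargo beads onto target points (cycled) with a fixed offset."""
    reps = int(np.ceil(cargo_n / len(points)))
    tgt = np.tile(points, (reps, 1))[:cargo_n]
    return tgt + offset


def generate_labeled_trajectories(scenario_set=SCENARIOS, n_per_scenario=7,
                                  seed=0, jitter=1.0, n_frames=400,
                                  toy: ToyReplisome | None = None):
    """Scripted trajectories with ground-truth recycling labels.

    The cargo sits on the donor tail, optionally visits the carrier, then is
    deposited on the scripted destination arm (or never deposited).  Event
    margins are ≥20% beyond the default classifier thresholds and hold for
    contact cutoffs 8–12 Å.  Returns a list of (Trajectory,
    RecyclingOutcome) pairs; deterministic for a fixed seed.
    """
    for s in scenario_set:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")
    toy = toy or build_toy_replisome(ToySpec(chain_length=20, tail_length=40,
                                             carrier_length=24,
                                             carrier_loop_length=12))
    top, base = toy.topology, toy.coords
    cargo = top.select("cargo")
    carrier = top.select("carrier")
    rng = np.random.default_rng(seed)
    out = []
    for scenario in scenario_set:
        for _ in range(n_per_scenario):
            traj, label = _script_one(scenario, top, base, cargo, carrier,
                                      rng, jitter, n_frames)
            out.append((traj, label))
    return out


def _script_one(scenario, top, base, cargo, carrier, rng, jitter, n_frames):
    frames = np.tile(base, (n_frames, 1, 1))
    tail_pose = base[cargo]
    carrier_pts = base[carrier]
    dest = scenario.split("-")[0] if scenario != "none" else None
    mediated = scenario.endswith("mediated") and not scenario.endswith("unmediated")

    if scenario == "none":
        pose = np.tile(tail_pose, (n_frames, 1, 1))
    else:
        site = _strand_site(top, base, f"{dest}_duplex", 45)
        dep_pts = base[site]
        normal = dep_pts.mean(axis=0) - base.mean(axis=0)
        normal /= np.linalg.norm(normal)
        dep_pose = _cargo_on(dep_pts, len(cargo), rng, 3.0 * normal)
        carrier_pose = _cargo_on(carrier_pts, len(cargo), rng,
                                 np.array([0.0, 0.0, 3.0]))
        away = base.mean(axis=0) + np.array([-90.0, -60.0, 40.0])
        free_pose = _cargo_on(away[None, :] + np.arange(len(cargo))[:, None]
                              * np.array([1.2, 0.4, 0.2]), len(cargo), rng,
                              np.zeros(3))
        pose = np.empty((n_frames, len(cargo), 3))
        dep_start = 200
        if mediated:
            legs = [(0, 80, tail_pose, tail_pose),
                    (80, 100, tail_pose, carrier_pose),
                    (100, 180, carrier_pose, carrier_pose),
                    (180, dep_start, carrier_pose, dep_pose),
                    (dep_start, n_frames, dep_pose, dep_pose)]
        else:
            legs = [(0, 80, tail_pose, tail_pose),
                    (80, 110, tail_pose, free_pose),
                    (110, 170, free_pose, free_pose),
                    (170, dep_start, free_pose, dep_pose),
                    (dep_start, n_frames, dep_pose, dep_pose)]
        for a, b, p0, p1 in legs:
            for f in range(a, b):
                w = (f - a) / max(b - a - 1, 1)
                pose[f] = (1 - w) * p0 + w * p1
    frames[:, cargo, :] = pose + rng.normal(scale=jitter,
                                            size=(n_frames, len(cargo), 3))
    traj = Trajectory(frames, np.arange(1, n_frames + 1),
                      metadata={"scenario": scenario})
    if scenario == "none":
        label = RecyclingOutcome("none")
    else:
        label = RecyclingOutcome(dest, carrier_mediated=mediated)
    return traj, label
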