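"""Trajectory analytics for replication-fork histone-recycling runs.

Everything here operates on tagged bead groups (hub ring, donor tail,
carrier, cargo, duplex arms), so the same code runs on real replisome models
and on the synthetic toy systems.  The fork coordinate frame puts the origin
at the centre of mass (COM) of the helicase hub ring, Z along the ring axis,
and X through the COM of the donor subunit (Mcm2 in the real system);
elevation φ is measured toward Z in the X–Z plane and azimuth θ toward Y in
the X–Y plane.  Angle statistics are circular (distributions straddle ±180°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class ForkFrame:
    """Orthonormal right-handed frame anchored on the hub ring."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        for v in (self.X, self.Y, self.Z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError("frame axes must be unit vectors")
        if (abs(self.X @ self.Y) > 1e-8 or abs(self.X @ self.Z) > 1e-8
                or abs(self.Y @ self.Z) > 1e-8):
            raise ValueError("frame axes must be orthogonal")
        if np.cross(self.X, self.Y) @ self.Z < 0:
            raise ValueError("frame must be right-handed")


@dataclass
class OrientationAngles:
    """Elevation φ and azimuth θ in degrees, each in (−180, 180]."""

    elevation_phi: float
    azimuth_theta: float


@dataclass
class RecyclingOutcome:
    destination: str                      # leading | lagging | parental | none
    carrier_mediated: bool | None = None  # None = not applicable
    deposition_step: int | None = None
    dyad_nt_from_junction: int | None = None
    junction_distance_at_deposition: float | None = None

    def __post_init__(self):
        if self.destination not in ("leading", "lagging", "parental", "none"):
            raise ValueError(f"unknown destination {self.destination!r}")
        deposited = self.destination != "none"
        if not deposited and self.deposition_step is not None:
            raise ValueError("deposition fields defined without a destination")


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _resolve(topology_or_indices, tag=None):
    if tag is None:
        return np.asarray(topology_or_indices, dtype=int)
    idx = topology_or_indices.select(tag)
    if len(idx) == 0:
        raise KeyError(f"no beads tagged {tag!r}")
    return idx


def contact_count_frame(frame, group_a, group_b, cutoff):
    """Indices of group_a beads within ``cutoff`` of any group_b bead."""
    tree = cKDTree(frame[group_b])
    d, _ = tree.query(frame[group_a])
    return np.asarray(group_a)[d < cutoff]


def contact_timeseries(trajectory, group_a, group_b, cutoff=10.0):
    """Per-frame count of group_a beads within ``cutoff`` Å of group_b.

    Returns ``(counts, contact_sets)`` where ``contact_sets`` holds the
    per-frame arrays of contacting group_a bead indices.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("contact groups must be non-empty")
    sets = [contact_count_frame(f, group_a, group_b, cutoff)
            for f in trajectory.frames]
    counts = np.array([len(s) for s in sets], dtype=int)
    return counts, sets


def residue_contact_probability(trajectories, group_a, group_b, cutoff=10.0):
    """Per-bead probability (over frames, equal frame weighting across runs)
    that each group_a bead contacts any group_b bead."""
    group_a = np.asarray(group_a, dtype=int)
    hits = np.zeros(len(group_a))
    total = 0
    for traj in np.atleast_1d(trajectories):
        for f in traj.frames:
            tree = cKDTree(f[np.asarray(group_b, dtype=int)])
            d, _ = tree.query(f[group_a])
            hits += d < cutoff
            total += 1
    if total == 0:
        raise ValueError("no frames supplied")
    return hits / total


@dataclass
class SurvivalCurve:
    times: np.ndarray        # episode-duration grid (frames)
    survival: np.ndarray     # S(t) = fraction of episodes lasting ≥ t
    episodes: np.ndarray     # episode durations, frames
    defined: bool = True


def _episodes_from_counts(counts, min_gap_frames):
    active = counts > 0
    # merge interruptions shorter than min_gap_frames
    if min_gap_frames > 0:
        a = active.copy()
        i = 0
        n = len(a)
        while i < n:
            if not a[i]:
                j = i
                while j < n and not a[j]:
                    j += 1
                if 0 < i and j < n and (j - i) < min_gap_frames:
                    a[i:j] = True
                i = j
            else:
                i += 1
        active = a
    durations = []
    run = 0
    for x in active:
        if x:
            run += 1
        elif run:
            durations.append(run)
            run = 0
    if run:
        durations.append(run)
    return np.asarray(durations, dtype=int)


def association_survival(trajectories, group_a, group_b, cutoff=10.0,
                         min_gap_frames=0) -> SurvivalCurve:
    """Survival curve of contact-episode durations.

    Episodes are maximal runs of frames with a nonzero contact count,
    merging interruptions shorter than ``min_gap_frames``; S(t) is the
    fraction of episodes lasting at least t frames (S(0) = 1).
    """
    episodes = []
    for traj in np.atleast_1d(trajectories):
        counts, _ = contact_timeseries(traj, group_a, group_b, cutoff)
        episodes.extend(_episodes_from_counts(counts, min_gap_frames))
    episodes = np.asarray(episodes, dtype=int)
    if len(episodes) == 0:
        return SurvivalCurve(np.zeros(0), np.zeros(0), episodes, defined=False)
    tmax = episodes.max()
    times = np.arange(tmax + 2)
    surv = np.array([(episodes >= t).mean() for t in times])
    return SurvivalCurve(times, surv, episodes)


# ---------------------------------------------------------------------------
# fork frame and angles
# ---------------------------------------------------------------------------

def define_fork_frame(coords, ring_indices, mcm2_indices,
                      n_tier_reference=None) -> ForkFrame:
    """Frame from the hub ring: origin = COM(ring); Z = best-fit-plane normal
    of the ring beads (sign fixed toward ``n_tier_reference`` if given, else
    toward the positive-determinant orientation); X = projection of
    (COM(donor) − origin) orthogonal to Z; Y = Z × X."""
    coords = np.asarray(coords, dtype=float)
    ring = coords[np.asarray(ring_indices, dtype=int)]
    if len(ring) < 3:
        raise ValueError("ring selection needs at least 3 beads")
    origin = ring.mean(axis=0)
    centred = ring - origin
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-9:
        raise ValueError("ring beads are collinear; plane undefined")
    z = vt[2]
    if n_tier_reference is not None:
        ref = np.asarray(n_tier_reference, dtype=float) - origin
        if z @ ref < 0:
            z = -z
    x_raw = coords[np.asarray(mcm2_indices, dtype=int)].mean(axis=0) - origin
    x = x_raw - (x_raw @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("donor COM lies on the ring axis; X undefined")
    x = x / nx
    y = np.cross(z, x)
    return ForkFrame(origin, x, y / np.linalg.norm(y), z / np.linalg.norm(z))


def orientation_angles(frame: ForkFrame, point) -> OrientationAngles:
    """Elevation φ = atan2(v·Z, v·X) and azimuth θ = atan2(v·Y, v·X) of the
    vector from the frame origin to ``point``, in degrees."""
    v = np.asarray(point, dtype=float) - frame.origin
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("zero vector: point coincides with the origin")
    phi = math.degrees(math.atan2(v @ frame.Z, v @ frame.X))
    theta = math.degrees(math.atan2(v @ frame.Y, v @ frame.X))
    return OrientationAngles(phi, theta)


def circular_mean_sd(angles_deg):
    """Circular mean and SD (degrees) for angles straddling ±180°."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    mean = math.degrees(math.atan2(s, c))
    r = math.hypot(s, c)
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(max(r, 1e-300)), 0.0)))
    return mean, sd


# ---------------------------------------------------------------------------
# spatial densities
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Normalized 3D probability density on a regular grid (Å⁻³)."""

    density: np.ndarray
    edges: tuple            # per-axis bin edges
    spacing: float

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def integral(self) -> float:
        return float(self.density.sum() * self.voxel_volume)

    def superlevel_volume(self, level: float) -> float:
        return float((self.density > level).sum() * self.voxel_volume)

    def isosurface(self, level: float):
        """Triangulated iso-surface (vertices in Å, faces) via marching cubes."""
        from skimage.measure import marching_cubes

        verts, faces, _, _ = marching_cubes(self.density, level=level,
                                            spacing=(self.spacing,) * 3)
        offset = np.array([e[0] for e in self.edges])
        return verts + offset, faces


def spatial_density(trajectories, frame_fn, point_selector, grid_spacing=5.0,
                    bounds=None) -> DensityGrid:
    """Histogram of selected points expressed in the per-snapshot fork frame.

    ``frame_fn(coords) -> ForkFrame`` supplies the frame per snapshot;
    ``point_selector(coords) -> (k, 3) array`` the points (lab coordinates).
    The density is divided by (N · voxel volume) so it integrates to 1.
    """
    pts = []
    for traj in np.atleast_1d(trajectories):
        for f in traj.frames:
            fr = frame_fn(f)
            raw = np.atleast_2d(point_selector(f)) - fr.origin
            local = np.stack([raw @ fr.X, raw @ fr.Y, raw @ fr.Z], axis=1)
            pts.append(local)
    if not pts:
        raise ValueError("no snapshots supplied")
    pts = np.concatenate(pts)
    if len(pts) == 0:
        raise ValueError("empty point selection")
    if bounds is None:
        lo = np.floor(pts.min(axis=0) / grid_spacing) * grid_spacing - grid_spacing
        hi = np.ceil(pts.max(axis=0) / grid_spacing) * grid_spacing + grid_spacing
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    edges = [np.arange(lo[d], hi[d] + grid_spacing / 2, grid_spacing)
             for d in range(3)]
    hist, _ = np.histogramdd(pts, bins=edges)
    density = hist / (len(pts) * grid_spacing**3)
    return DensityGrid(density, tuple(edges), grid_spacing)


def region_overlap_fraction(grid_a: DensityGrid, grid_b: DensityGrid,
                            level: float, reference="a") -> float:
    """Fraction (volume of A∩B)/(volume of reference super-level set).

    Both grids must share spacing; the intersection is evaluated on the
    overlap of their bounding boxes.
    """
    if abs(grid_a.spacing - grid_b.spacing) > 1e-9:
        raise ValueError("grids must share spacing")
    inter = _intersection_volume(grid_a, grid_b, level)
    ref = grid_a if reference == "a" else grid_b
    denom = ref.superlevel_volume(level)
    if denom == 0:
        return 0.0
    return inter / denom


def _intersection_volume(grid_a, grid_b, level):
    h = grid_a.spacing
    vol = 0.0
    lo_a = np.array([e[0] for e in grid_a.edges])
    lo_b = np.array([e[0] for e in grid_b.edges])
    mask_a = grid_a.density > level
    idx = np.argwhere(mask_a)
    if len(idx) == 0:
        return 0.0
    centres = lo_a + (idx + 0.5) * h
    jdx = np.floor((centres - lo_b) / h).astype(int)
    shape = grid_b.density.shape
    ok = np.all((jdx >= 0) & (jdx < shape), axis=1)
    sel = jdx[ok]
    if len(sel):
        vol = float(np.sum(grid_b.density[sel[:, 0], sel[:, 1], sel[:, 2]]
                           > level)) * h**3
    return vol


# ---------------------------------------------------------------------------
# recycling classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifierThresholds:
    """Deposition / pathway event thresholds (all in saved frames or beads).

    Deposition: cargo–strand contact count ≥ ``n_dep`` continuously for
    ``t_dep`` frames while donor-tail contacts ≤ ``n_tail``.  The carrier-
    mediated flag requires ≥ ``n_car`` cargo–carrier contacts within the
    ``window`` frames preceding deposition.
    """

    contact_cutoff: float = 10.0
    n_dep: int = 30
    t_dep: int = 50
    n_tail: int = 5
    n_car: int = 10
    window: int = 200


_DEST_TAGS = (("leading", "leading_duplex"), ("lagging", "lagging_duplex"),
              ("parental", "parental_duplex"))


def classify_recycling(trajectory, topology, thresholds=None,
                       cargo_tag="cargo", carrier_tag="carrier",
                       tail_tag="donor_tail") -> RecyclingOutcome:
    """Label one trajectory with its recycling destination and pathway.

    Returns destination ∈ {leading, lagging, parental, none}; for deposited
    outcomes also whether the handover was carrier-mediated, the deposition
    step, the dyad position (nt from the fork junction, where the topology
    provides nucleotide indexing) and the cargo–junction 3D distance at
    deposition.
    """
    th = thresholds or ClassifierThresholds()
    cargo = _resolve(topology, cargo_tag)
    carrier = _resolve(topology, carrier_tag)
    tail = _resolve(topology, tail_tag)
    strand_groups = {}
    for dest, tag in _DEST_TAGS:
        idx = topology.select(tag)
        if len(idx):
            strand_groups[dest] = idx
    if not strand_groups:
        raise KeyError("no duplex groups tagged in topology")

    counts = {dest: contact_timeseries(trajectory, cargo, idx,
                                       th.contact_cutoff)[0]
              for dest, idx in strand_groups.items()}
    tail_counts, _ = contact_timeseries(trajectory, cargo, tail,
                                        th.contact_cutoff)
    car_counts, _ = contact_timeseries(trajectory, cargo, carrier,
                                       th.contact_cutoff)

    n_frames = trajectory.n_frames
    deposition = None  # (frame, destination)
    for dest, c in counts.items():
        ok = (c >= th.n_dep) & (tail_counts <= th.n_tail)
        run = 0
        for f in range(n_frames):
            run = run + 1 if ok[f] else 0
            if run >= th.t_dep:
                start = f - th.t_dep + 1
                if deposition is None or start < deposition[0]:
                    deposition = (start, dest)
                break
    if deposition is None:
        return RecyclingOutcome("none")

    dep_frame, dest = deposition
    w0 = max(0, dep_frame - th.window)
    mediated = bool((car_counts[w0:dep_frame + 1] >= th.n_car).any())

    dyad = None
    jdist = None
    meta = topology.metadata
    dep_coords = trajectory.frames[dep_frame]
    if "junction_bead" in meta:
        jdist = junction_distance_3d(dep_coords, cargo,
                                     meta["junction_bead"])
    if "nt_from_junction" in meta and dest in strand_groups:
        try:
            dyad = dyad_distance_nt(dep_coords, topology, dest, 0, cargo,
                                    cutoff=th.contact_cutoff)
        except ValueError:
            dyad = None
    step = int(trajectory.step_ids[dep_frame])
    return RecyclingOutcome(dest, carrier_mediated=mediated,
                            deposition_step=step,
                            dyad_nt_from_junction=dyad,
                            junction_distance_at_deposition=jdist)


def dyad_distance_nt(coords, topology, destination, junction_nucleotide,
                     cargo_indices, cutoff=10.0) -> int:
    """Nucleotides from the fork junction to the dyad of the wrapped cargo.

    The dyad is the median nucleotide index (counted from the junction along
    the destination arm, via ``topology.metadata['nt_from_junction']``) among
    destination nucleotides with any site bead within ``cutoff`` of the
    cargo; the distance is |dyad − junction| in nucleotides.
    """
    tag = dict(_DEST_TAGS).get(destination, destination)
    strand = _resolve(topology, tag)
    cargo = np.asarray(cargo_indices, dtype=int)
    coords = np.asarray(coords, dtype=float)
    nt_map = np.asarray(topology.metadata["nt_from_junction"])
    tree = cKDTree(coords[cargo])
    d, _ = tree.query(coords[strand])
    touching = strand[d < cutoff]
    nts = nt_map[touching]
    nts = nts[nts >= 0]
    if len(nts) == 0:
        raise ValueError("empty footprint: no strand bead within cutoff")
    dyad = int(np.median(nts))
    return abs(dyad - int(junction_nucleotide))


def junction_distance_3d(coords, cargo_indices, junction_bead) -> float:
    """Euclidean distance from the cargo COM to the junction base pair."""
    coords = np.asarray(coords, dtype=float)
    com = coords[np.asarray(cargo_indices, dtype=int)].mean(axis=0)
    return float(np.linalg.norm(com - coords[int(junction_bead)]))
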