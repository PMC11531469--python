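"""Coarse-grained topology building for proteins and forked DNA.

Proteins are reduced to one bead per residue at the Cα position; DNA to three
beads per nucleotide (base, sugar, phosphate), with the 5′-terminal nucleotide
of every strand carrying no phosphate bead.  Folded protein regions receive
native-anchored bond/angle/dihedral terms; intrinsically disordered regions
(IDRs) keep only bonds plus a weak generic angle term so coils stay flexible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

# local-potential defaults (kcal/mol, Å, radians)
CA_BOND_LENGTH = 3.8
K_BOND = 100.0
K_ANGLE = 20.0
K_DIHEDRAL = 1.0
K_ANGLE_IDR = 1.0
THETA0_IDR = math.radians(130.0)

K_BOND_DNA = 60.0
K_ANGLE_DNA = 20.0
K_DIHEDRAL_DNA = 1.0
K_ANGLE_SS = 2.0
THETA0_SS = math.radians(150.0)

PROTEIN_RADIUS = 2.5
DNA_RADII = {"base": 3.0, "sugar": 3.0, "phosphate": 2.5}

DEFAULT_CONTACT_EPS = 0.3

_POSITIVE = {"K", "R", "LYS", "ARG"}
_NEGATIVE = {"D", "E", "ASP", "GLU"}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def residue_formal_charge(name: str) -> float:
    """+1 for Lys/Arg, −1 for Asp/Glu, 0 otherwise (one- or three-letter)."""
    key = name.strip().upper()
    if key in _POSITIVE:
        return 1.0
    if key in _NEGATIVE:
        return -1.0
    return 0.0


@dataclass
class Bead:
    """One coarse-grained site.

    ``resid`` is the residue/nucleotide index within its chain (1-based, as in
    user-facing tables); ``site_kind`` is ``residue`` for protein beads and
    ``base``/``sugar``/``phosphate`` for DNA sites.
    """

    index: int
    chain_id: str
    site_kind: str
    name: str
    charge: float
    radius: float
    resid: int
    group_tags: set = field(default_factory=set)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"bead {self.index}: radius must be positive")
        if self.site_kind not in ("residue", "base", "sugar", "phosphate"):
            raise ValueError(f"unknown site kind {self.site_kind!r}")


@dataclass
class ChainRecord:
    chain_id: str
    molecule_class: str  # "protein" | "dna_strand"
    start: int           # first bead index
    stop: int            # one past last bead index


@dataclass
class Topology:
    beads: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    bonds: list = field(default_factory=list)        # (i, j, r0, k)
    angles: list = field(default_factory=list)       # (i, j, k, theta0, kk)
    dihedrals: list = field(default_factory=list)    # (i, j, k, l, phi0, kk)
    idr_ranges: dict = field(default_factory=dict)   # chain_id -> [(first, last)]
    metadata: dict = field(default_factory=dict)

    # ---- bookkeeping -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def add_bead(self, chain_id, site_kind, name, charge, radius, resid, tags=()):
        b = Bead(len(self.beads), chain_id, site_kind, name, charge, radius,
                 resid, set(tags))
        self.beads.append(b)
        return b.index

    def add_bond(self, i, j, r0, k=K_BOND):
        if r0 <= 0:
            raise ValueError("reference bond length must be positive")
        self.bonds.append((i, j, float(r0), float(k)))

    def add_angle(self, i, j, k, theta0, kk=K_ANGLE):
        self.angles.append((i, j, k, float(theta0), float(kk)))

    def add_dihedral(self, i, j, k, l, phi0, kk=K_DIHEDRAL):
        self.dihedrals.append((i, j, k, l, float(phi0), float(kk)))

    def select(self, *tags) -> np.ndarray:
        """Indices of beads whose tag set intersects ``tags``."""
        want = set(tags)
        out = [b.index for b in self.beads if b.group_tags & want]
        return np.asarray(out, dtype=np.int64)

    def tag_beads(self, indices, tag):
        for i in np.atleast_1d(np.asarray(indices, dtype=int)):
            self.beads[int(i)].group_tags.add(tag)

    def chain(self, chain_id) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not found")

    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    def is_dna(self) -> np.ndarray:
        kinds = {"base", "sugar", "phosphate"}
        return np.array([b.site_kind in kinds for b in self.beads])

    def validate(self):
        n = self.n_beads
        for i, j, r0, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond references invalid bead index")
            if r0 <= 0:
                raise ValueError("bond reference length must be positive")
        for t in self.angles:
            if not all(0 <= x < n for x in t[:3]):
                raise ValueError("angle references invalid bead index")
        for t in self.dihedrals:
            if not all(0 <= x < n for x in t[:4]):
                raise ValueError("dihedral references invalid bead index")
        for cid, spans in self.idr_ranges.items():
            chain = self.chain(cid)
            resids = [self.beads[i].resid for i in range(chain.start, chain.stop)]
            lo, hi = min(resids), max(resids)
            for a, b in spans:
                if a > b or a < lo or b > hi:
                    raise ValueError(f"IDR span {(a, b)} outside chain {cid} bounds")

    def merge(self, other: "Topology") -> "Topology":
        """Concatenate two topologies (bead indices of ``other`` are offset)."""
        off = self.n_beads
        out = Topology()
        out.beads = [Bead(b.index, b.chain_id, b.site_kind, b.name, b.charge,
                          b.radius, b.resid, set(b.group_tags))
                     for b in self.beads]
        for b in other.beads:
            out.beads.append(Bead(b.index + off, b.chain_id, b.site_kind,
                                  b.name, b.charge, b.radius, b.resid,
                                  set(b.group_tags)))
        out.chains = list(self.chains) + [
            ChainRecord(c.chain_id, c.molecule_class, c.start + off, c.stop + off)
            for c in other.chains]
        out.bonds = list(self.bonds) + [(i + off, j + off, r0, k)
                                        for i, j, r0, k in other.bonds]
        out.angles = list(self.angles) + [(i + off, j + off, k + off, t0, kk)
                                          for i, j, k, t0, kk in other.angles]
        out.dihedrals = list(self.dihedrals) + [
            (i + off, j + off, k + off, l + off, p0, kk)
            for i, j, k, l, p0, kk in other.dihedrals]
        out.idr_ranges = {**self.idr_ranges, **other.idr_ranges}
        out.metadata = {**self.metadata, **other.metadata}
        return out


@dataclass
class ContactSet:
    """Native-contact pairs for the structure-based (Gō-like) attraction.

    Each pair carries its reference distance ``r0`` (Å) and strength ``eps``
    (kcal/mol); ``sigma`` is the global scale applied to the whole set.
    """

    pairs: list  # (i, j, r0, eps)
    sigma: float = 1.0
    label: str = "native"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative (0 decouples the set)")
        norm = []
        for i, j, r0, eps in self.pairs:
            if i == j:
                raise ValueError("contact pair with identical indices")
            if r0 <= 0 or eps <= 0:
                raise ValueError("contact r0 and eps must be positive")
            a, b = (i, j) if i < j else (j, i)
            norm.append((int(a), int(b), float(r0), float(eps)))
        self.pairs = norm

    def __len__(self):
        return len(self.pairs)

    def with_sigma(self, sigma: float) -> "ContactSet":
        return ContactSet(list(self.pairs), sigma=sigma, label=self.label)

    def shifted(self, offset: int) -> "ContactSet":
        return ContactSet([(i + offset, j + offset, r0, e)
                           for i, j, r0, e in self.pairs],
                          sigma=self.sigma, label=self.label)


@dataclass
class ChargeContext:
    """Charge conventions.

    DNA phosphates are dual-valued: −0.6e against DNA partners (counter-ion
    condensation) and −1.0e against protein partners (counter-ion release on
    binding).  Protein beads carry formal charges: K/R → +1, D/E → −1.
    """

    intra_dna_phosphate_charge: float = -0.6
    cross_phosphate_charge: float = -1.0
    overrides: list = field(default_factory=list)  # (bead_index, charge)


@dataclass
class ChargeTable:
    """Per-bead charges resolved for both interaction contexts.

    ``q_intra[i]`` applies when both partners are DNA; ``q_cross[i]`` when the
    pair crosses the protein/DNA divide (or is protein–protein, where the two
    are equal).
    """

    q_intra: np.ndarray
    q_cross: np.ndarray
    is_dna: np.ndarray

    def pair_charge_product(self, i: int, j: int) -> float:
        if self.is_dna[i] and self.is_dna[j]:
            return float(self.q_intra[i] * self.q_intra[j])
        return float(self.q_cross[i] * self.q_cross[j])

    def total_protein_charge(self) -> float:
        return float(np.sum(self.q_cross[~self.is_dna]))


@dataclass
class CGStructure:
    """A built coarse-grained model: topology, coordinates, optionally the
    per-bead heavy-atom coordinates it was reduced from, and any contact
    sets the builder derived (e.g. duplex-stabilization sets)."""

    topology: Topology
    coords: np.ndarray
    heavy_atoms: list | None = None  # per-bead (m, 3) arrays
    contact_sets: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# protein builder
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Which chain to coarse-grain and how to tag it."""

    chain_id: str
    tags: set = field(default_factory=set)
    tag_ranges: list = field(default_factory=list)  # (first_resid, last_resid, tag)
    out_chain_id: str | None = None


def _in_ranges(resid, spans):
    return any(a <= resid <= b for a, b in spans)


def coarse_grain_protein(structure, chain_specs, idr_ranges=None) -> CGStructure:
    """Reduce protein chains to one Cα bead per residue.

    Parameters
    ----------
    structure
        A parsed structure as returned by :func:`forkcg.io.read_pdb`
        (Bio.PDB entity).
    chain_specs
        Sequence of :class:`ChainSpec` (or bare chain-id strings).
    idr_ranges
        ``{chain_id: [(first_resid, last_resid), ...]}`` spans treated as
        intrinsically disordered: bonds only plus a weak generic angle term.

    Raises on a missing chain, or on a missing Cα at a non-terminal residue.
    """
    idr_ranges = idr_ranges or {}
    specs = [s if isinstance(s, ChainSpec) else ChainSpec(str(s))
             for s in chain_specs]

    model = next(structure.get_models())
    top = Topology()
    coords = []
    heavy = []
    for spec in specs:
        chain_obj = None
        for ch in model.get_chains():
            if ch.id == spec.chain_id:
                chain_obj = ch
                break
        if chain_obj is None:
            raise KeyError(f"chain {spec.chain_id!r} not found in structure")
        residues = [r for r in chain_obj.get_residues() if "CA" in r
                    or r.id[0] == " "]
        residues = [r for r in residues if r.id[0] == " "]
        spans = idr_ranges.get(spec.chain_id, [])
        start = top.n_beads
        kept = []
        for pos, res in enumerate(residues):
            if "CA" not in res:
                if pos in (0, len(residues) - 1):
                    continue  # ragged terminus: drop silently
                raise ValueError(
                    f"residue {res.get_resname()}{res.id[1]} in chain "
                    f"{spec.chain_id} has no Cα atom")
            kept.append(res)
        out_id = spec.out_chain_id or spec.chain_id
        for res in kept:
            resid = res.id[1]
            name = res.get_resname()
            tags = set(spec.tags)
            for a, b, t in spec.tag_ranges:
                if a <= resid <= b:
                    tags.add(t)
            idx = top.add_bead(out_id, "residue", name,
                               residue_formal_charge(name), PROTEIN_RADIUS,
                               resid, tags)
            coords.append(np.asarray(res["CA"].coord, dtype=float))
            heavy.append(np.array([a.coord for a in res.get_atoms()
                                   if a.element != "H"], dtype=float))
            assert idx == len(coords) - 1
        top.chains.append(ChainRecord(out_id, "protein", start, top.n_beads))
        if spans:
            top.idr_ranges[out_id] = [tuple(s) for s in spans]
        _add_protein_local_terms(top, np.asarray(coords), start, top.n_beads,
                                 spans)
    top.validate()
    return CGStructure(top, np.asarray(coords, dtype=float), heavy)


def _add_protein_local_terms(top, coords, start, stop, idr_spans):
    """Bond/angle/dihedral terms for one protein chain span."""

    def disordered(idx):
        return _in_ranges(top.beads[idx].resid, idr_spans)

    def consecutive(i, j):
        return top.beads[j].resid == top.beads[i].resid + 1

    for i in range(start, stop - 1):
        if not consecutive(i, i + 1):
            continue  # chain break in the resolved structure
        if disordered(i) or disordered(i + 1):
            top.add_bond(i, i + 1, CA_BOND_LENGTH, K_BOND)
        else:
            r0 = float(np.linalg.norm(coords[i + 1 - start] - coords[i - start]))
            top.add_bond(i, i + 1, r0, K_BOND)
    for i in range(start, stop - 2):
        if not (consecutive(i, i + 1) and consecutive(i + 1, i + 2)):
            continue
        trio = (i, i + 1, i + 2)
        if any(disordered(x) for x in trio):
            top.add_angle(*trio, THETA0_IDR, K_ANGLE_IDR)
        else:
            t0 = _angle(coords[i - start], coords[i + 1 - start],
                        coords[i + 2 - start])
            top.add_angle(*trio, t0, K_ANGLE)
    for i in range(start, stop - 3):
        quad = (i, i + 1, i + 2, i + 3)
        if not all(consecutive(quad[k], quad[k + 1]) for k in range(3)):
            continue
        if any(disordered(x) for x in quad):
            continue  # IDRs get no dihedral term
        p0 = _dihedral(*(coords[x - start] for x in quad))
        top.add_dihedral(*quad, p0, K_DIHEDRAL)


def _angle(a, b, c):
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return float(np.arctan2(y, x))


# ---------------------------------------------------------------------------
# DNA builders
# ---------------------------------------------------------------------------

# ideal B-form fiber parameters (Å, degrees)
BDNA_RISE = 3.38
BDNA_TWIST = 36.0
_SITE_GEOM = {  # site -> (radius, phase offset deg, z offset)
    "base": (2.0, 0.0, 0.0),
    "sugar": (6.9, -40.0, 0.2),
    "phosphate": (8.9, -70.0, -1.8),
}


def _dna_site_position(nt_index, site, strand, origin, axis_frame):
    """Position of one DNA site on the ideal fiber.

    ``axis_frame`` is a (3, 3) rotation whose third row is the helix axis;
    strand 0 runs 5′→3′ with z increasing, strand 1 antiparallel.
    """
    r, dphi, dz = _SITE_GEOM[site]
    phase = BDNA_TWIST * nt_index
    if strand == 0:
        ang = math.radians(phase + dphi)
        z = nt_index * BDNA_RISE + dz
    else:
        ang = math.radians(phase + 180.0 - dphi)
        z = nt_index * BDNA_RISE - dz
    local = np.array([r * math.cos(ang), r * math.sin(ang), z])
    return origin + local @ axis_frame


def _build_strand(top, coords, seq, chain_id, positions, tags, resid_offset=0,
                  duplex=True):
    """Append one DNA strand; ``positions`` maps (nt, site) -> xyz.

    The 5′-terminal nucleotide carries no phosphate bead.
    """
    start = top.n_beads
    site_index = {}
    for nt, base in enumerate(seq):
        resid = resid_offset + nt + 1
        sites = ("sugar", "base") if nt == 0 else ("phosphate", "sugar", "base")
        for site in sites:
            charge = -0.6 if site == "phosphate" else 0.0
            idx = top.add_bead(chain_id, site, base if site == "base" else site[0].upper(),
                               charge, DNA_RADII[site], resid, tags)
            coords.append(positions[(nt, site)])
            site_index[(nt, site)] = idx
    top.chains.append(ChainRecord(chain_id, "dna_strand", start, top.n_beads))
    _add_dna_local_terms(top, coords, site_index, len(seq), duplex=duplex)
    return site_index


def _add_dna_local_terms(top, coords, site_index, n_nt, duplex=True):
    def pos(key):
        return np.asarray(coords[site_index[key]])

    k_bond = K_BOND_DNA
    for nt in range(n_nt):
        s, b = site_index[(nt, "sugar")], site_index[(nt, "base")]
        top.add_bond(s, b, float(np.linalg.norm(pos((nt, "base")) - pos((nt, "sugar")))),
                     k_bond)
        if (nt, "phosphate") in site_index:
            p = site_index[(nt, "phosphate")]
            top.add_bond(p, s, float(np.linalg.norm(pos((nt, "sugar")) - pos((nt, "phosphate")))),
                         k_bond)
            sp = site_index[(nt - 1, "sugar")]
            top.add_bond(sp, p, float(np.linalg.norm(pos((nt, "phosphate")) - pos((nt - 1, "sugar")))),
                         k_bond)
    k_ang = K_ANGLE_DNA if duplex else K_ANGLE_SS
    for nt in range(1, n_nt):
        p, s = site_index[(nt, "phosphate")], site_index[(nt, "sugar")]
        sp = site_index[(nt - 1, "sugar")]
        t0 = (_angle(pos((nt - 1, "sugar")), pos((nt, "phosphate")), pos((nt, "sugar")))
              if duplex else THETA0_SS)
        top.add_angle(sp, p, s, t0, k_ang)
        # P-S-B angle also provides the 1-3 exclusion within a nucleotide
        t0 = _angle(pos((nt, "phosphate")), pos((nt, "sugar")), pos((nt, "base")))
        top.add_angle(p, s, site_index[(nt, "base")], t0, k_ang)
    if duplex:
        for nt in range(1, n_nt - 1):
            quad = (site_index[(nt - 1, "sugar")], site_index[(nt, "phosphate")],
                    site_index[(nt, "sugar")], site_index[(nt + 1, "phosphate")])
            p0 = _dihedral(pos((nt - 1, "sugar")), pos((nt, "phosphate")),
                           pos((nt, "sugar")), pos((nt + 1, "phosphate")))
            top.add_dihedral(*quad, p0, K_DIHEDRAL_DNA)


def generate_bform_duplex(sequence, chain_ids=("D1", "D2"), tags=(),
                          origin=None, axis_frame=None,
                          resid_offset=0) -> CGStructure:
    """Build an ideal B-form duplex (3.38 Å rise, 36°/bp twist).

    ``sequence`` is the 5′→3′ sequence of the first strand; the complementary
    antiparallel strand is generated automatically.
    """
    seq = sequence.strip().upper()
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotides in sequence: {sorted(bad)}")
    comp = "".join(COMPLEMENT[b] for b in reversed(seq))
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    frame = np.eye(3) if axis_frame is None else np.asarray(axis_frame, dtype=float)

    top = Topology()
    coords: list = []
    n = len(seq)
    pos1 = {(nt, site): _dna_site_position(nt, site, 0, origin, frame)
            for nt in range(n) for site in ("base", "sugar", "phosphate")}
    # antiparallel partner: nucleotide j of strand 2 pairs with n-1-j of strand 1
    pos2 = {(j, site): _dna_site_position(n - 1 - j, site, 1, origin, frame)
            for j in range(n) for site in ("base", "sugar", "phosphate")}
    idx1 = _build_strand(top, coords, seq, chain_ids[0], pos1, set(tags),
                         resid_offset)
    idx2 = _build_strand(top, coords, comp, chain_ids[1], pos2, set(tags),
                         resid_offset)
    top.metadata["site_index"] = {chain_ids[0]: idx1, chain_ids[1]: idx2}
    top.validate()
    return CGStructure(top, np.asarray(coords, dtype=float))


def duplex_stabilization_contacts(struct: CGStructure, cutoff=9.0,
                                  eps=DEFAULT_CONTACT_EPS,
                                  label="dna_duplex") -> ContactSet:
    """Native-anchored contacts (pairing + stacking) holding a duplex in B-form.

    Pairs any two DNA beads of different nucleotides within ``cutoff`` Å in
    the built reference, skipping pairs already covered by a bond or angle
    term (which holds stacking neighbours too, so the excluded-volume term
    never fights the native geometry).
    """
    top, coords = struct.topology, struct.coords
    tree = cKDTree(coords)
    bonded = {(min(i, j), max(i, j)) for i, j, _, _ in top.bonds}
    bonded |= {(min(i, k), max(i, k)) for i, _, k, _, _ in top.angles}
    pairs = []
    for i, j in tree.query_pairs(cutoff):
        bi, bj = top.beads[i], top.beads[j]
        if bi.chain_id == bj.chain_id and bi.resid == bj.resid:
            continue
        if (min(i, j), max(i, j)) in bonded:
            continue
        pairs.append((i, j, float(np.linalg.norm(coords[i] - coords[j])), eps))
    return ContactSet(pairs, sigma=1.0, label=label)


# ---------------------------------------------------------------------------
# forked DNA
# ---------------------------------------------------------------------------

def _random_sequence(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def assemble_fork(parental_bp, leading_bp, lagging_bp, leading_gap_nt,
                  lagging_gap_nt, seed=0, max_retries=20,
                  sequences=None) -> CGStructure:
    """Build a branched replication-fork DNA assembly.

    A parental duplex ends at the fork junction; two daughter duplex arms
    (leading/lagging) branch off, each connected to the junction through a
    single-stranded gap of the requested length (0 allowed).  Groups are
    tagged ``parental_duplex``, ``leading_duplex``, ``lagging_duplex``,
    ``leading_ssDNA``, ``lagging_ssDNA``; the junction bead (base bead of the
    last parental pair) index is stored in ``topology.metadata["junction_bead"]``
    and per-bead nucleotide distances from the junction in
    ``metadata["nt_from_junction"]``.
    """
    if min(parental_bp, leading_bp, lagging_bp, leading_gap_nt,
           lagging_gap_nt) < 0:
        raise ValueError("all lengths must be non-negative")
    if parental_bp < 2 or leading_bp < 2 or lagging_bp < 2:
        raise ValueError("duplex segments need at least 2 bp")
    rng = np.random.default_rng(seed)
    seqs = sequences or {}

    def seq(key, n):
        return seqs.get(key) or _random_sequence(n, rng)

    last_err = None
    for attempt in range(max_retries):
        try:
            return _assemble_fork_once(
                parental_bp, leading_bp, lagging_bp, leading_gap_nt,
                lagging_gap_nt, rng, seq)
        except RuntimeError as err:  # clash — retry with fresh randomness
            last_err = err
    raise RuntimeError(
        f"fork assembly failed after {max_retries} retries: {last_err}")


def _rotation_about_y(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), 0, math.sin(a)],
                     [0, 1, 0],
                     [-math.sin(a), 0, math.cos(a)]])


def _assemble_fork_once(parental_bp, leading_bp, lagging_bp, leading_gap_nt,
                        lagging_gap_nt, rng, seq):
    # parental duplex along −z ending at the junction (origin)
    par = generate_bform_duplex(seq("parental", parental_bp),
                                chain_ids=("PAR1", "PAR2"),
                                tags={"parental_duplex"},
                                origin=np.array([0.0, 0.0, -parental_bp * BDNA_RISE]))
    top, coords = par.topology, list(par.coords)
    junction = par.topology.metadata["site_index"]["PAR1"][(parental_bp - 1, "base")]
    top.metadata["junction_bead"] = junction
    contact_sets = [duplex_stabilization_contacts(par, label="parental_duplex_fold")]

    arms = []
    for name, n_bp, gap_nt, tilt in (("leading", leading_bp, leading_gap_nt, 55.0),
                                     ("lagging", lagging_bp, lagging_gap_nt, -55.0)):
        frame = _rotation_about_y(tilt)
        gap_step = 6.0
        arm_start_dist = 6.0 + 0.5 * gap_step * gap_nt
        origin = frame.T @ np.array([0.0, 0.0, arm_start_dist])
        arm = generate_bform_duplex(seq(name, n_bp),
                                    chain_ids=(f"{name.upper()[:3]}1",
                                               f"{name.upper()[:3]}2"),
                                    tags={f"{name}_duplex"},
                                    origin=origin, axis_frame=frame)
        arms.append((name, gap_nt, arm, origin, frame))

    nt_from_junction = np.full(top.n_beads + sum(a[2].topology.n_beads +
                                                 3 * a[1] - (1 if a[1] else 0)
                                                 for a in arms), -1, dtype=int)
    # parental beads: distance back from the junction (negative side, mark 0..)
    merged = CGStructure(top, np.asarray(coords))
    for name, gap_nt, arm, origin, frame in arms:
        offset = merged.topology.n_beads
        contact_sets.append(duplex_stabilization_contacts(
            arm, label=f"{name}_duplex_fold").shifted(offset))
        merged_top = merged.topology.merge(arm.topology)
        merged_coords = np.vstack([merged.coords, arm.coords])
        # nucleotide distance from junction: gap nts count 1..gap, duplex
        # nts continue gap+1 ..
        for b in arm.topology.beads:
            nt_from_junction[b.index + offset] = gap_nt + b.resid
        merged = CGStructure(merged_top, merged_coords)
        if gap_nt > 0:
            merged = _add_ssdna_gap(merged, name, gap_nt, origin, frame,
                                    rng, nt_from_junction, seq)
        else:
            # covalently join junction-side parental sugar to arm first sugar
            si = arm.topology.metadata["site_index"][f"{name.upper()[:3]}1"]
            first_sugar = si[(0, "sugar")] + offset
            par_sugar = par.topology.metadata["site_index"]["PAR1"][(parental_bp - 1, "sugar")]
            r0 = float(np.linalg.norm(merged.coords[par_sugar]
                                      - merged.coords[first_sugar]))
            merged.topology.add_bond(par_sugar, first_sugar, r0, K_BOND_DNA)
    top = merged.topology
    coords = merged.coords
    top.metadata.pop("site_index", None)
    top.metadata["junction_bead"] = junction
    top.metadata["nt_from_junction"] = nt_from_junction[:top.n_beads]
    _check_clashes(top, coords)
    top.validate()
    return CGStructure(top, coords, contact_sets=contact_sets)


def _add_ssdna_gap(merged, name, gap_nt, arm_origin, frame, rng,
                   nt_from_junction, seq):
    """Self-avoiding ssDNA coil joining the junction to a daughter arm."""
    top, coords = merged.topology, merged.coords
    start_pt = np.array([0.0, 0.0, -2.0])
    end_pt = np.asarray(arm_origin, dtype=float)
    path = bridged_self_avoiding_walk(start_pt, end_pt, gap_nt, step=6.0,
                                      rng=rng, obstacles=coords,
                                      min_clearance=2.0)
    sequence = seq(f"{name}_gap", gap_nt)
    positions = {}
    for nt in range(gap_nt):
        s = path[nt]
        jitter = rng.normal(scale=0.5, size=3)
        positions[(nt, "sugar")] = s
        positions[(nt, "base")] = s + np.array([2.5, 0, 0]) + jitter
        positions[(nt, "phosphate")] = s + np.array([0, 2.5, 0]) - jitter
    new_coords = list(coords)
    chain_id = f"{name.upper()[:3]}SS"
    site_index = _build_strand(top, new_coords, sequence, chain_id, positions,
                               {f"{name}_ssDNA"}, duplex=False)
    # connect coil ends: junction side and arm side
    chain = top.chain(chain_id)
    for b_idx in range(chain.start, chain.stop):
        nt_from_junction[b_idx] = top.beads[b_idx].resid  # 1..gap
    junction_sugar = None
    for c in top.chains:
        if c.chain_id == "PAR1":
            junction_sugar = c.stop - 2  # last nt sugar of strand PAR1
    arr = np.asarray(new_coords)
    r0 = float(np.linalg.norm(arr[junction_sugar]
                              - arr[site_index[(0, "sugar")]]))
    top.add_bond(junction_sugar, site_index[(0, "sugar")], r0, K_BOND_DNA)
    arm_chain = top.chain(f"{name.upper()[:3]}1")
    # first sugar bead of the daughter arm
    arm_first_sugar = arm_chain.start  # first bead of 5'-terminal nt is sugar
    r0 = float(np.linalg.norm(arr[site_index[(gap_nt - 1, "sugar")]]
                              - arr[arm_first_sugar]))
    top.add_bond(site_index[(gap_nt - 1, "sugar")], arm_first_sugar, r0,
                 K_BOND_DNA)
    return CGStructure(top, arr)


def _check_clashes(top, coords, min_dist=1.5):
    tree = cKDTree(coords)
    close = tree.query_pairs(min_dist)
    bonded = {(min(i, j), max(i, j)) for i, j, _, _ in top.bonds}
    bad = [p for p in close if p not in bonded]
    if bad:
        raise RuntimeError(f"{len(bad)} steric clashes after placement")


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def derive_native_contacts(topology, coords, heavy_atom_map=None,
                           cutoff=6.5, sigma=1.0, eps_rule=None,
                           label="native", groups=None,
                           min_seq_sep=4) -> ContactSet:
    """Native-contact pairs from reference coordinates.

    A bead pair becomes a contact when any mapped heavy-atom pair lies within
    ``cutoff`` Å (bead positions are used where no heavy-atom map is given),
    with sequence separation ≥ ``min_seq_sep`` within a chain.  ``groups``, if
    given as ``(indices_a, indices_b)``, restricts to cross pairs between the
    two selections.  ``eps_rule`` maps ``(bead_i, bead_j) -> eps`` (default
    uniform 0.3 kcal/mol).  The reference distance is the bead–bead distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    if heavy_atom_map is not None:
        atom_xyz, owner = [], []
        for i, arr in enumerate(heavy_atom_map):
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            atom_xyz.append(arr)
            owner.extend([i] * len(arr))
        atom_xyz = np.vstack(atom_xyz)
        owner = np.asarray(owner)
        tree = cKDTree(atom_xyz)
        cand = set()
        for a, b in tree.query_pairs(cutoff):
            i, j = owner[a], owner[b]
            if i != j:
                cand.add((min(i, j), max(i, j)))
    else:
        tree = cKDTree(coords)
        cand = {tuple(sorted(p)) for p in tree.query_pairs(cutoff)}

    if groups is not None:
        ga, gb = (set(map(int, groups[0])), set(map(int, groups[1])))
        cand = {(i, j) for i, j in cand
                if (i in ga and j in gb) or (i in gb and j in ga)}

    pairs = []
    for i, j in sorted(cand):
        bi, bj = topology.beads[i], topology.beads[j]
        if bi.chain_id == bj.chain_id and abs(bi.resid - bj.resid) < min_seq_sep:
            continue
        r0 = float(np.linalg.norm(coords[i] - coords[j]))
        if r0 <= 0:
            continue
        eps = eps_rule(bi, bj) if eps_rule else DEFAULT_CONTACT_EPS
        pairs.append((i, j, r0, eps))
    return ContactSet(pairs, sigma=sigma, label=label)


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def assign_charges(topology, charge_context=None, neutralize_tags=()) -> ChargeTable:
    """Resolve per-bead charges for both interaction contexts.

    Protein beads get formal charges (K/R → +1, D/E → −1, else 0); phosphate
    beads are dual-valued per :class:`ChargeContext`; beads whose tags
    intersect ``neutralize_tags`` are zeroed in all contexts.
    """
    ctx = charge_context or ChargeContext()
    n = topology.n_beads
    q_intra = np.zeros(n)
    q_cross = np.zeros(n)
    is_dna = topology.is_dna()
    for b in topology.beads:
        if b.site_kind == "residue":
            q = residue_formal_charge(b.name)
            q_intra[b.index] = q
            q_cross[b.index] = q
        elif b.site_kind == "phosphate":
            q_intra[b.index] = ctx.intra_dna_phosphate_charge
            q_cross[b.index] = ctx.cross_phosphate_charge
    for idx, q in ctx.overrides:
        if not (0 <= idx < n):
            raise IndexError(f"charge override index {idx} out of range")
        q_intra[idx] = q
        q_cross[idx] = q
    kill = set(neutralize_tags)
    if kill:
        for b in topology.beads:
            if b.group_tags & kill:
                q_intra[b.index] = 0.0
                q_cross[b.index] = 0.0
    return ChargeTable(q_intra, q_cross, is_dna)


# ---------------------------------------------------------------------------
# disordered-region conformations
# ---------------------------------------------------------------------------

def bridged_self_avoiding_walk(start, end, n_steps, step, rng, obstacles=None,
                               min_clearance=2.0, max_retries=50,
                               max_step_tries=300):
    """Self-avoiding random walk of ``n_steps`` new points from ``start``
    toward ``end`` (``end=None`` for a free terminal walk).

    Each consecutive distance equals ``step``; every new point keeps
    ``min_clearance`` from obstacles and previously placed points.  Raises if
    the gap is unbridgeable or placement keeps failing.
    """
    start = np.asarray(start, dtype=float)
    tree = cKDTree(obstacles) if obstacles is not None and len(obstacles) else None
    if end is not None:
        end = np.asarray(end, dtype=float)
        span = float(np.linalg.norm(end - start))
        if (n_steps + 1) * step < span:
            raise ValueError(
                f"gap of {n_steps} steps × {step} Å cannot bridge {span:.1f} Å")
    for _ in range(max_retries):
        pts = _walk_attempt(start, end, n_steps, step, rng, tree,
                            min_clearance, max_step_tries)
        if pts is not None:
            return pts
    raise RuntimeError(f"self-avoiding walk failed after {max_retries} retries")


def _walk_attempt(start, end, n_steps, step, rng, tree, clearance, tries):
    pts = []
    cur = start
    for k in range(n_steps):
        remaining = n_steps - k  # points left to place after this one
        placed = None
        if end is not None:
            gap = np.linalg.norm(end - cur)
            # closure bias grows as slack runs out (ρ→1 means fully taut)
            rho = gap / max(remaining * step, 1e-12)
            pull = (end - cur) / max(gap, 1e-12)
        for t in range(tries):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            if end is not None:
                w = min(1.0, max(0.0, (rho - 0.35) / 0.55) + 0.25 * t / tries)
                d = w * pull + (1.0 - w) * d
                d /= np.linalg.norm(d)
            cand = cur + step * d
            if end is not None:
                if np.linalg.norm(end - cand) > remaining * step:
                    continue
            if tree is not None and tree.query(cand)[0] < clearance:
                continue
            if pts and cKDTree(np.asarray(pts)).query(cand)[0] < clearance * 0.9:
                continue
            placed = cand
            break
        if placed is None:
            return None
        pts.append(placed)
        cur = placed
    return np.asarray(pts)


def model_idr_conformation(topology, fixed_coords, seed=0, step=CA_BOND_LENGTH,
                           min_clearance=2.0, max_retries=50) -> np.ndarray:
    """Fill in coordinates for unresolved spans (rows of NaN).

    Internal gaps are bridged by a self-avoiding walk with ``step`` Å bonds
    between their anchors; terminal spans walk freely outward.  Deterministic
    for a fixed seed.
    """
    coords = np.array(fixed_coords, dtype=float)
    rng = np.random.default_rng(seed)
    missing = np.isnan(coords).any(axis=1)
    if not missing.any():
        return coords
    fixed_pts = coords[~missing]
    for chain in topology.chains:
        i = chain.start
        while i < chain.stop:
            if not missing[i]:
                i += 1
                continue
            j = i
            while j < chain.stop and missing[j]:
                j += 1
            left = coords[i - 1] if i > chain.start else None
            right = coords[j] if j < chain.stop else None
            n_gap = j - i
            if left is None and right is None:
                raise ValueError(f"chain {chain.chain_id} has no anchored bead")
            if left is not None and right is not None:
                span = np.linalg.norm(right - left)
                if (n_gap + 1) * step < span:
                    raise ValueError(
                        f"gap {chain.chain_id}[{i}:{j}] of {n_gap} residues "
                        f"cannot bridge {span:.1f} Å anchors")
                pts = bridged_self_avoiding_walk(left, right, n_gap, step, rng,
                                                 obstacles=fixed_pts,
                                                 min_clearance=min_clearance,
                                                 max_retries=max_retries)
            else:
                anchor = left if left is not None else right
                pts = bridged_self_avoiding_walk(anchor, None, n_gap, step, rng,
                                                 obstacles=fixed_pts,
                                                 min_clearance=min_clearance,
                                                 max_retries=max_retries)
                if left is None:
                    pts = pts[::-1]
            coords[i:j] = pts
            i = j
    return coords
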