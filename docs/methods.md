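# Methods

`forkcg` implements a coarse-grained model of a replisome-like protein
assembly engaging forked DNA, the dynamics and free-energy machinery needed
to calibrate its key protein–protein interaction, and the trajectory
analytics used to characterise histone recycling at a replication fork.
This note records the model, its parameters, the numerical choices, and
what the synthetic test systems do and do not establish.

## Representation

Proteins are reduced to one bead per residue at the Cα position.  DNA uses
a three-site-per-nucleotide representation: one bead each at the base,
sugar and phosphate positions, with the 5′-terminal nucleotide of every
strand carrying no phosphate bead (so a strand of *n* nt has 3*n* − 1
beads, and an assembly has 3·nt − #strands DNA beads).  Ideal B-form
duplexes are generated on the standard fibre geometry (3.38 Å rise,
36°/bp twist) with site placements chosen to give plausible intra-
nucleotide distances; the exact site radii/phases are conventions, not
fitted quantities, because all local terms and duplex-stabilisation
contacts are anchored to the generated reference geometry.

Folded protein regions carry native-anchored harmonic bonds
(k = 100 kcal/mol/Å²), harmonic angles (k = 20 kcal/mol/rad²) and periodic
dihedrals (k(1 − cos(φ − φ₀)), k = 1 kcal/mol).  Intrinsically disordered
regions (IDRs) keep bonds only (3.8 Å) plus a weak generic angle term
(k = 1 kcal/mol/rad², θ₀ = 130°) and no dihedral, so coils stay flexible.
Duplex DNA gets native-anchored backbone bonds/angles/dihedrals plus a
native-anchored contact set covering pairing and stacking neighbours;
ssDNA gets bonds and weak angles only.  Initial conformations for IDRs and
ssDNA gaps are built by seeded self-avoiding walks bridged between their
anchors (step 3.8 Å for protein, 6 Å for ssDNA), with a closure bias that
strengthens as the remaining contour runs out.

## Energetics

The structure-based (Gō-like) attraction over a contact set with native
distances r₀ and per-pair strengths ε is

    V = σ Σ ε_ij [5 (r₀/r)^12 − 6 (r₀/r)^10],

minimised at r = r₀ with value −σε per pair.  σ is a per-set global scale;
cross-molecular sets carry their own σ so a single interaction can be
calibrated without touching intra-molecular stability.  Native contacts are
defined by any heavy-atom pair within 6.5 Å (bead–bead distance where no
atomic detail exists), sequence separation ≥ 4 within a chain; ε defaults
to 0.3 kcal/mol uniformly and is configurable per set.

Electrostatics are Debye–Hückel: U = C q_i q_j exp(−r/λ_D)/(ε_r r) with
ε_r = 78.0 and monovalent ionic strength 0.3 M at 300 K (λ_D ≈ 5.55 Å).
Protein beads carry formal charges (K/R +1, D/E −1); per-bead overrides
accept externally computed surface charges.  DNA phosphate beads are
dual-valued by interaction-partner class: −0.6 e against DNA (counter-ion
condensation) and −1.0 e against protein (counter-ion release on binding).
The cutoff is 50 Å (≈9 λ_D) with energy-shift truncation; the residual
force discontinuity there is orders of magnitude below thermal forces.
Excluded volume is ε_ev[(d/r)^12 − 1] for r < d = r_i + r_j, zero beyond,
with ε_ev = 0.6 kcal/mol and radii 2.5 Å (protein, phosphate) and 3.0 Å
(base, sugar).  1-2 and 1-3 bonded neighbours are excluded from all
nonbonded terms; contact pairs are excluded from excluded volume because
the Gō core already provides their short-range repulsion.  Nonbonded pairs
are enumerated all-against-all inside the compiled kernels: at the
≲2000-bead scale this package targets, a dense pair sweep is faster and
simpler than a neighbour list, and the pair-status mask is precomputed
once per system.

Units: Å, kcal/mol, amu, elementary charges; k_B = 0.0019872 kcal/mol/K;
the derived time unit sqrt(amu Å²/(kcal/mol)) ≈ 48.9 fs, so the standard
timestep of 0.3 time units is ≈ 14.7 fs.  Every bead carries a uniform
mass of 110 amu (the mean residue mass).  A literal "1 mass unit" per bead
would put the stiffest bond mode at ~14 rad per time unit and make the
standard timestep unconditionally unstable; since equilibrium sampling is
mass-independent, the uniform physical mass only fixes the stability
budget and the meaning of the time axis.  All forces are exact analytic
gradients; a central-difference oracle in the test suite holds the whole
stack to 10⁻⁴ relative agreement.

## Dynamics

Langevin dynamics uses the BAOAB splitting with the friction sub-step
solved exactly (Ornstein–Uhlenbeck), friction 0.843 inverse time units and
temperature 300 K by default.  BAOAB's kinetic-energy estimator carries a
known (hω/2)² discretisation bias (~4% at h = 0.3 for the stiffest bond
mode, ~1% at h = 0.15); thermostat-validation runs therefore use h = 0.15,
chosen from that closed-form estimate so the bias sits below the 2%
validation band while production runs keep h = 0.3.  Runs abort with the
last stable frame when the potential energy diverges.  Built structures
are relaxed by damped steepest descent (displacement-capped) before
dynamics; the relaxation is deterministic, preserving bit-reproducibility
of config + seed.

Replica exchange propagates one replica per temperature (default 300–390 K
in 10 K steps), proposing neighbour swaps every 1000 steps with
alternating even/odd pairing and Metropolis acceptance min(1, exp(Δβ ΔE));
swaps exchange configurations and rescale velocities by sqrt(T′/T).  The
exchange log stores every proposal (Δ, accepted) and the
replica↔temperature mapping per round, so per-temperature and per-replica
continuous trajectories are both recoverable.  Each replica draws from its
own counter-seeded generator; swap decisions use a separate stream.
Validation: per-rung mean energies and exponential-averaging free-energy
differences of a harmonically tethered bead match the closed-form
β-scaling of the Gaussian partition function, and empirical acceptance
rates match the Metropolis expectation computed from the logged Δ values.

## Binding free energies and σ calibration

The fraction of native contacts Q counts a pair as formed when
r < 1.2 r₀; the bound state is Q > 0 (any partial native-contact formation
implies binding), with a minimum-inter-molecular-distance criterion
(default 10 Å) as a robustness alternative.  From a run confined to a
sphere of radius R,

    ΔG° = −k_B T ln[(P_b/P_u) · (V_free/V°)],   V° = 1661 Å³,

where V_free is the sphere volume minus an excluded core taken as the
receptor's bounding sphere about its centre of mass.  The volume
correction is reported as a separate term so either standard-state
convention is recoverable.  Errors come from block averaging (10 blocks,
half-count continuity correction per block); bound↔unbound transitions
are counted and fewer than 5 flags the estimate.  Analysis uses the
replica at (or nearest) the target temperature; a multi-temperature
exponential-averaging estimator is available for free-energy differences
between rungs.  `calibrate_sigma` runs the full REMD + estimation protocol
per grid value and selects the σ whose ΔG° lies closest to the target —
the procedure used to pin a cross-interaction against an experimentally
measured dissociation constant.

## Fork analytics

All analyses operate on tagged bead groups so toy and real systems share
one code path.  The fork frame sets the origin at the hub-ring centre of
mass, Z along the best-fit-plane normal of the ring beads (sign fixed
toward the designated N-tier side), X as the projection of the donor-
subunit COM direction orthogonal to Z, and Y = Z × X.  Elevation
φ = atan2(v·Z, v·X) and azimuth θ = atan2(v·Y, v·X); angle statistics are
circular (means/SDs from the resultant vector) because the distributions
straddle ±180°.  Spatial densities histogram frame-local coordinates on a
5 Å grid, normalised by N · voxel volume; iso-surfaces are extracted by
marching cubes (default level 10⁻⁴ Å⁻³) and region overlap is the volume
of the intersection of two super-level sets divided by the reference-set
volume (same numerator whichever set is the reference).

Contact analyses count beads of one group within a cutoff (default 10 Å,
configurable; the classifier suite passes at 8, 10 and 12 Å) of another.
Association survival treats maximal runs of nonzero contact count as
episodes, merging interruptions shorter than a gap threshold, and reports
S(t) = fraction of episodes lasting ≥ t frames.  The recycling classifier
declares deposition when the cargo–arm contact count stays ≥ 30 beads for
≥ 50 saved frames while donor-tail contacts are ≤ 5; the destination is
that arm (parental allowed), and the pathway is carrier-mediated when the
cargo–carrier count reached ≥ 10 within the 200 frames preceding
deposition.  These defaults scale with the contact-count plateaus (tens of
beads) seen when a tetramer-sized cargo wraps an arm, and are all
configurable.  The tetrasome dyad is the median nucleotide index (counted
from the junction, which is index 0 of each daughter arm) among
destination nucleotides with any site bead within the cutoff of the cargo —
the median is robust to ragged footprint edges.  The 3D junction distance
is from the cargo COM to the junction base bead.

## Synthetic study systems

The toy replisome is not a structural model of the real machine; it
carries the statistical structure the analyses assume.  A six-chain
annular hub (four bead rows at radii 50/56 Å, z = ±3 Å, each chain one
angular sector) provides the ring for the coordinate frame; a flexible
80-residue tail with a stated charge pattern (K at every 5th residue, E at
every 11th, serine elsewhere) anchors a basic 4-helix-bundle cargo whose
composition (K/R-rich) makes it strongly positive; a carrier chain has a
folded knob and a 16-residue acidic loop (alternating D/E); forked DNA
from the fork builder hangs below the hub with configurable arms, gaps
and 0–2 rigid binder chains occluding the lagging-strand gap.  All
builders are seed-deterministic.

Scripted labelled trajectories are kinematic, not dynamical: the cargo
follows piecewise-linear paths (tail → optional carrier visit →
destination arm, plus parental and never-deposited scenarios) constructed
with ≥20% margin beyond every classifier threshold and 1 Å positional
jitter, so classifier tests are exact and fast.  Passing them shows the
classifier implements its definition correctly — not that the thresholds
are optimal for any particular force field's dynamics.

The dimer benchmark is an open dish pocket (five-bead ring plus bottom
bead, tethered at the sphere centre) binding a single-bead ligand chain;
all designed contacts (default 6, ε = 1.5 kcal/mol) form simultaneously at
the docked pose on the dish axis, the approach from above crosses no
repulsive core, and binding/unbinding cycles hundreds of times in a
minutes-long REMD run.  Its ΔG°(σ) is monotone decreasing with
well-separated steps over σ ∈ {0.5, 0.7, 0.9}, making it a sharp test of
the estimator and calibration loop.  A separate carrier–cargo subsystem
(reduced bead mass 30 amu to speed diffusion; equilibrium populations are
mass-independent) reproduces the qualitative electrostatic-capture effect:
with the acidic loop charged the cargo is held in long contact episodes
that largely disappear when the loop is neutralised.

What the synthetic systems do not show: quantitative correspondence to any
real replisome's recycling statistics, sequence-dependent DNA mechanics,
hydrogen-bonding or hydrophobic chemistry, or the production-scale
(~10⁴ beads, 10⁸ steps) regime — production runs are supported as
configuration but validated only at desk scale.

## Numerical choices and degenerate inputs

- Angle forces clamp sin θ at 10⁻⁸; collinear dihedrals contribute zero
  (undefined torsion).
- Zero distances in any pairwise term raise immediately rather than
  propagate NaN; non-finite energies name the offending term.
- The fork-frame plane fit uses SVD; a collinear ring or a donor COM on
  the ring axis is an error, not a silent default.
- Walk-based builders (ssDNA gaps, IDR spans) retry with fresh randomness
  and fail loudly with the retry count; unbridgeable gaps
  ((n+1)·step < anchor span) are rejected up front.
- Trajectory DCD round trips are single precision (≤10⁻⁴ Å); metadata
  (parameters, seeds, code version) travels in a JSON sidecar.
- Test and validation run sizes (e.g. 1.6×10⁶-step REMD for the σ scan,
  2×10⁴-step thermostat checks) are chosen so each statistical assertion
  resolves its effect at ≥3 standard errors at desk scale.

## Known limitations

- Formal charges everywhere (surface-charge optimisation is out of scope);
  the charge-override mechanism accepts externally derived values.
- Uniform contact ε (no per-contact energetic decomposition); σ absorbs
  the overall scale during calibration.
- No hydrogen-bond functional form: histone–DNA stabilisation is a
  native-anchored contact set with its own label and strength.
- Dense nonbonded masks cost O(N²) memory; fine at desk scale, a
  neighbour-list backend would be needed well beyond ~10⁴ beads.
- The two-state ΔG estimator assumes the analysis replica is equilibrated;
  the transition count and block errors surface, but cannot repair, poor
  sampling.
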