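# forkcg

Coarse-grained simulation and analysis of histone recycling at a DNA
replication fork.

When a replisome passes through chromatin, the parental H3/H4 histone
tetramer must be handed from the machinery back onto one of the two
replicated DNA strands.  `forkcg` provides the modelling stack to study
that handover at residue/nucleotide resolution: a Cα-protein /
three-site-DNA coarse-grained representation, a structure-based (Gō)
potential with screened electrostatics, Langevin and temperature-replica-
exchange dynamics, a binding free-energy estimator for calibrating the
decisive protein–protein interaction, and the full set of fork-geometry
trajectory analytics — contact kinetics, hub-ring coordinate frames and
orientation angles, spatial probability densities with iso-surfaces, and a
recycling-pathway classifier that labels each trajectory by destination
strand (leading / lagging / parental / none) and by whether the handover
was mediated by a carrier protein.

It is a library first: you import it from Python.  A thin `forkcg` CLI
(`build`, `toy`, `run`, `remd`, `calibrate`, `analyze`) wraps the same
functions for shell pipelines, and `examples/` holds one short narrative
script per capability.

## The model in brief

Proteins: one bead per residue at Cα; folded regions native-anchored
(bonds/angles/dihedrals), disordered regions flexible (bonds + weak
angles).  DNA: base/sugar/phosphate beads per nucleotide, no 5′-terminal
phosphate; ideal B-form duplexes (3.38 Å rise, 36°/bp).  Native contacts
interact through

    V = σ Σ ε_ij [ 5 (r_ij0 / r_ij)^12 − 6 (r_ij0 / r_ij)^10 ],

where σ scales a whole contact set — calibrating σ for the cross-
interaction between a histone-binding tail and its cargo is how the model
is pinned to an experimental binding free energy.  Electrostatics are
Debye–Hückel (300 mM, ε_r = 78, λ_D ≈ 5.6 Å) with formal protein charges
and dual-context DNA phosphate charges (−0.6 e toward DNA, −1.0 e toward
protein).  Dynamics are BAOAB Langevin (timestep 0.3 time units ≈ 14.7 fs,
friction 0.843); replica exchange uses Metropolis neighbour swaps.  The
bound state is Q > 0 (a native contact counts as formed within 1.2× its
native distance) and

    ΔG° = −k_B T ln[(P_b/P_u) · (V_free/V°)],  V° = 1661 Å³.

See `docs/methods.md` for every parameter, default and numerical choice.

## Worked example

Calibrating the Gō scale σ on the built-in dimer benchmark (an open dish
pocket binding a single-bead ligand inside a 30 Å confinement sphere),
exactly as one would calibrate a tail–cargo interaction against an
experimental dissociation constant:

```python
import forkcg
from forkcg.binding import BoundStateCriterion, estimate_binding_free_energy
from forkcg.dynamics import LangevinParams, ReplicaSchedule, run_remd

for sigma in (0.5, 0.7, 0.9):
    bench = forkcg.build_dimer_benchmark(sigma=sigma, seed=1)
    result = run_remd(
        bench.system,
        ReplicaSchedule((300.0, 330.0, 360.0, 390.0), 2000, seed=1),
        LangevinParams(timestep=0.3, n_steps=1_600_000, save_interval=400,
                       seed=1))
    est = estimate_binding_free_energy(
        result, BoundStateCriterion(), bench.contacts,
        receptor_indices=bench.receptor_indices, sphere_radius=30.0)
    print(f"sigma={sigma}: dG = {est.delta_G:6.2f} "
          f"+- {est.standard_error:.2f} kcal/mol "
          f"({est.n_transitions} transitions)")
```

Output (a few minutes on one core):

```
sigma=0.5: dG =  -0.75 +- 0.29 kcal/mol (83 transitions)
sigma=0.7: dG =  -1.33 +- 0.30 kcal/mol (103 transitions)
sigma=0.9: dG =  -2.77 +- 0.49 kcal/mol (157 transitions)
```

Binding strengthens monotonically with σ; `calibrate_sigma` automates the
scan and returns the σ closest to a target ΔG°.  The hundreds of
bound↔unbound transitions are what make the estimate trustworthy — the
estimator flags runs with fewer than five.

The other capabilities follow the same pattern; run any script in
`examples/`:

- `01_build_fork.py` — forked DNA with duplex arms and ssDNA gaps.
- `02_energies_and_dynamics.py` — energy breakdown, relaxation, a short run.
- `03_sigma_calibration.py` — the σ scan via `calibrate_sigma`.
- `04_recycling_analysis.py` — pathway classification of labelled
  trajectories.
- `05_orientation_density.py` — fork-frame angles and spatial densities.

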