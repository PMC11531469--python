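"""Build a replicated-DNA fork at the geometry used for the two-RPA system
(23 bp parental, 90/96 bp daughter duplexes, 33 nt leading and 56 nt lagging
ssDNA gaps) and write it out as topology JSON + coarse-grained PDB.

The printed counts follow the three-site DNA representation: every
nucleotide contributes a base, a sugar and (except at each strand's 5'
terminus) a phosphate bead, so a strand of n nt has 3n − 1 beads.
"""

from pathlib import Path

import forkcg
from forkcg import io

fork = forkcg.assemble_fork(parental_bp=23, leading_bp=90, lagging_bp=96,
                            leading_gap_nt=33, lagging_gap_nt=56, seed=0)
top = fork.topology

print(f"total beads: {top.n_beads}")
for tag in ("parental_duplex", "leading_duplex", "lagging_duplex",
            "leading_ssDNA", "lagging_ssDNA"):
    print(f"  {tag:16s} {len(top.select(tag)):4d} beads")
print(f"fork junction bead index: {top.metadata['junction_bead']}")
print(f"duplex-stabilization contact sets: "
      f"{[cs.label for cs in fork.contact_sets]}")

out = Path("scratch/fork")
out.mkdir(parents=True, exist_ok=True)
io.write_topology(top, out / "fork_topology.json")
io.write_cg_pdb(top, fork.coords, out / "fork.pdb")
print(f"wrote {out}/fork_topology.json and {out}/fork.pdb")
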