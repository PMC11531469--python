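"""Fork-frame orientation angles and spatial probability densities.

The hub-ring coordinate frame puts Z along the ring axis and X through the
donor-subunit centre of mass; a point's elevation φ = atan2(v·Z, v·X) and
azimuth θ = atan2(v·Y, v·X) describe where a strand end or the cargo sits
relative to the hub.  The cargo positions over a scripted trajectory are
histogrammed into a 3D density (normalised to integrate to 1, in Å⁻³) from
which an iso-surface can be extracted at a chosen level.
"""

import numpy as np

import forkcg
from forkcg.analysis import (circular_mean_sd, define_fork_frame,
                             orientation_angles, spatial_density)

toy = forkcg.build_toy_replisome(
    forkcg.ToySpec(chain_length=20, tail_length=40, carrier_length=24,
                   carrier_loop_length=12))
top = toy.topology
ring, donor, cargo = (top.select(t) for t in ("hub_ring", "donor_hub",
                                              "cargo"))

pairs = forkcg.generate_labeled_trajectories(("leading-mediated",), 1,
                                             seed=3, toy=toy)
traj = pairs[0][0]

phis, thetas = [], []
for frame in traj.frames:
    fr = define_fork_frame(frame, ring, donor)
    ang = orientation_angles(fr, frame[cargo].mean(axis=0))
    phis.append(ang.elevation_phi)
    thetas.append(ang.azimuth_theta)
mp, sp = circular_mean_sd(phis)
mt, st = circular_mean_sd(thetas)
print(f"cargo elevation phi: {mp:6.1f} deg +- {sp:.1f} (circular)")
print(f"cargo azimuth theta: {mt:6.1f} deg +- {st:.1f} (circular)")


def frame_fn(coords):
    return define_fork_frame(coords, ring, donor)


grid = spatial_density([traj], frame_fn,
                       lambda c: c[cargo], grid_spacing=5.0)
print(f"density integral: {grid.integral():.9f} (must be 1)")
level = 1e-4
print(f"super-level-set volume at {level} A^-3: "
      f"{grid.superlevel_volume(level):.0f} A^3")
verts, faces = grid.isosurface(level)
print(f"iso-surface mesh: {len(verts)} vertices, {len(faces)} triangles")
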