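"""Phantom blood smear through the simulated microscope.

Generates the default synthetic field (granulocytes, lymphocytes and
monocytes over 29 bands, 470-750 nm), acquires the four analyzer cubes with
1% detector noise, reconstructs Stokes and DOP cubes, and summarizes the
class contrast and reconstruction quality.
"""

import numpy as np

from stokescope import (
    NoiseModel,
    PhantomSpec,
    compute_derived,
    compute_stokes,
    generate_phantom,
    physicality_report,
    simulate_acquisition,
)

scene = generate_phantom(PhantomSpec(seed=3))
print(f"scene: {scene.spatial_shape} px, {scene.n_bands} bands, "
      f"{len(scene.cell_records)} cells")

stack = simulate_acquisition(scene, noise=NoiseModel(kind="gaussian", level=0.01), seed=11)
cube = compute_stokes(stack)
derived = compute_derived(cube)
print(f"clipped pixels (noise pushed DOP above 1): {derived.n_clipped}")

rep = physicality_report(cube)
print(f"physicality violations: {rep.total_violations} px "
      f"({100 * rep.total_fraction:.3f}% of the cube), "
      f"max excess {rep.max_violation:.4f}")

print("\nmean DOP over ground-truth masks (band-averaged):")
for rec in scene.cell_records:
    mask = scene.cell_mask(rec.cell_id)
    print(f"  cell {rec.cell_id:2d} {rec.class_label:12s} "
          f"{rec.n_pixels:4d} px   DOP = {derived.dop[:, mask].mean():.3f}")
# Granulocyte-like cells depolarize most (DOP ~ 0.5), lymphocyte-like least
# (~0.3); the clear background transmits unpolarized light (DOP ~ noise).
bg = scene.labels == 0
print(f"  background                DOP = {derived.dop[:, bg].mean():.3f}")
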