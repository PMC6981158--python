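"""Particle image velocimetry on synthetic bead images.

Renders a field of fluorescent beads, displaces it by a known sub-pixel
amount, and recovers the displacement with windowed cross-correlation
(32 px windows, 50% overlap, 3-point Gaussian sub-pixel fit).
"""

import numpy as np

from monolayer_mechanics import piv, synthetic as syn
from monolayer_mechanics.fields import GridSpec, VectorField2D

beads = syn.make_bead_image(256, 256, 900, noise_sd=2.0, seed=0)

grid = GridSpec((0, 0), 17, 17, 16.0)
shift = VectorField2D(grid, np.full(grid.shape, 0.6), np.full(grid.shape, -0.3), "px")
moved = syn.warp_image(beads, shift)

field = piv.piv_displacement(beads, moved)
valid = field.valid
print(f"windows: {valid.size}, valid: {valid.sum()}")
print(f"mean recovered displacement: ({field.u[valid].mean():+.3f}, "
      f"{field.v[valid].mean():+.3f}) px   (truth: +0.600, -0.300)")
rms = np.sqrt(((field.u[valid] - 0.6) ** 2 + (field.v[valid] + 0.3) ** 2).mean())
print(f"RMS error: {rms:.3f} px")
# The RMS error of a few hundredths of a pixel is what makes sub-micron
# substrate deformations measurable at 1.294 µm/px.

vel = piv.to_velocity(piv.interpolate_to_grid(field, 16, 1.294), 1.294, 5.0)
print(f"as velocity at 5-min frame interval: mean u = "
      f"{vel.u[vel.valid].mean():.4f} µm/min on a {vel.grid.spacing:.1f} µm grid")
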