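"""Monolayer stress from traction by regularised force-balance inversion.

The 2D stress tensor σ of a thin adherent sheet satisfies div σ = t with
t the traction it exerts on its substrate.  This example builds a stress
field with analytically known divergence, inverts the traction with the
Bayesian-style estimator (Λ = 10⁻⁶, free-stress boundary on the
cell-free edge), and compares against the ground truth.
"""

import numpy as np

from monolayer_mechanics import bism, synthetic as syn, tension
from monolayer_mechanics.fields import GridSpec

grid = GridSpec((0, 0), 46, 46, 20.72)
truth, traction = syn.make_stress_field(grid, "potential_bumps", {
    "bumps": [
        {"potential": "x", "amplitude": 5e3, "center": (380, 430), "width": 120},
        {"potential": "y", "amplitude": 3.5e3, "center": (500, 380), "width": 100},
    ]
})

inferred = bism.infer_stress(traction, bism.BismConfig(lambda_=1e-6,
                                                       free_edges=("right",)))
for name in ("sxx", "syy", "sxy"):
    r = np.corrcoef(getattr(truth, name).ravel(), getattr(inferred, name).ravel())[0, 1]
    print(f"Pearson r({name}) truth vs inferred: {r:.4f}")

residual, _ = bism.residual_report(traction, inferred)
print(f"force-balance residual |Aσ - t|/|t|: {residual:.2e}")

tau = tension.isotropic_tension(inferred)
print(f"bulk isotropic tension (200 µm margins discarded): "
      f"{tension.bulk_average(tau, 200.0):.2f} Pa·µm")
# Pearson correlations near 1 and a residual far below 1% mean the
# inversion reproduced both the stress pattern and the force balance.
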