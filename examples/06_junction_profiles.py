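"""Quantifying junction fluorescence: cross-section profiles and kymographs.

Builds a two-channel image with a bright ridge along a cell–cell
interface (e.g. a GFP-tagged cadherin and an mCherry-tagged partner),
samples perpendicular cross-sections, recentres them on the membrane
channel's peak, and aggregates min–max-normalised profiles.
"""

import numpy as np

from monolayer_mechanics import profiling, synthetic as syn
from monolayer_mechanics.fields import FrameSequence
from monolayer_mechanics.profiling import LineSegment

image = syn.make_junction_image((96, 96), ((48, 5), (48, 90)),
                                ridge_sigma_px=2.5, channel_peaks=(1000.0, 600.0),
                                noise_sd=15.0, seed=0)

lines = [LineSegment(20.0, 10 + 8 * i, 76.0, 10 + 8 * i, width_px=3) for i in range(9)]
ps = profiling.cross_section_profiles(image, lines, center_channel=0)
print(f"{ps.n} cross-sections aggregated ({ps.n_degenerate} degenerate excluded)")
mid = np.argmin(np.abs(ps.positions))
print(f"normalised intensity at the interface: "
      f"channel 0 = {ps.mean[0, mid]:.2f} ± {ps.sd[0, mid]:.2f}, "
      f"channel 1 = {ps.mean[1, mid]:.2f} ± {ps.sd[1, mid]:.2f}")
# Position 0 is the membrane-channel peak; both channels peaking there
# with small s.d. indicates stable co-localisation at the interface.

frames = [image[0] for _ in range(6)]
kymo = profiling.kymograph(FrameSequence(frames, 1.0, 5.0),
                           LineSegment(20.0, 48.0, 76.0, 48.0))
print(f"kymograph shape (positions x time): {kymo.shape}; "
      f"a static junction gives identical columns: "
      f"{np.allclose(kymo[:, 0], kymo[:, -1])}")
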