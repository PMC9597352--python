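"""Threshold a punctate image and measure organelle sizes.

Mirrors the usual confocal workflow for measuring lysosome size: apply a
maximum-entropy (Kapur) threshold, label connected components (8-neighbour
connectivity), and report per-particle areas in square micrometres.  Here
the image is synthetic, so the recovered count can be checked against the
planted ground truth.
"""

import numpy as np

from vesiquant import kapur_threshold, mean_particle_area, segment_particles, synth_two_channel_puncta

img, _, truth = synth_two_channel_puncta(
    n_puncta=60, coloc_fraction=0.0, puncta_radius_px=4, noise_sd=8.0, seed=3
)
threshold = kapur_threshold(img)
mask, table = segment_particles(img, threshold, connectivity=8, min_area_px=4)

print(f"max-entropy threshold: {threshold:.1f} (background {truth.background}, puncta {truth.background + truth.intensity})")
print(f"particles found: {len(table)} (planted: {len(truth.centers_a)})")
print(f"mean particle area: {mean_particle_area(table):.4f} um^2")
analytic = np.pi * (truth.radius_px * img.pixel_size) ** 2
print(f"analytic disk area: {analytic:.4f} um^2 (r = {truth.radius_px} px at {img.pixel_size} um/px)")
print("\nper-particle table (first 5 rows):")
print(table.head().to_string(index=False))
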