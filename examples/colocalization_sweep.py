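"""Pearson and Manders coefficients across a known colocalization ladder.

Generates two-channel punctate images in which a controlled fraction of
channel-B puncta share centres with channel-A puncta, then runs the
thresholded colocalization pipeline (per-channel maximum-entropy threshold,
Pearson correlation, Manders M1/M2).  M2 — the fraction of supra-threshold
B signal inside A-positive pixels — should track the planted fraction.
"""

from vesiquant import coloc_pipeline, synth_two_channel_puncta

print(f"{'planted':>8s} {'M1':>6s} {'M2':>6s} {'PCC':>7s}")
for fraction in [0.0, 0.25, 0.5, 0.75, 1.0]:
    a, b, truth = synth_two_channel_puncta(
        n_puncta=200, coloc_fraction=fraction, noise_sd=5.0, seed=7
    )
    res = coloc_pipeline(a, b)
    print(
        f"{fraction:8.2f} {res.manders_m1:6.3f} {res.manders_m2:6.3f} "
        f"{res.pearson_r:7.3f}"
    )
print(
    "\nM1/M2 rise from 0 to 1 with the planted overlap; the Pearson\n"
    "coefficient rises too but mixes in intensity correlation, which is\n"
    "why overlap fractions and correlation are reported separately."
)
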