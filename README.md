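# vesiquant

Quantitative analysis of intracellular vesicle trafficking from microscopy
data: single-particle track motility classification, organelle morphometry,
two-channel colocalization, radial intensity distributions, and scalar
fluorescence assays (CTCF, pulse-chase degradation, ratiometric pH).

It is written for cell biologists quantifying endosome/lysosome behaviour —
for example whether a receptor's carriers move processively toward the cell
centre (dynein-driven retrograde transport), whether two markers occupy the
same compartments, or whether organelles enlarge or redistribute after a
perturbation.

## What it computes

**Track motility.** For each 2D trajectory (≥ 25 frames retained), the
time-averaged mean squared displacement over all overlapping pairs,

```
MSD(Δt) = ⟨ |r(t + Δt) − r(t)|² ⟩ ,
```

is fit by ordinary least squares to the power law

```
log MSD(Δt) = α log Δt + C ,
```

and the anomalous-diffusion exponent α classifies the track: **processive**
(α > 1.45, directed motor-driven transport), **diffusive** (1 ≤ α ≤ 1.45),
or **non-processive** (α < 1, confined/stalled). A rolling-window version
of the same exponent segments each track into active and passive phases;
the **run length** of an active phase is its net displacement in µm, binned
into a 1-µm histogram at the population level.

**Images.** Maximum-entropy (Kapur) histogram thresholding; connected-
component particle morphometry (areas in µm²); Pearson correlation and
thresholded Manders overlap coefficients M1/M2; concentric-ring radial
profiles about a centre and fixed-width ring profiles measured outward from
the nuclear rim by a distance transform, normalized to total cell intensity.

**Scalar assays.** CTCF = integrated density − (cell area × mean
background); residual fractions of a pulse-chase time course normalized to
the t = 0 pulse; fold change of summary intensities; an ordinary
least-squares pH calibration line (340/380 excitation ratio vs buffer pH
over pH 4–6) with inverse read-out of measured ratios.

A synthetic-data module generates trajectories (ballistic, Brownian,
confined, two-state switching), punctate two-channel images with a known
colocalized fraction, radially structured cells, calibration readings and
decay time courses — each with ground truth — so the whole pipeline is
testable without microscopy data.

## Worked example

`examples/` holds one short script per capability. From
`examples/colocalization_sweep.py`, which plants a known colocalized
fraction and recovers it through the thresholded pipeline:

```
 planted     M1     M2     PCC
    0.00  0.047  0.007  -0.703
    0.25  0.282  0.254  -0.378
    0.50  0.502  0.503  -0.308
    0.75  0.750  0.751   0.080
    1.00  0.998  0.998   1.000
```

M1/M2 track the planted overlap fraction; the Pearson coefficient rises
with it but also reflects intensity correlation, which is why both are
reported. From `examples/intensity_assays.py`:

```
calibration: ratio = -0.6230 * pH + 4.5166 (residual SE 0.0083, n = 7)
ratio 1.04 -> pH 5.58
CTCF(1000, 10 px, 5/px) = 950  (integrated density minus area x background)
```

The fitted line inverts a measured 340/380 ratio to a lysosomal pH, flagged
when it falls outside the calibrated range.

## Command line

Each analysis stage is also a `vesiquant` subcommand operating on CSV/TIFF
inputs and writing CSV/JSON outputs plus a run report (parameters, version,
seed, input checksums):

```sh
vesiquant simulate --kind switching --n-tracks 200 --out sim/
vesiquant motility --tracks sim/tracks.csv --min-frames 25 --out mot/
vesiquant coloc --a chanA.tif --b chanB.tif --auto-threshold --out coloc.json
vesiquant radial --image img.tif --nucleus-mask nuc.tif --cell-mask cell.tif --ring-width 5 --out profile.csv
vesiquant ph --calibration cal.csv --ratio 1.04
```

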