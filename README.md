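# wellmotion

Image-based quantification of *Caenorhabditis elegans* movement in
multiwell plates, for acute drug-response experiments: from raw well
images to fractional mobility scores, dose-response curves with EC50s,
and paralysis-recovery statistics.

## The problem

A standard way to measure the acute effect of a compound on worms is to
bathe populations of animals in liquid in a 96-well plate and watch how
much they move. Imaging each well **twice in quick succession**
(hundreds of milliseconds apart) and comparing the two frames gives a
simple, robust movement readout without tracking individual animals:
pixels that changed belong to worms that moved, pixels that stayed
belong to worms that did not. Repeating every few minutes for hours
yields a dose x time picture of paralysis and — surprisingly often — of
*recovery* from paralysis.

`wellmotion` implements that assay's analysis end to end, plus a
synthetic well-image generator with exact ground truth, so every stage
of the pipeline is testable without a microscope.

## The measurements

**Fractional mobility score (FMS).** For a frame pair (Im1, Im2) of one
well:

1. Gaussian-blur both frames; Sobel edge filter on the reference frame
   (frame 1); local-mean adaptive threshold; two iterations of binary
   closing (fills worm interiors between their side edges); circular
   mask removing the well rim → binary **reference** mask of worm
   pixels. In adult mode, connected components below a size threshold
   are dropped (removes eggs, which some compounds stimulate).
2. `|Im1 − Im2|` thresholded → binary difference image. It flags moving
   pixels from *both* frames, so it is intersected with the
   single-frame reference to correct the double count → **moving**
   mask; the remainder of the reference is **stationary**.
3. `FMS = |moving| / |reference|` ∈ [0, 1].

**Normalization and curves.** Drug-well FMS is divided by the mean FMS
of drug-free control wells at the same timepoint. Dose-response columns
are fitted by least squares with either the three-parameter logistic

    f(x) = A + (1 − A) / (1 + e^(−B(M − x)))

whose midpoint `M` is the EC50 (upper plateau fixed at 1, floor `A`,
slope `B`, linear concentration axis), or the exponential
`f(x) = M·e^(−x) + A` for shallow responses; the family is chosen from
the range of the data unless overridden.

**Proportional recovery.** For a normalized time course,

    score = (FMS_after_recovery − FMS_min) / (1 − FMS_min)

with `FMS_after_recovery` the mean over the final 30 minutes (150–180
min for the standard 3-hour assay) and `FMS_min` the minimum over the
whole course; 0 = no recovery from maximal paralysis, 1 = full return
to control-level movement.

## Worked example

```python
import numpy as np
from wellmotion import (SceneConfig, simulate_well_pair, quantify_well,
                        DoseResponseModel, logistic3)

# a synthetic well: 10 worms, half displaced between the two frames
cfg = SceneConfig(n_worms=10, moving_fraction=0.5, seed=42)
f1, f2, truth = simulate_well_pair(cfg)
rec = quantify_well(f1, f2)
print(f"true moving fraction: {truth.true_moving_fraction:.3f}")
print(f"measured FMS:         {rec.fms:.3f}  ({rec.moving_px}/{rec.total_px} px)")

# a dose-response fit (Model -> Results, statsmodels-style)
doses = np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0])
rng = np.random.default_rng(0)
y = logistic3(doses, A=0.1, B=5.0, M=0.76) + rng.normal(0, 0.02, doses.size)
res = DoseResponseModel(doses, y).fit()
print(res.summary())
```

prints

```
true moving fraction: 0.478
measured FMS:         0.468  (2488/5317 px)

Dose-Response Fit
==============================================
family:     logistic3
nobs:       8
converged:  True
rss:        0.000845714
----------------------------------------------
param         estimate       std err
A             0.110374    0.00652599
B              5.14508      0.210804
M              0.76069     0.0122515
----------------------------------------------
EC50 (M):   0.76069
```

The measured FMS (0.468) agrees with the generator's ground truth
(0.478: half the worm pixels were displaced between frames), and the
fit recovers the generating EC50 of 0.76 concentration units from noisy
responses, with standard errors from the Gauss–Newton approximation.

## Command line

```sh
wellmotion simulate plate_dir --rows 2 --cols 6 --timepoints 5   # synthetic plate
wellmotion quantify plate_dir plate_dir/plate_map.csv results.csv
wellmotion fit results.csv plate_dir/plate_map.csv fits.csv
wellmotion recovery results.csv plate_dir/plate_map.csv recovery.csv
```

Plate directories follow `t{index:04d}/{Well}_f{1,2}.tif` (8- or
16-bit grayscale TIFF, well IDs `A01`–`H12`); the plate-map CSV has
columns `well,compound,dose,unit,strain,stage,is_control`. `--adult`
enables the egg size filter; a YAML config can fix all segmentation
parameters per plate.

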