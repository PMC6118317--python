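# Methods

This note documents the models and procedures `wellmotion` implements,
the parameters that matter, what the synthetic generator does and does
not emulate, and the design choices made where the design was open.

## Movement quantification

Each well is imaged twice per timepoint, a sub-second interval apart.
Worms that moved between the two frames produce large absolute
intensity differences; worms that did not produce none. The per-well
pipeline is:

1. **Pre-blur.** Both frames are Gaussian-blurred (`blur_sigma`,
   default 1 px) to suppress sensor noise before any thresholding.
2. **Reference mask.** The first frame of the pair is the designated
   reference. Sobel gradient magnitude highlights worm outlines; a
   local-mean adaptive threshold (block 51 px) keeps pixels whose edge
   response exceeds the neighbourhood mean by `adaptive_offset`
   (default 0.01 on the [0, 1] intensity scale) — adaptive so uneven
   well illumination does not shift the segmentation. Two iterations of
   binary closing with a 3x3 square element fill the interior between a
   worm's two side edges; a centered circular mask
   (`mask_radius_frac = 0.95`) removes the bright well rim. In adult
   mode, 8-connected components smaller than `min_object_px` are
   dropped: eggs laid during the assay segment as small blobs and would
   otherwise count as stationary "worm" pixels.
3. **Difference mask.** `|frame1 − frame2| > diff_threshold`. The raw
   difference flags the moving worms at *both* their old and new
   positions — about twice the truly moving pixels — so it is
   intersected with the single-frame reference mask (moving = diff AND
   reference), and stationary = reference AND NOT moving. The three
   masks partition exactly by construction.
4. **Score.** FMS = |moving| / |reference|. Wells whose reference mask
   holds fewer than `min_worm_pixels` (default 50) pixels are marked
   invalid (NaN) rather than scored: an empty well has no meaningful
   denominator.

### Calibration of the segmentation defaults

`adaptive_offset` and `diff_threshold` have no universal values; they
were calibrated once against the synthetic generator at its default
scene conditions and then frozen. Two findings drove the choices:

* Worm recall of the reference mask is 1.0 for any offset in
  [0.005, 0.02]; 0.01 keeps background false positives ~1% of the
  in-circle area (the residue is the 2–3 px edge halo the Sobel band
  and closing add around each worm, not noise).
* That halo makes `diff_threshold` matter more than expected: a
  conservative threshold (e.g. 0.04 at default contrast 0.4) does not
  reach the outer halo, deflating FMS by a systematic ~0.8x. At 0.01
  the difference image covers the halo of displaced worms and per-level
  FMS error stays below 0.05 across the full range of moving fractions,
  while identical frames still score exactly 0 and the noise floor at
  zero motion is ~0.01. Contrast scaled by 0.8 changes FMS by < 0.02,
  so the fixed difference threshold is tolerant of moderate
  illumination drift.

Because FMS is later normalized to same-plate controls, any residual
multiplicative bias common to all wells cancels in the normalized
traces.

## Normalization and response traces

For each timepoint, drug-well FMS is divided by the mean FMS of the
plate's valid drug-free control wells at that timepoint; replicate
wells of a condition are averaged first (mean, with the replicate count
kept per point). Timepoints where the control mean falls below a floor
(default 0.05) are marked missing instead of dividing by a near-zero
number. Normalization is per plate; cross-plate batch structure is out
of scope. Normalized values may exceed 1 (wells can out-move
controls).

## Dose-response fitting

Two curve families, both fitted on the **linear** concentration axis
exactly as the formulas read (a log-dose option exists but is off by
default):

* **Three-parameter logistic** `f(x) = A + (1−A)/(1+e^(−B(M−x)))`:
  upper plateau fixed at 1 (normalized untreated mobility), floor `A ∈
  [0,1]`, slope `B > 0`, midpoint `M` = EC50 constrained to the tested
  dose range extended by one decade. Fitting uses
  `scipy.optimize.least_squares` (TRF, bounded) from a multi-start
  grid — A ∈ {0, 0.25, 0.5}, M at the 25/50/75% dose quantiles, B ∈
  {0.5, 2, 10}/dose-scale — keeping the lowest residual sum of squares,
  ties broken toward the shallower slope. Needs ≥ 4 distinct doses.
* **Exponential** `f(x) = M·e^(−x) + A` for shallow responses. This is
  linear in (M, A) and solved exactly by ordinary least squares; ≥ 3
  distinct doses. Note the family has no concentration-scale
  parameter: `x` enters as printed, so the fit inherits the dose units.
  This asymmetry is deliberate and documented rather than silently
  "fixed".

Model choice (`select_model`): logistic when the responses resolve both
the high plateau (max > 0.8) and substantial inhibition (min < 0.5),
exponential otherwise; an explicit user override always wins. The
0.8/0.5 thresholds are this package's concretization of "choose by the
range of the data" and are arguments, not constants.

Results objects carry Gauss–Newton standard errors (finite-difference
Jacobian at the optimum, residual variance on n − k degrees of
freedom). These are asymptotic and indicative; with 8 doses they are
not a substitute for replicate-level confidence intervals.

## Recovery scoring and response classes

`score = (FMS_after − FMS_min) / (1 − FMS_min)`, with FMS_min the
minimum of the normalized trace over the whole assay and FMS_after the
mean over the recovery window — (150, 180) min for the standard 3-hour
assay, otherwise the final 30 minutes. Traces whose minimum never drops
below 1 − ε (ε = 0.05) show no paralysis and the score is undefined
(flagged, not NaN-by-accident). Scores land in (−∞, 1]: 1 is full
return to control movement; negative values mean the window average
sits below the earlier minimum (still-deepening paralysis).

Time courses are labelled `no_effect` (minimum stays above 0.8),
`sustained_paralysis` (recovery score < 0.2), `sustained_recovery`
(window mean within 0.1 of the post-minimum maximum) or
`transient_recovery`. These thresholds operationalize the qualitative
notion of multi-phase responses; they are exposed as arguments and are
not claimed to reproduce any particular published tally.

## Synthetic data

**Scenes.** A bright circular well (background 0.7) on a dark surround
(0.05), dark worms (0.3) rendered as smoothed random-walk tubes
(unit steps with Gaussian curvature jitter, constant width), optional
small egg discs at worm intensity, additive Gaussian noise (σ = 0.01,
clipped to [0, 1]). Worms are placed with a 6 px clearance so closing
cannot merge neighbours; a chosen count fraction is displaced between
frames to **fully disjoint** positions (escalating the displacement
magnitude, and finally re-placing anywhere in the well, if crowding
blocks the nominal offset). Ground truth records per-worm masks for
both frames and the true moving pixel fraction, which is exact because
placements never overlap. Eggs are placed last from an independent RNG
stream with doubled clearance, so scenes differing only in egg count
share identical worms, motion and noise — paired comparisons isolate
the size filter. Everything is deterministic under a fixed seed.

The default test scene is 256x256 px with 6 worms of 24–36 px length;
the generator default is 512x512 with 10 worms (image resolution per
well is a free parameter of the assay). The full-plate checks
(96 wells x 10 timepoints) use the 256 px scene, which keeps a complete
simulate → quantify → fit → recovery cycle within a couple of minutes
on one CPU.

**What the generator does not emulate:** partial (overlapping) motion —
available behind the disjointness fallback but excluded from oracle
tests; out-of-focus blur, vignetting and illumination gradients beyond
what the adaptive threshold already absorbs; worm postural change
without displacement; shot noise; debris. Passing the oracle tests
therefore shows the pipeline recovers the moving fraction when motion
is unambiguous and contrast is adequate — not that it matches any
specific microscope's imagery.

**Kinetics.** Response surfaces follow a two-phase model: normalized
FMS(x, t) = 1 − depth(x)·p(t)·(1 − extent·r(t)), with depth(x) =
max_depth·(1 − L(x)) for a three-parameter logistic L in dose,
paralysis onset p(t) = 1 − e^(−k_p·t), and delayed recovery r(t) = 1 −
e^(−k_r·(t − t_onset)) after the onset time. With recovery off, the
late-time dose column equals L(x) exactly (onset rate 0.1/min leaves
e^(−18) residue at 180 min), which is what makes noiseless
parameter-recovery tests exact. The 2.1-fold midpoint separation used
in the shift-recovery check mirrors the magnitude of a competitive
antagonist's effect on an agonist's EC50.

## Degenerate inputs and numerical notes

* Identical frames give a difference image of exactly zero, hence
  FMS = 0 with no tolerance needed.
* Blank wells fail the `min_worm_pixels` floor and come back invalid,
  never as 0/0.
* Constant dose-responses: the exponential family admits the exact
  degenerate solution (M = 0, A = c); the logistic fit converges to a
  plateau with near-zero residual and is flagged only by its
  uninformative parameters, not an exception.
* The logistic's exponent is clipped at ±700 to avoid overflow at
  extreme slopes; the fitted curve at x = M equals (1 + A)/2 by
  construction, which the tests use as a closed-form check.
* CSV round trips preserve all fields; invalid records serialize with
  an empty FMS field and `valid=False`.

## Known limitations

* FMS is a population-level pixel statistic: it cannot distinguish ten
  half-paralysed worms from five fully paralysed ones, and it saturates
  for very dense wells where worm footprints merge.
* The fixed difference threshold assumes worm/background contrast well
  above noise; very low-contrast imagery would need recalibration of
  the frozen defaults.
* Standard errors from a single plate ignore between-plate variance;
  replicate experiments should be aggregated upstream.
* The exponential family's unit dependence (no rate constant in x)
  means its parameters are comparable only within one dose unit.
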