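# Methods

This note records the models, conventions and numerical choices behind the
package, the reasoning where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real cards.

## Coordinate and signal conventions

All card geometry is expressed in millimetres with the origin at the
top-left card corner, x rightward, y downward; images use pixel
coordinates with the same handedness, and a pixel at array index (i, j)
has coordinates (x=j, y=i). A rectified image at scale `s` px/mm places
the reference point (x, y) mm at pixel (x·s, y·s). One convention,
used everywhere, removes sign ambiguity from the homography.

Greyscale is the unweighted channel mean (R+G+B)/3 — not luma weights.
The choice is arbitrary; consistency between calibration and measurement
is what matters, so the same definition is used in both. Because blue
colour development darkens the indicator circle, the measured signal is
`255 − greyscale`, which increases with analyte. ROI integration is the
*mean* over member pixels (pixels whose centres fall inside the layout
circle), making signals independent of photograph resolution.

## Card layout

The layout is configuration, not code (`data/default_layout.yaml`):
zone geometry, quantitative ranges, control roles, colour standards and
fiducial positions can all change without touching the pipeline. The
bundled design has 12 zones in a 4×3 grid: three replicate ladders
(0–12, 10–24, 22–36 ppm) giving triplicate coverage of 0–35 ppm, one
high-range zone (28–50 ppm), one positive control and one negative
control. Which zones serve as controls on the original card is not
public; the assignment here is a documented stand-in, and the validator
only requires that at least one of each exists.

Two deliberate geometric choices:

- **Asymmetric fiducial constellation.** Fiducials are matched to the
  layout purely by the shape of the detected constellation under a
  similarity transform. A constellation with 180° rotational symmetry
  would be ambiguous, so the sixth mark sits off-grid, making the match
  unique.
- **Footprint validation via exact geometry** (shapely): containment and
  pairwise non-overlap of all printed elements are checked exactly, and
  violations are returned as a list (naming element and rule) rather than
  raised, so a layout editor can show all problems at once.

Serialization rounds lengths to 0.01 mm; a save/load round trip is exact
at that precision.

## Forward model (simulation)

Zone chemistry is piecewise linear: signal = background below the
threshold, rising by `gain` per ppm above it, clipped at saturation.
Defaults are background 45 and saturation 175 signal units. Both numbers
are constrained from two sides of the imaging physics:

- the *lower* background bound keeps bright (unreacted) indicator circles
  below channel value 212, so an illumination gain up to 1.2 cannot clip
  them against the 8-bit ceiling — clipped colour is unrecoverable by any
  white balance, and the pipeline is required to undo casts exactly;
- the *upper* saturation bound keeps fully developed spots (grey ≈ 80)
  clearly lighter than fiducial ink (grey 15), as on a printed card where
  indicator spots develop blue, not black, so blob detection can never
  confuse a developed spot with a registration mark.

The blue tint of a developed spot is rendered with channel offsets that
preserve the channel mean exactly and respect the 212 ceiling.

Rendering evaluates the card's analytic appearance at every pixel centre
through the inverse perspective, so region interiors carry exact colours
(no resampling). Colour development bleeds 0.5 mm past the indicator
circle, so the measured interior stays uniform after the pipeline's own
bilinear resampling; physically, the applied drop wets the whole circle.
Defects are applied scene-then-camera: perspective, then diagonal-RGB
illumination gain, then i.i.d. Gaussian pixel noise clipped to [0, 255]
and quantized to 8 bits. A single seed threads through all stochastic
draws; renders are bit-reproducible.

Controls develop by role, not by sample: the positive control carries its
own analyte (always saturates) and the negative control is masked (never
develops). Control faults for testing are injected by overriding the
analyte amount an individual zone sees.

Default imaging ranges — nominal scale 4.5–6 px/mm, rotation ±8°, tilt
±12°, per-channel gains 0.85–1.15, noise SD 2–5 — describe a hand-held
photograph of a card in a light box: visible keystoning and cast, but a
legible card. Gains stay below 1.2 for the clipping reason above.

What the simulator does *not* model: reflectance/Beer-Lambert physics,
lens distortion beyond projective, spatially varying illumination, reagent
aging, humidity, or within-zone development texture. Passing tests
therefore demonstrate the *software* recovers what the forward model
encodes under the defects the pipeline claims to correct — not that a
physical card achieves any particular accuracy. The published field
metrics (e.g. ~7 ppm accuracy) require physical samples and are out of
scope; the synthetic round trip instead demands MAE ≤ 2 ppm with ≥ 95%
acceptance over 200 random cards, which the implementation exceeds by a
wide margin (MAE ≈ 0.03 ppm).

## Imaging pipeline

Fiducial candidates are connected components of pixels darker than grey
50 (black ink under the dimmest modelled cast is ≈ 13; the darkest
developed spot is ≈ 68), filtered by area ≥ 30 px and isoperimetric
circularity ≥ 0.5, keeping at most the 8 largest. Centroids are
intensity-weighted. Matching scores every injective assignment of
candidates to layout marks by the RMS residual of the best similarity
transform (closed-form, reflections excluded since cards are never
mirrored); ties break deterministically. With three or more candidates a
match is attempted; fewer are unidentifiable and reported as none.

The geometric correction is a full 8-DOF homography — keystoning is
projective, an affine model cannot express it — estimated by normalized
DLT over all matched marks (≥ 4 required, collinear configurations
rejected). Rectification resamples bilinearly at 10 px/mm by default;
output pixels with no source data get a sentinel colour and a False entry
in a validity mask, and any ROI touching such a pixel is flagged
unreadable.

White balance follows rectification (mask alignment and measurement
follow it in turn). Gains are nominal/measured channel means over the
brightest neutral patch that is fully sampled and unsaturated; a channel
mean ≥ 250 means clipping has destroyed the cast information, so such
patches are skipped and the card is unreadable only if no neutral patch
survives. Patch means use a 1 mm inset to avoid edge blur.

## Calibration and quantification

Per-zone curves are ordinary least squares over standards that sit
strictly between the background and saturation plateaus; a plateau is a
run of two or more extreme points whose consecutive signals change by at
most 1 unit (a single extreme point is not identifiable as flat and is
kept). At least three distinct usable concentrations are required and the
fitted slope must be positive. The linear signal range is the [min, max]
of fitted values at the usable standards — gating is deliberately
conservative: the curve is never extrapolated beyond where it was
observed. Inversion is exact over that range (machine precision).

Aggregation over in-range replicate zones uses the median (robust to one
mis-developed zone; the original software's combination rule is not
public) with ties resolved as the mean of the middle pair, and reports
dispersion as MAD × 1.4826. Outputs are rounded to 0.1 ppm; internal
values keep full precision.

Control expectations are configuration (per-zone signal intervals), with
defaults negative ≤ 80 and positive ≥ 140 signal units — roughly halfway
between the modelled background (45) and saturation (175), leaving equal
headroom for noise and residual cast on either side.

A card whose sample exceeds the top calibrated range has every
measurement zone out of range and is rejected as `no_in_range_zones`;
the reader does not guess "above range". In a survey over 0–120 ppm
samples such cards simply yield no classification. A production reader
covering that span would add high-range zones (a card-design change, i.e.
a layout file, not a code change).

Rejected cards keep whatever per-zone readings were measured before the
failing gate, for diagnostics; gates earlier in the chain (fiducials,
neutral patch) leave no readings.

## Statistics layer

Classification edges follow the stated inequalities exactly: adequate iff
≥ 15 ppm; the 30–50 ppm QC band includes both edges; spray actions
trigger strictly below 32 and strictly above 46 ppm. Contingency tables
take *binner callables* rather than numeric bin edges so closed bands are
expressible; accuracies are ratios of correct to total counts over any
row subset. ROC operating points are generated at every distinct score
threshold and integrated by the trapezoid rule, which equals the
Mann-Whitney probability of correct ranking with half credit for ties;
tests verify this against exhaustive pair counting up to n = 50.
"Accuracy" is the mean over samples of |mean replicate − titration|,
"precision" the mean of per-sample replicate SDs (ddof = 1, the
convention for duplicate analyses). The paired comparison is a two-sided
one-sample t test on the differences, with "indistinguishable" defined as
zero inside the confidence interval. The fraction of under-30 ppm samples
called sellable is reported with both plausible denominators (all
readings, and under-30 readings only), since the choice is ambiguous.

## Problem sizes and determinism

The test suite and acceptance script use: 24-point calibration ladders,
200-card round trips, 100 random homographies, 30 corrupted-control
cards, 60 AUC oracle instances, 2,000 t-test replicates, and an 80-card
simulated survey — sizes at which the Monte-Carlo checks are stable at
their stated tolerances while the whole suite runs in a few minutes.
Every stochastic quantity is driven by an explicit seed (the acceptance
script derives independent per-section generators from its `--seed` via
`SeedSequence`); renders, analyses and CSV outputs are byte-reproducible.

## Known limitations

- The simulated chemistry's thresholds/gains are constructed from the
  layout's stated ranges, not measured from real reagents.
- Fiducial matching is exhaustive over assignments (fine for 6 marks;
  would not scale to dozens).
- White balance is a single diagonal gain; spatially varying illumination
  is neither simulated nor corrected.
- The QR region is carried as an opaque rectangle; card identity comes
  from file names, and calibration files are keyed by design version as a
  stand-in for a QR-driven lookup.
- Quantification is censored outside the calibrated span (see above).
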