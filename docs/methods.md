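# Methods

## Problem

Black-blood late-gadolinium-enhancement (BL-LGE) cardiac MRI nulls both the
ventricular blood pool and healthy myocardium so that scar — which retains
contrast agent — stands out.  The contrast hinges on one parameter, the
inversion time TI: the delay between the magnetization preparation and the
readout.  Before the whole-heart acquisition, a *TI scout* is acquired: a
short series of co-registered single-shot short-axis images at increasing
TIs (by default 60–160 ms in 10 ms steps, 11 images), from which the TI
that best nulls blood and myocardium must be picked.  `tiscout` automates
that pick with plain image processing, no segmentation and no learning.

## Selection algorithm

Inputs: the scout series and the rectangular shim box the operator placed
over the heart at the scanner (its outline in contact with the myocardial
border).  The pipeline:

1. **ROI.** A region concentric with the shim box, either a rectangle with
   the shim's dimensions divided by `k` (aspect preserved, each side
   rounded to the nearest pixel, floor 4) or a disk of diameter
   `min(width, height)/k` (guaranteed to stay inside the box).  The
   validated operating point is a rectangle at `k = 2.5`.  The ROI needs
   no anatomical accuracy: it only has to sample blood pool, or blood pool
   plus myocardium, because the preparation is tuned so both tissues null
   near a common TI.

2. **Histograms.** For each image `n`, a bin-size-1 histogram `h_n(i)`
   over integer gray levels `i ∈ [0, maxPI]` of the ROI pixels.  Input
   images are quantized once at the boundary (clamp, round half up);
   `maxPI` defaults to 4095 (12-bit), configurable.

3. **Common threshold.** Well-nulled tissue spans few gray levels, so the
   best-nulled image carries the tallest histogram peak of the whole
   series.  Let `α = argmax_n max_i h_n(i)`; the threshold is
   `S_thr = argmax_i h_α(i)`.

4. **Selection.** `g(n) = Σ_{i ≤ S_thr} h_n(i)` counts sub-threshold ROI
   pixels; the selected TI is the one of `argmax_n g(n)`.

Tie rules (the reference description is silent; these are deterministic
and storage-order independent): gray-level argmax ties break toward the
lower level; peak-height ties across images break toward the image whose
peak sits at the *lower* gray level — the better-nulled image — then
toward the lower TI; `g` ties break toward the lower TI.  The
lower-mode-first rule matters in degenerate (noise-free, piecewise-
constant) inputs, where every image's peak height saturates: it makes an
identically-zero image win over uniformly bright ones, which a pure
lower-TI rule would not.

Whether "under this threshold" counts `i ≤ S_thr` or `i < S_thr` is not
observable from the reference description; both are implemented
(`threshold_mode="inclusive" | "strict"`), inclusive by default since the
modal level of the best-nulled image itself represents nulled tissue.

## Quality control

Two rules, both advisory (the tool only flags; it never re-acquires):

* **Boundary.** If the first (last) grid image is selected, the true null
  may lie below (above) the scouted range: flag `extend_lower`
  (`extend_upper`) and suggest extending the grid by 5 native increments,
  never below 10 ms.  Interior selections are unflagged.
* **Artifact.** Bright artifacts in the ROI depress the sub-threshold
  fraction `g(selected)/|ROI|`.  Against a reference median of that
  fraction built from ≥ 3 trusted cases, a case is flagged when its
  fraction falls below `tolerance_factor ×` the median.  The default
  factor is 0.75: an artifact replacing a fraction *f* of the ROI scales
  the sub-threshold fraction by about `1 − f`, so 0.75 detects artifacts
  occupying more than roughly a quarter of the ROI while tolerating
  ordinary variation.  No clinically validated cut-off exists; the factor
  is an engineering default and a parameter.  Note the fraction is only a
  stable statistic when the global-peak image is unambiguous; at high
  noise it grows heavy upper tails (see *Limitations*).

## Synthetic phantom

The generator emulates a mid-ventricular short-axis slice: circular blood
pool (radius ≈ inner myocardial radius), myocardial annulus, optional scar
sector inside the annulus, background tissue.  Per-compartment magnitude
signal follows a surrogate inversion-recovery model

    S(TI) = | m0 · (1 − (1 + η) · e^(−TI / T1_eff)) |,

a stand-in for the sequence's magnetization-prepared bSSFP contrast, whose
one essential property is that blood and healthy myocardium null near a
common TI inside the scouted range.  Defaults (post-contrast-like
surrogates, not measured values): blood `m0 = 600`, `T1_eff = 150 ms`;
myocardium `400 / 160 ms`; scar `500 / 60 ms` (bright at the nulling TI);
background `300 / 800 ms`; `η = 1`.

**Intra-tissue heterogeneity.** Strictly uniform compartments would make
every noiseless ROI histogram a delta function: all images would tie on
peak height and the threshold step would degenerate to its tie-break.
Real tissue intensity varies smoothly (proton density, receive profile,
partial volume), and — crucially — that spread scales with the mean
signal, which is exactly the property the algorithm exploits.  The
phantom therefore multiplies each compartment by `1 + β·u`, where `u` is
a deterministic diagonal ramp through the heart center scaled to span
about [−1, 1] across a default (shim/2.5) ROI, and `β = 0.2`.  A ramp is
used rather than a periodic texture because its value density is flat: a
sinusoid's arcsine density puts spikes at every band's edges, which
masquerade as histogram peaks at all TIs.  With `β = 0.2` a tissue far
from its null spans a band several times wider than the noise floor,
while the nulled tissue collapses toward the Rician floor — the contrast
the method needs.

**Noise and quantization.** Rician noise (magnitude of the clean signal
plus two independent Gaussian channels of scale `noise_sigma`, default 12
gray levels = 2 % of blood `m0`), then clamp to `[0, maxPI]` and round
half up.  Signals exceeding `maxPI` are clipped with a logged warning.
Generation is bit-reproducible under a fixed seed.

**Shim box.** Tight bounding box of the outer myocardial circle padded by
2 px, emulating the operator guideline.

**Ground truth.** The grid TI minimizing the mean of the *quantized
noiseless* images over blood ∪ myocardium, ties toward the lower TI.
Quantized rather than continuous means keep truth and selection consistent
in razor-edge cases where two grid TIs straddle the null almost
symmetrically.

**Randomized sampling.** `sample_phantom_spec` varies geometry only
(heart position ± 6 px, outer radius 22–30 px, wall 6–10 px, scar sector
present with probability 0.3); tissue parameters stay at the defaults
above, which are the simulated study conditions.  With
`shared_null=True`, both tissues' `T1_eff` are instead drawn within ± 3 %
of a common value whose null (uniform in 75–145 ms) lies in the scouted
range, and draws are rejected until blood and myocardium share their
grid-argmin nulling TI — the regime the scanner-side preparation
optimization is designed to realize, and the precondition under which
noiseless recovery is exact.

**Artifact injection** is limited to a bright horizontal streak
(constant across TIs, ± 20 % internal modulation) used to exercise the QC
artifact rule.

## What the phantom does and does not show

Passing recovery tests demonstrates that the selection logic extracts the
nulling TI whenever the core contrast mechanism (narrow histogram at the
null) holds, and that it degrades gracefully with noise.  The phantom has
no cardiac or respiratory motion, no bSSFP banding, no coil-array
sensitivity structure, no through-plane partial volume, and perfectly
co-registered images; performance on it does not bound performance on
patient data.  With the default (non-shared-null) tissues, blood's own
grid-argmin sits one grid step below the blood + myocardium truth, so the
blood-dominated ROI typically selects 100 ms against a 110 ms truth —
which is why noisy recovery is quoted as the fraction within one grid
step (10 ms), the same granularity used when comparing automated and
expert selections.

## Agreement statistics

Selections are categorical ratings on the TI grid.  Fleiss' kappa is
computed per rater pair (the two-rater Fleiss formulation) via
`statsmodels`, with the category set equal to the TIs observed in the
table; an overall kappa per grouping is the arithmetic mean of its
pairwise kappas.  Perfect observed agreement returns exactly 1.0; a table
in which every rating is one single category has chance agreement 1 and
raises an explicit error.  Strength bands: ≤ 0.2 Poor, ≤ 0.4 Fair,
≤ 0.6 Moderate, ≤ 0.8 Good, ≤ 1.0 Excellent.  Because kappa ignores the
size of disagreements, pairs are also summarized by the mean ± SD absolute
TI difference and the percentage of exactly matched TIs.

The ROI sweep evaluates both shapes over divisors 1.0, 1.1, …, 4.0 (31
values) against per-series reference TIs, reporting mean ± SD absolute
difference, percent matched, and failure counts for degenerate cells
(possible only for small disks; rectangles have a 4 × 4 px floor, and any
ROI below 16 px is refused).

## Numerical and interface choices

* Pixel coordinates are 0-based, row-major; the shim box is half-open,
  `[x0, x0+width) × [y0, y0+height)`; `x` indexes columns.
* Disk membership: pixel center within the radius.
* Median (QC reference): mean of the two central values for even counts.
* Scout series are re-sorted by ascending TI on construction and on read;
  duplicate TIs, mixed image dimensions and out-of-range intensities are
  rejected at the boundary.
* DICOM input takes the shim rectangle as explicit configuration; vendor
  private tags are not parsed.
* Problem sizes in the test suite and the acceptance script (128 × 128
  phantoms, 20 noiseless + 100 noisy recovery runs, 50 brute-force
  series) are chosen so the whole suite runs in seconds while the
  binomial margins on the pass/fail fractions stay meaningful.

## Limitations

* The surrogate signal model is not an extended-phase-graph simulation of
  the actual preparation; `T1_eff`/`η` are effective constants.
* The sub-threshold fraction that drives the artifact check is bimodal at
  high noise (it saturates at 1 when the global peak lands on a non-
  selected image), so the artifact rule is most reliable at moderate
  noise; its cut-off has no clinical validation.
* No registration between scout images is attempted; motion between TIs
  is out of scope.
* Kappa confidence intervals are not provided.
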