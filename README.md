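# tiscout

Automated inversion-time (TI) selection for black-blood late-gadolinium-
enhancement (BL-LGE) cardiac MRI TI scouts.

BL-LGE imaging nulls both the ventricular blood pool and healthy
myocardium so that scar tissue, which retains gadolinium, appears bright.
The image contrast depends on a single timing parameter — the inversion
time — chosen per patient from a *TI scout*: a short series of short-axis
images acquired at increasing TIs (typically 60–160 ms in 10 ms steps, 11
images).  Picking the best-nulled image by eye is slow and
reader-dependent; `tiscout` automates it for MR operators, sequence
developers and imaging researchers who want a reproducible, explainable
selection that runs anywhere plain Python runs.

## Method

Given the scout series and the operator-placed shim box (a rectangle in
contact with the myocardial border, reused as a coarse heart localizer):

1. Extract an ROI concentric with the shim box — rectangle or disk, sized
   `FOV_shim / k` (default: rectangle, `k = 2.5`).
2. For each image `n`, compute the bin-size-1 intensity histogram
   `h_n(i)` of the ROI pixels.
3. Set the common threshold from the global histogram peak:

       α     = argmax_n  max_i  h_n(i)
       S_thr = argmax_i  h_α(i)

4. Count sub-threshold pixels `g(n) = Σ_{i ≤ S_thr} h_n(i)` and select

       TI_auto = TI of argmax_n g(n).

The nulled image has the narrowest intensity distribution, hence the
tallest histogram peak; thresholding at its mode and maximizing the
sub-threshold count picks the image where blood and myocardium are
darkest.  Quality-control rules flag selections at the grid boundary
(suggesting a scout extension range) and suspected ROI artifacts (a
sub-threshold fraction well below a reference median).  The package also
ships a synthetic scout phantom with known nulling TI, agreement
statistics (pairwise Fleiss' κ, mean absolute TI difference, percent
matched) and the ROI shape/size sweep used to choose `k`.  See
`docs/methods.md` for assumptions and parameter rationale.

## Worked example

Simulate one noisy scout and select its TI:

```sh
$ tiscout simulate --out demo --n 1 --seed 7
wrote 1 series to demo
$ tiscout select --input demo/series_000.tiff --output demo/result.json
selected_ti_ms=100
```

`demo/result.json` then contains (abridged):

```
selected_ti_ms:      100.0
threshold:           64
subthreshold_counts: [0, 0, 3, 361, 576, 574, 344, 12, 1, 0, 0]
roi_pixel_count:     576
qc.boundary_flag:    "none"
```

Reading: the common threshold landed at gray level 64; of the 576 ROI
pixels, the counts below threshold peak at the 5th image (TI 100 ms),
with its neighbors (90 and 110 ms) close behind and far-from-null images
near zero — the expected V-shape around the nulling point.  The simulated
phantom's true blood + myocardium null is at 110 ms
(`demo/ground_truth.csv`), one grid step from the selection: the ROI is
dominated by blood, whose own null sits slightly below the joint null.
The interior selection raises no QC flag.

The same pipeline is available as a library:

```python
from tiscout import read_series, select_ti

series = read_series("demo/series_000.tiff")        # or a DICOM directory
result = select_ti(series)                          # rectangle, k = 2.5
print(result.selected_ti_ms, result.threshold)
```

Other subcommands: `tiscout qc-reference` (build the artifact-check
median from trusted results), `tiscout agree` (κ and partial agreement
from a ratings CSV), `tiscout sweep` (ROI shape × divisor error sweep).

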