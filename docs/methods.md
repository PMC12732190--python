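# Methods

## Assay model

A hemagglutination run is a plate (or plate pair) of two-fold serial
dilutions, one series per row, with 100 µL retained per well after each
transfer.  Well `n` of a series started at concentration `C₀` (ng/µL)
therefore holds

```
m(n) = C₀ · V / f^(n−1)        (V = 100 µL, f = 2, well 1 undiluted)
```

of analyte — or of *powder*, when the series describes a w/v extract
(10% w/v ≡ 100,000 ng powder/µL).  The titer assigned to an endpoint at
well `n_lp` is `HAU = f^(n_lp−1)`, the reciprocal of the last agglutinating
dilution, following the convention that counts only the pre-cell-addition
serial dilution (the 1:2 dilution by the red-cell suspension is not
included).  Two useful identities follow: `m(n)/m(n+1) = f` exactly, and
`HAU · m(n_lp) = C₀·V` (the bookkeeping conserves the well-1 load).

## Imaging and endpoint determination

Photographs are converted to 8-bit grayscale by standard luminance
weighting; rotation, cropping and a linear exposure offset are explicit
config options, never auto-detected.  The physical scale is calibrated as
`mm_per_px = d_well / w_px` from one well's measured edge-to-edge pixel
width and the manufacturer's well-bottom diameter.  A circular ROI grid
(default 95% of the well-bottom diameter) is laid out row-major from a
single anchor well center at the well pitch; computing the grid from one
anchor (rather than dragging ROIs by hand) is what makes headless,
reproducible analysis possible.

Within each ROI, pixels with gray value in **[0, 235]** (inclusive upper
bound, of 256 levels) are segmented; pixels outside the ROI are treated as
white background.  Area is the segmented pixel count × `mm_per_px²`;
multiple connected components in one ROI are **summed** into a single area
(with a diagnostic component count), so a fragmented edge-effect mat is
measured on the same footing as a contiguous one.  No size or circularity
filters are applied.  An empty ROI reports area 0 with its centroid pinned
to the ROI center.  Wells are ordered by ascending centroid x within a row.

Positivity is decided against the PBS negative-control row of the same
run: a well is positive iff its area **strictly exceeds**
`mean + 3·SD` of the negative-control areas (sample SD, n−1 denominator;
the multiplier is configurable).  Strictness matters only for the
degenerate SD = 0 case, where ties call negative.  Each run must carry its
own negative-control row — pellet areas drift with red-blood-cell age, so
the API provides no way to reuse a threshold across runs.  At least two
negative wells are required; the default is a full PBS row.

The endpoint is the **last positive** well (highest positive index); the
first negative well follows it.  Any sub-threshold well strictly left of
the last positive well is flagged as the **edge-effect artifact** — at high
lectin concentration the mat rolls into small polygons whose thresholded
area is deceptively small — and is never allowed to terminate the series.
This turns an instruction to "ignore" such wells on a graph into a
deterministic rule: artifacts are exactly the negative calls left of the
rightmost positive call.  An all-negative series is censored (`HAU < 1`),
never reported as zero.  Series longer than one plate (24 wells) are
concatenated by well index before calling; the caller is agnostic to plate
boundaries.  The positive-control row is QC-gated: if its endpoint misses
the expected well (tolerance 0 by default), the run fails QC (CLI exit
code 2), the operational signal to repeat the assay.

## Quantitation

Given the minimal analyte amount θ that produces detectable agglutination
(default 200 ng), the active-lectin content of a powder extract is

```
conc = θ / m_powder(n_fn) × 1000   [mg active analyte / g dry powder]
```

using the powder mass in the first negative well.  Because the assay's
experimental accuracy is ±1 dilution step, uncertainty is reported as
±1-step bounds, not propagated CIs.  A series that never goes negative
yields a right-censored lower bound (computed at a hypothetical next
dilution step).

ELISA standards (0–300 ng) are fit by ordinary least squares,
`A = α + β·ng`, with a t-distribution 95% CI on β and replicates entering
individually (visible in the CI's residual degrees of freedom).  The model
is deliberately linear, not 4PL, matching the single-coefficient
calibration this workflow uses; the intercept is estimated rather than
forced through zero because a 0-ng standard implies a measurable blank.
Back-calculation divides the blank-corrected absorbance by β and converts
with config-supplied constants (well volume 100 µL, extract powder load
0.1 mg/µL for 10% w/v):
`conc = ng/V · DF / load / 1000` mg/g.  Results below the 15 ng LLOQ are
censored at the LLOQ-equivalent bound; results above the top standard are
flagged rather than extrapolated.  A non-positive fitted slope makes
quantitation refuse (error), not return nonsense.  Exposure dose is
`conc × dry mass` (mg), with an optional fold-margin against a reference
dose (default 544 mg, the four-raw-seed estimate).

Computation is kept at full precision throughout; display rounding happens
only at the reporting layer.  The worked powder example illustrates why:
200/610.35 × 1000 = 327.68 mg/g at full precision, while rounding the well
mass to 610 ng first gives 327.87; both truncate to 327 for integer
display, and the package never bakes in either rounding.

## Synthetic plate renderer

The renderer exists so the imaging pipeline can be validated end-to-end
against known ground truth.  It emulates the features the pipeline
actually exploits: a white backlit background (gray > 235), red-toned well
contents whose luminance falls below the threshold, an area contrast
between broad mats and compact pellets, near-endpoint morphologies
(oblong fuzzy mats, donuts), edge-effect polygons, an illumination
gradient, and Gaussian sensor noise.  All randomness flows through one
seeded generator; renders are bit-reproducible.

Positivity is simulated as a logistic in `log₂(amount/θ)` with width
`logistic_width` (default 0.15; 0 gives a hard step at θ = 200 ng).  The
width default is deliberately nonzero so near-endpoint ambiguity is
exercised; the hard step is used where determinism is the point.  Positive
wells far above θ render as mats (~85% of the ROI), wells within 1–3
doublings of θ as fuzzy mats or donuts (~28–55%), negatives as pellets
(~4%).  Above `edge_effect_amount_ng` (default 150,000 ng ≈ 9–10 doublings
over θ, where crude extracts show the artifact but purified controls
usually do not) wells render as 2–4 small polygons totalling 1–2% of the
ROI — *below* the pellet band, so the analyzer classifies them negative
and must flag them as artifacts without shifting the endpoint.  Polygon
count and size are free parameters of the renderer; no quantitative
morphology for them exists to calibrate against.

Pellet-area variation is **bounded**: per-well jitter is a two-sided shell
(`|δ| ∈ [h/2, h]`, default h = 10% of the pellet area), optionally shifted
by a scalar red-cell-age offset shared across a run.  The shell was chosen
over a plain uniform because its SD is 76% of its support half-width, so
three sample-SDs estimated from a finite negative-control row robustly
exceed the maximum pellet deviation — i.e. the renderer honours the
separation premise of the mean+3SD rule.  Real pellet-area distributions
have tails the renderer does not model; consequently the end-to-end
recovery results bound pipeline error (segmentation, thresholding,
artifact handling), not biological false-positive rates.

Other idealizations: no meniscus refraction or specular highlights, well
contents centered up to ±1 px jitter, hard (non-anti-aliased) shape edges,
illumination gradient ≤ 3% so the background never crosses the threshold.
Passing tests therefore demonstrate correctness of the measurement and
calling logic under controlled contrast, not robustness to poorly lit or
misaligned photographs — real-image robustness is governed by the explicit
rotation/crop/exposure pre-processing and the requirement that plates be
photographed flat and backlit.

## Numerical and validation choices

* Grid/geometry defaults for synthetic work: 9.0 mm pitch (ANSI/SLAS),
  6.4 mm well-bottom diameter, 0.1 mm/px scale (ROI radius 30.4 px).  For
  real photographs all of these are config values.
* End-to-end validation renders at 0.15 mm/px (ROI radius ≈ 20 px), a size
  at which 100 plate pairs (300 sample rows spanning HAU 1–8192, every
  plate carrying an edge-effect row) render and analyze in well under a
  minute; recovery of the ground-truth endpoint is exact on all 300 rows
  in the suite's seeded run, against a ≥95%-exact / never-off-by->1
  acceptance bar.
* Area oracles: rendered pixel counts are compared *exactly* against an
  independent brute-force count, and against analytic shape areas within
  2% (rasterization error at radii ≥ 12 px stays below this).
* Standard-curve validation: a noise-free fit recovers its generating
  slope to machine precision; at 0.01 AU noise the 95% CI covers the true
  slope in ≥ 93/100 seeded replicates and the slope bias over 1000
  replicates is < 1%.
* Wet-lab calibration constants (θ = 200 ng, LLOQ = 15 ng, the published
  per-target slopes) are *inputs* with defaults, never recomputed: they
  are properties of reagents and instruments, not of this code.

## Known limitations

No automatic plate localization, deskewing or perspective correction (the
protocol controls parallax physically); no color-based classification of
red-cell states; no inter-plate ELISA normalization beyond per-plate
standards; the donut morphology is captured only through its area, not as
a distinct class; and the renderer's noise model is too clean to stand in
for validation on real photographs of aged or turbid samples.
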