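# Methods

## The analysis model

`flowintern` scores compound internalization per cell from a three-channel
image of each event: a brightfield channel carrying the cell silhouette, a
compound fluorescence channel, and a viability-dye channel (PI-like). The
method assumes round, suspension-type cells (MT-4-like lymphoblasts are the
motivating case) imaged at ~1 µm pixel pitch, where the plasma membrane is an
unresolved ~1 px ring at the silhouette edge.

### Masks

The **object** mask is an Otsu threshold on the absolute deviation of the
brightfield image from its modal (histogram-mode, 256-bin) background, with
holes filled and the largest 8-connected component kept. The **tight** object
additionally closes and erodes by 1 px (intersected with the default mask, so
tightening is strictly anti-extensive). All structuring elements are 3×3
squares and all components 8-connected — one convention used everywhere.

**Adaptive erosion** shrinks a mask by repeated 1-px erosions until its area
first drops to or below `coefficient/100` of the original (coefficient 100 is
the identity; if erosion would empty the mask, the last nonempty iterate is
returned). The coefficient therefore keeps a "percent of area retained"
meaning. This is a deterministic, shape-preserving stand-in for proprietary
intensity-contour-guided erosion operators; no equivalence to any vendor
implementation is claimed, and whether such coefficients denote area percent
or an intensity percentile is an open question we resolve as area percent.

The **cytoplasm** is the adaptively eroded (default 70%) object, intersected
with the tight object; the **membrane** is tight-minus-cytoplasm. By
construction membrane ∪ cytoplasm = tight object and membrane ∩ cytoplasm =
∅, exactly, for every cell. The optional **nucleus** mask is the nuclear
channel's object eroded 3 px and clipped to the object.

### Per-cell statistics

* Intensity features subtract the modal background estimated outside the
  object mask and clip negatives to zero before summing — robust to puncta.
* **Internalization coefficient**: IC = log₁₀(mean intensity over the target
  mask / mean over the whole-cell mask), clamped to [−6, 6]. Means, not sums:
  with sums a nested target forces the ratio ≤ 1 and a "> 0 ⇒ internalized"
  rule could never fire; with means the rule is well defined. A cell with
  zero whole-cell signal is unscorable (missing, not 0).
* **GLCM entropy**: in-mask intensities are quantized to 256 levels by linear
  min–max scaling (making the statistic invariant to affine intensity
  rescaling); co-occurrences are accumulated over pixel pairs with both
  endpoints in the mask, at an offset of `granularity/pixel size` (≥ 1 px,
  default 1 µm), over the four standard directions, symmetrized, normalized,
  and H = −Σ p log₂ p with 0·log 0 = 0. No valid pair ⇒ missing, not 0; a
  constant in-mask image gives exactly 0.
* **Focus metric**: RMS central-difference gradient magnitude over the
  object, normalized by mean in-mask intensity, ×100.
* Morphometrics: area (pixel count × pixel area), marching-squares contour
  perimeter, circularity = mean/SD of boundary-to-centroid distances (capped
  at 100 when the SD vanishes), aspect ratio = minor/major second-moment
  ellipse axes. The circularity and focus formulas are this package's own
  stand-ins for undocumented vendor definitions.
* **Bright-detail similarity**: Pearson correlation of white-top-hat filtered
  (disk radius 3 px) channel pairs within a mask, clamped to [0, 1]. A
  published "log-transform" of this score is not reproducible from its
  description (no stated map takes a log-transformed r into [0, 1]), so the
  clamped raw correlation is reported.
* **1-D profile colocalization**: signed Pearson r of two channels sampled
  along a line (unit spacing, linear interpolation); negative r along a
  diameter indicates interior signal anti-correlated with a membrane marker.

### Gating cascade

Fixed order: focus → time → singlets → viability → uptake → internalization.
Defaults: gradient RMS ≥ 40; timestamp ≥ 20 s; area ∈ [50, 300] µm² and
aspect ratio ≥ 0.6; PI total < 10⁴ (strict, matching the threshold's
definition as the level live cells stay under); compound total ≥ 0 (or
"auto": negative-control mean + 3 SD); IC > 0 (strict). Viability and
internalization are strict inequalities; all other bounds inclusive. Cells
with a missing feature fail the gate that reads it. When a spillover matrix
is supplied, fluorescence totals are unmixed (observed · S⁻¹) before the
viability and uptake gates. Focus and singlet thresholds have no published
values; the defaults are calibrated against the synthetic generator and must
be re-tuned for real instrument data.

Summary percentages are nested: viable % of all events, uptake % of viable
singlets, internalized % of uptake-positive cells; median entropy and median
IC are taken over uptake-positive cells.

### Spillover

S[i,j] is the fraction of channel-i signal appearing in channel j (unit
diagonal). It is estimated from single-stain controls as the median over
positive events of the secondary/primary total ratio — a median-ratio
estimator chosen over a regression slope for robustness to noise; positives
are events above the control's low-quartile background + 3 SD (falling back
to all nonzero events when the control is uniformly bright), with ≥ 20
required. Compensation acts on scalar per-cell totals, which suffices for
gating; per-pixel unmixing is out of scope.

### Statistics layer

Report tables (one per time point, tab-separated, a `File` column of
`<object>_<Num>.daf` entries) are parsed by splitting each file stem at its
*last* underscore — object names may contain underscores; only spaces are
forbidden. Comparative analysis runs on units that survive an exclusion
screen (object present at every time point, ≥ 2 replicates each, nonzero
variance; at least three replicates are recommended since multiple-comparison
tests misbehave under very low variance); descriptive statistics always use
the full table.

Between objects at one time point: one-way ANOVA (F = MSB/MSW), ω² =
(SSB − (k−1)·MSW)/(SST + MSW), with a 95% CI obtained by inverting the
noncentral-F CDF for the noncentrality λ and mapping ω² = λ/(λ+N); Tukey HSD
p-values from the studentized range (Tukey–Kramer for unequal n) and Cohen's
d from the pairwise pooled SD; Benjamini–Hochberg step-up across the pairwise
family of each (parameter, time). Within an object across time: one-way
within-subject decomposition on complete cases (SS_subject, SS_time,
SS_error), F = MS_time/MS_error, GES = SS_time/(SS_time + SS_subject +
SS_error) with a seeded 2000-resample percentile bootstrap over subjects for
the CI; paired t-tests per time pair with dz = mean(diff)/SD(diff) and BH
across the time-pair family. CI methods are this package's choices — the
upstream description specifies 95% CIs but no construction. No sphericity
correction is applied by default (none is specified upstream); a zero
error SS is reported as an infinite F with a flag rather than silently
capped. Zero-variance difference pairs are logged and given no p-value.

## The synthetic generator

The generator emulates what the analysis assumes, with one seed driving
everything through counter-keyed per-event substreams (bit-reproducible, any
prefix independent of gallery length).

* **Geometry**: cells are disks of radius 7–8 px (uniform integer) at ~1 µm
  pitch — MT-4-sized; the range is chosen jointly with the default singlet
  area gate so singlets fall inside [50, 300] µm² and doublets outside. The
  brightfield silhouette extends 1.3 px beyond the fluorescence disk (an
  optical halo): this matches the ~1.2 px effective shrink of one 8-connected
  erosion, so the tight-minus-cytoplasm band straddles the membrane ring.
  Brightfield texture (CV 0.10) is confined to the cell core so the Otsu
  boundary stays smooth.
* **Compound channel**: each cell internalizes with probability
  `internalized_fraction` (default 0.7). Internalizers carry the whole
  `total_signal` (10⁵ a.u.) strictly inside the interior (disk minus the 1 px
  membrane ring), either diffusely (smoothed multiplicative texture) or as
  4 Gaussian puncta of σ = 1 px (sparse endosome-like foci — the low-entropy
  contrast); membrane-bound cells carry it strictly on the ring. Fields are
  smoothed within their region and renormalized, so placement is exact and
  totals conserve to machine precision before noise.
* **Viability channel**: PI total 5×10⁴ (dead, 10% of events) vs 10³ (live),
  spread over the disk — cleanly separable at the 10⁴ gate.
* **Nuisances**: doublets (5%) are two disks 1.8 radii apart (second-moment
  aspect ratio ≈ 0.49, under the 0.6 singlet cut); defocused events (5%) are
  blurred with σ = 3 px; Gaussian read noise (SD 2) and a flat fluorescence
  background (5) are added last, clipped at zero. Timestamps are cumulative
  exponential arrivals at 10 events/s, so roughly the first 200 events of a
  500-event gallery fall inside the 20 s carryover window — deliberately
  exercising the time gate.
* **Single-stain controls** mix the raw fluorescence channels per pixel by a
  given spillover matrix before background and noise.

What it does *not* emulate: real point-spread functions, spectral emission,
autofluorescence, cell-cycle size variation, irregular or adherent cell
shapes, or segmentation of touching cells. Passing tests therefore
demonstrate internal correctness of the mask algebra, scores, gates and
statistics under the stated geometry — not instrument-level accuracy on real
data, where focus/singlet thresholds and mask coefficients need re-tuning.

## Numerical conventions and problem sizes

Ties and degenerate inputs: blank images raise an empty-mask error; a cell
whose masks cannot be built gets an all-NaN feature row and fails every gate;
boundary values follow the strict/inclusive rules above. The test suite and
the acceptance script use 500-event galleries for end-to-end checks, 200 for
IC sign rates, 100 matched pairs for the entropy contrast, and 20 random
designs for statistics cross-checks — sizes at which the binomial error of
every rate sits well inside the asserted margins.
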