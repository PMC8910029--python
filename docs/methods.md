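# Methods

`punctaquant` quantifies the accumulation of fluorescent condensate puncta
(P-bodies marked by GFP-tagged decapping factors in budding yeast) from
wide-field micrographs. This note documents the measurement model, the
synthetic data the test suite runs on, the numerical conventions, and the
known limitations.

## Measurement model

Each field contributes two figures of merit:

* **punctum maximal intensity** — for every segmented punctum, the largest
  pixel value over its member pixels; the distribution of maxima over all
  puncta of a group reflects condensate *density* irrespective of how many
  cells carry puncta;
* **integrated density per cell** — the sum of pixel intensities over all
  puncta of a field, divided by the field's cell count; this is the
  per-cell condensation *quantity*, and the symbol `I` entering the RRR.

The per-field chain is: shading-correct the raw image, rescale to 8 bit,
select the top 0.05% brightest pixels, group them into 8-connected
components, and read each component's area, maximum and integrated density.

### Shading correction

The instrument model is `I(x) = flatfield(x) * S(x) + darkfield(x)`, with a
multiplicative gain surface (vignetting; mean 1 by convention) and an
additive offset. A `ShadingModel` is either loaded from predefined profile
TIFFs or estimated retrospectively from the image stack itself. The
estimator alternates:

1. a robust per-pixel split of dark-field-subtracted observations into
   background and cell-covered classes (Otsu on the pooled residuals),
   summarizing the covered class by a lower-75% trimmed mean (which rejects
   bright puncta) and the background class by its mean;
2. ridge-penalized 2-D polynomial surface fits through the two summaries
   (degree 4 for the flat-field — enough for quartic radial vignetting —
   and degree 2 for the dark-field), weighted by per-pixel observation
   counts.

Iteration stops when the largest surface change falls below `tol`
(default 1e-4) or after `max_iter` (default 12) sweeps; non-convergence
is a warning plus a `converged=False` flag, never a hard failure, because
a partial correction still beats none. The `smoothness` parameter
(default 1e-3) is the ridge weight on non-constant polynomial
coefficients. Estimation requires at least 8 images (configurable floor):
below that the gain/specimen separation is badly posed. The computation
uses only per-pixel order statistics of the stack, sorted along the stack
axis first, so the result is bit-identical under permutation of the input
images. On 32 synthetic 128x128 fields with a radial flat-field spanning
[0.8, 1.2] the flat-field is recovered to roughly 1% relative RMSE
(tests assert < 5%).

One identifiability limit is inherent to retrospective estimation: a
spatially uniform ambient flux (medium autofluorescence, stray light) that
passes through the optics is absorbed into the estimated dark-field as
`flatfield * ambient + darkfield`. Correction therefore returns the
cell-borne signal above ambient, which is exactly what the puncta metrics
need; the estimated dark-field should not be read as a pure camera offset.

Correction is `max(0, (I - darkfield) / flatfield)`, in continuous
intensity units (no re-quantization), with the provenance recorded on the
output image.

### Segmentation and particle analysis

The corrected image is linearly rescaled to 8 bit. By default the rescale
uses the image's own min/max (a constant image maps to zero by convention,
and the mapping parameters are logged per image); a fixed display range
shared across compared images can be supplied instead. With
`N` pixels and top fraction `f` (default 0.0005), the budget is
`k = floor(f * N)` and the threshold is the `(N-k)`-th smallest pixel
value; the mask keeps values *strictly above* it. Ties at the threshold
are excluded, so at most `k` pixels are ever selected and a constant
image selects nothing. `floor` rather than rounding keeps the budget
conservative. Components are 8-connected and no size or circularity
filter is applied (single-pixel puncta are legitimate). Coordinates are
0-based `(row, col)`.

Punctum intensities are read from the 8-bit segmentation image by default
(`measure_on="8bit"`, the literal transform-then-measure order). The
`measure_on="corrected"` switch reads them from the full-depth corrected
image instead. The difference matters: per-image min/max 8-bit rescaling is
scale-free by construction, so any comparison of absolute intensity between
groups must either share a fixed 8-bit display range or measure on the
corrected image. The replicated comparison demos in this repository use
`measure_on="corrected"` for exactly that reason.

### Cell counting

Counts can be supplied per field; otherwise the paired phase-contrast image
is counted automatically: Otsu threshold (cells dark on light background),
hole filling, distance-transform watershed with peaks at least 12 px apart,
and a 120 px minimum region area. A contrast guard (the two Otsu classes
must be separated by at least four within-class SDs) makes background-only
fields count zero instead of shattering noise into specks. On default
synthetic fields the count is exact on >= 95% of fields and off by at most
one otherwise. A field with zero cells and any detected punctum is an
error (the per-cell metric is undefined); zero cells with zero puncta
yields an integrated density per cell of 0.

## Statistics

* `student_t` — classical pooled-variance two-sided two-sample t
  (`df = n_a + n_b - 2`); Welch available behind a flag. Zero variance
  with equal means returns `t = 0, p = 1` by convention; with unequal
  means it is an error, not a number.
* `nested_t` — values nested within independent experiments are compared
  through the nested-ANOVA ratio `t^2 = SS(group) / MS(experiment within
  group)` with `df = m_a + m_b - 2` experiments; sums of squares are
  weighted by per-experiment sample sizes, which in the balanced case is
  the exact ANOVA equivalent of the mixed-model nested t test and reduces
  *exactly* to `student_t` when every experiment contributes one value.
  Unbalanced designs reuse the same weighted sums of squares and df
  convention (no Satterthwaite adjustment) — a documented simplification.
  The test exists to guard against pseudoreplication: hundreds of puncta
  from three experiments are not hundreds of independent observations.
* `star_code` — strict thresholds: `****` p < 0.0001, `***` p < 0.001,
  `**` p < 0.01, `*` p < 0.05, otherwise `n.s.` (p = 0.05 exactly is
  non-significant).
* No multiple-testing correction is applied; stars are per-comparison,
  matching the reporting convention the pipeline reproduces.

### Relative response ratio

With `R_x = I_x,mut / I_x,wt` (integrated density per cell of construct
`x` in the mutant vs. wild-type backgrounds),

    RRR = (R_test - R_neg) / (R_pos - R_neg).

It is an affine re-anchoring of the test construct's ratio: the negative
control (empty vector) maps to 0 and the positive control (reference
scaffold) to 1, exactly; multiplying all mutant (or all wild-type) inputs
by one positive constant leaves it unchanged. A non-positive wild-type
denominator and coinciding control ratios raise distinct named errors.
By default the six inputs are grand means of integrated density per cell
over a group's fields (a per-experiment RRR distribution is a possible
extension, not implemented).

## Synthetic data

No raw micrographs are publicly available for this assay, so the generator
is a first-class module and the ground truth for every test. A field is
rendered as `flatfield * (ambient + baseline * cells + sum of spots) +
darkfield`, then Poisson shot noise (scaled by the photon gain), Gaussian
read noise, rounding to integer counts, and clipping to 16 bit.

* **Cells** are filled ellipses, semi-axes ~15-25 px (a 100x objective
  scale), placed by rejection sampling to near-non-overlap — yeast cells
  do not interpenetrate, and this keeps watershed counting well posed.
  Budding morphology is not modelled.
* **Puncta** are isotropic 2-D Gaussians truncated at 4 sigma (the standard
  diffraction-limited spot), sigma 1.0 px by default (FWHM ~2.4 px,
  ~210 nm at ~90 nm/px), placed uniformly in the interior 70% of the
  parent ellipse; counts are Poisson (negative binomial optional) and
  amplitudes log-normal.
* **Condition presets** encode the biological states: log phase (sparse dim
  puncta, amplitude 250 counts), diauxic shift (mean 1 punctum/cell,
  amplitude 800), glucose deprivation (1.2/cell, 900), vector control
  (0.8/cell, 300), scaffold overexpression and CHX persistence (0.8/cell,
  1200 — four times the vector amplitude), and dispersal presets
  (hexanediol, glucose replenishment) that zero the puncta while folding
  their whole intensity budget into the cytoplasmic baseline, conserving
  total cell fluorescence as protein levels are unchanged when condensates
  dissolve. Cytoplasmic baseline is 120 counts, ambient 20 counts,
  amplitude CV 0.2, photon gain 1.0, read noise 2.0 counts — a typical CCD
  regime at 1 s exposure.
* **Shading truth**: radial polynomial flat-field scaled into [0.7, 1.3]
  (mean 1), constant-plus-gradient dark-field (~40 counts); both are
  recorded in the ground truth, and explicit surfaces can be injected for
  recovery tests.
* **Phase images** are synthetic contrast only (dark interiors at 80 on a
  200 background, SD 2 noise) — sufficient for counting, not a physical
  phase-contrast model.
* **Replication**: an `ExperimentDesign` expands groups x experiments x
  fields with per-field seeds derived deterministically (and collision-free)
  from the base seed; identical inputs are bit-identical outputs.

Camera geometry (image size, pixel pitch) is not asserted anywhere; both
are free parameters, since the source assay specifies optics but not
detector geometry.

### What the generator does and does not show

Passing tests demonstrate that the *pipeline* recovers known effects under
a faithful noise and shading model: segmentation matches its combinatorial
definition, shading recovery is accurate, a 4x amplitude difference is
detected with the correct replicate-aware significance, dispersal lowers
both metrics, and the RRR anchors behave analytically. They cannot certify
performance on real micrographs with out-of-focus light, uneven expression,
budding or clumped cells, or camera artifacts beyond the
Poisson-Gaussian model.

## Scale of the bundled analyses

The replicated designs in the tests and `analysis/` drivers use three
experiments of two 512x512 fields with 50 cells each per group (~300 cells
per group, matching the reported monitoring scale of the assay), and the
shading-recovery analyses use 32 fields of 128x128 with 20 small cells.
These sizes give stable Monte-Carlo behaviour for every asserted margin.

## Known limitations

* The nested test's unbalanced-design df convention is a simplification
  (documented above).
* Estimated dark-field absorbs ambient flux (identifiability, above).
* Segmentation measures at most `floor(f*N)` pixels; heavily condensed
  fields saturate the pixel budget, compressing differences between very
  strong conditions (the budget, threshold and selected count are logged
  per field so this is auditable).
* No sub-pixel localization, tracking, colocalization scoring, z-stacks,
  or photobleaching model.
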