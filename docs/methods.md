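# Methods

## The measurement problem

Kinetoplastid and diplonemid protists carry unusually large amounts of
DNA in their single mitochondrion (kinetoplast DNA, kDNA). No sequencing
assay measures *total* organellar DNA mass per cell, but densitometry
can: stain cells with two chemically unrelated DNA dyes — DAPI, a
minor-groove binder strongly preferring AT-rich sequence, and RedDot1,
an intercalator nearly insensitive to base composition — image them in
two channels, separate nuclear from organellar DNA by their base
composition, and integrate the composition-insensitive channel over each
compartment. The organellar fraction *p* of total cellular DNA signal,
combined with an independently known diploid nuclear genome size *N*
(Mbp), yields the absolute organellar content

```
M_org = N · p / (1 − p),        se(M_org) = N · se(p) / (1 − p)²   (delta method).
```

`kdnaquant` implements this pipeline end to end, plus a synthetic
micrograph generator that provides exact ground truth for testing.

## Dye-response calibration

Fluorescence of each dye bound to double-stranded 100-mers of AT
fraction 0, 0.05, …, 1.0 is fit with an affine model
`f(AT) = intercept + slope·AT`, rescaled so `f(1) = 1`. An affine form
is the most complex model identifiable from 21 points with unknown
noise; the fitted DAPI response is ≈ `AT` and RedDot1 ≈ `0.70 + 0.30·AT`.
Negative background-corrected measurements are kept in the fit
(clipping would bias it) and counted in the model report.

Quantifying DNA of unknown composition with a composition-sensitive dye
while assuming AT = `assumed_at` mis-scales amounts by
`f(AT)/f(assumed_at)`; for an affine response the extreme over
AT ∈ [0, 1] sits at an endpoint. For RedDot1 at `assumed_at = 0.5` the
exact bound is `1/0.85 − 1 = 17.65%` (loosely quoted elsewhere as
"about ±15%"); the package reports the exact value and the matching
multiplicative content band (0.850, 1.214). The bound is smallest at an
assumed AT of 0.5 and grows monotonically toward either extreme, but it
is *not* symmetric in |assumed_at − 0.5| for asymmetric responses.

## Synthetic micrographs

The generator paints each compartment (nucleus: ellipse; organelle:
compact disk or six dispersed blobs; optional host nucleus: ellipse) with
uniform DNA density — the simplest model consistent with
integrated-intensity densitometry — and forms each channel as
`background + gain · Σ f_dye(AT_c)·density_c`, convolved with an
isotropic Gaussian (σ = 1 px by default); out-of-focus haze is modelled
only through this kernel. Noise is Poisson on signal + background,
then additive Gaussian read noise (sd 2), then rounding and clipping to
the detector bit depth (16 by default, clipped pixels counted).
Relative DAPI/RedDot1 exposure gain is a free parameter, default 1:1
(real exposure scaling between channels is instrument-specific).

Default photon budget is 20 000 counts per Mbp spread over the
compartment footprint on a background of 100 counts — a few hundred to
a few thousand counts per signal pixel, i.e. a bright but realistic
widefield exposure. Per-cell DNA amounts are jittered lognormally with
CV 0.05 (replication-state variation); geometry is fixed per preset.

Species-like presets encode the study conditions: nuclear Mbp and true
organellar proportion (77.9/0.0509 trypanosome-like; 51.6/0.491
bodonid-like; 180/0.587 diplonemid-like with a GC-richer organelle;
19.0/0.928 endosymbiont-like with an optional adjacent host nucleus).
AT fractions (nucleus 0.45–0.55; organelle 0.72–0.78, or 0.42 for the
GC-rich case) are chosen as realistic for these genomes.

What the generator does **not** emulate: 3-D defocus structure, chromatic
shift, spectral bleed-through, photobleaching, cell crowding, and
non-uniform chromatin texture. Passing tests therefore demonstrate
correctness of the estimators under the linear mixing model, not
robustness to every real-microscope artefact.

## Unmixing

Class signatures are the median background-subtracted (DAPI, RedDot1)
vectors over user-marked reference regions (median for robustness to
bright speckles), normalised to unit column sum. The per-pixel 2×2
system is solved exactly; negative components are clipped to zero and
the clipped fraction reported (true NNLS is available as a verification
solver and can only lower the residual). A condition number above 30
triggers a "poorly separable" warning — the regime where nuclear and
organellar DNA have similar composition and deconvolution degrades.
Note that on shot-noise-limited images the clipped fraction is dominated
by empty background pixels whose noise straddles zero after background
subtraction, so the >5% clipping warning fires on essentially every
noisy field; it is informative mainly for noise-free or
background-masked data.

Background defaults to the per-channel 5th percentile of the raster (a
rough floor, exact only for clean images); when a background mask is
available the per-channel median over it is used instead — under Poisson
noise the median is an unbiased background estimate where a low
percentile is not.

## Quantitation

Compartment masks come either from manual label rasters (which always
take precedence, and are the only way to exclude a host nucleus,
label 3) or from automatic segmentation of the unmixed rasters
(Gaussian σ = 1 px → Otsu → components ≥ 10 px; overlaps resolved by
larger smoothed density). Before integration, labels are expanded by
4 px into background (nearest label wins), because a σ = 1 px blur
pushes an appreciable fraction of a small organelle's flux just outside
its geometric footprint; the expansion emulates the generous manual
area selections of practice. Integrated RedDot1 signal is the
background-subtracted sum over the mask with per-pixel negatives clipped
at zero.

Per cell, `p = org/(org + nuc)`; host-nucleus signal enters neither
term. Pooling across cells reports the mean and the across-cell
standard error `sd/√n` ("standard error of proportion"; a binomial SE is
not meaningful for intensity data). A single-cell pool reports se = 0
with a warning.

**AT correction (package extension).** The raw RedDot1 proportion
estimates the *signal* fraction, which differs from the DNA fraction by
the dyes' residual composition sensitivity whenever the two compartments
differ in AT (for the trypanosome-like preset: 0.0546 vs 0.0509, a +7%
relative bias — the systematic the error bound above quantifies). Since
the pipeline calibrates both dyes anyway, `quantify_field` can invert
the per-compartment DAPI:RedDot1 ratio through the affine responses to
an apparent AT fraction and divide each compartment's RedDot1 signal by
`f_red(AT̂)`, turning signal proportions into DNA proportions. This
assumes equal channel exposure gain and is enabled by default in the
end-to-end pipeline; the uncorrected estimator remains available and is
what the raw integrated-intensity operations return.

## Content inference

`organellar_content`, `content_se` and the AT-bias band combine into a
`ContentEstimate`; the bundled genome table carries the diploid nuclear
sizes used (the endosymbiont entry treats both nuclei in the host cell
as diploid; its haploid-nucleus variant, 9.5 Mbp, is noted alongside).
Auxiliary arithmetic: kDNA network size from minicircle/maxicircle
composition `(n_mini·L_mini + n_maxi·L_maxi)/1000` Mbp; an
electron-microscopy cross-check ratio `(d_a/d_b)³` with first-order SEM
propagation (content scales with volume under similar shape and packing
density); and the fixed conversion 0.001 pg = 1 Mbp.

## Numerical choices and problem sizes

- Calibration fit: `numpy.polyfit` (ordinary least squares); rescaling
  by `f(1)` after the fit.
- Unmixing: exact 2×2 solve; singular matrices (|det| < 1e−12 or
  non-finite condition number) rejected.
- Reports are written as sorted key-value YAML and seeded runs are
  byte-identical, so every report is reproducible from the logged
  config alone.
- Test-time simulations use 128×128 px fields, 20 cells per preset and
  100-seed calibration ensembles — sizes at which Monte-Carlo checks
  resolve the relevant biases while the whole suite runs in seconds.

## Known limitations

- The AT correction assumes equal channel gain; with unknown relative
  exposure it recovers only relative, not absolute, AT fractions and the
  correction degrades accordingly.
- Automatic segmentation cannot separate a host nucleus from the cell's
  own nucleus (both segment as the nuclear class); manual labels are
  required for that case.
- Blur is the only haze model; scattered light from a large adjacent
  structure (the endosymbiont's kDNA next to its nucleus) is represented
  only as far as a Gaussian kernel can express it.
- Published per-species pooled SEs cannot be reproduced because the
  underlying cell counts are unknown; the estimator's behaviour is
  instead validated on synthetic data.
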