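# kdnaquant

Densitometric quantitation of organellar DNA content — the mitochondrial
(kinetoplast) DNA of kinetoplastid and diplonemid protists — from
two-channel widefield fluorescence micrographs.

Some of these organisms carry more DNA in their single mitochondrion
than in their nucleus, yet no sequencing assay measures total organellar
DNA mass per cell. `kdnaquant` implements the dual-dye densitometric
route for microscopists and protistologists who want absolute numbers
with stated uncertainties:

1. **Calibration.** DAPI (AT-preferring minor-groove binder) and RedDot1
   (nearly composition-insensitive intercalator) are calibrated against
   double-stranded oligos of known AT fraction; each dye gets an affine
   response `f(AT) = intercept + slope·AT`, normalised so `f(1) = 1`.
2. **Colour deconvolution.** Each pixel's background-subtracted
   (DAPI, RedDot1) vector is unmixed into organellar and nuclear DNA
   components via a 2×2 signature matrix estimated from reference
   regions.
3. **Proportion estimation.** Integrated RedDot1 intensity over the
   compartment masks gives the per-cell organellar fraction
   `p = S_org / (S_org + S_nuc)`, pooled across cells as mean ± SE.
4. **Content inference.** With the diploid nuclear genome size *N* (Mbp)
   known independently,

   ```
   M_org = N · p / (1 − p),    se(M_org) = N · se(p) / (1 − p)²,
   ```

   plus a multiplicative worst-case band for residual composition
   sensitivity of the quantitation dye
   (`max_AT |f(AT)/f(0.5) − 1| = 17.6%` for RedDot1).

A synthetic-micrograph module renders cells with known DNA amounts, AT
fractions, blur, shot/read noise and ground-truth labels, so every stage
is testable without external data. See `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
import numpy as np
from kdnaquant import (
    DAPI_TRUTH, REDDOT1_TRUTH, OpticsSpec, make_species_cell, render_field,
    simulate_calibration, fit_response, max_relative_error,
    quantify_field, pool_proportions, infer_content,
)

# 1. calibrate both dyes from a 21-oligo series (2% measurement noise)
records = simulate_calibration([DAPI_TRUTH, REDDOT1_TRUTH],
                               list(np.linspace(0, 1, 21)), noise_sd=0.02, seed=1)
dapi = fit_response(records, "DAPI")
reddot = fit_response(records, "RedDot1")
print(f"RedDot1 response: f(AT) = {reddot.intercept:.3f} + {reddot.slope:.3f}*AT")
print(f"worst-case composition error: {max_relative_error(reddot, 0.5):.1%}")

# 2. image 20 trypanosome-like cells and measure the organellar proportion
rng = np.random.default_rng(1)
optics = OpticsSpec(blur_sigma=1.0, shot_noise=True)
ps = []
for _ in range(20):
    cell = make_species_cell("T_brucei", rng=rng)
    field, truth = render_field([cell], [DAPI_TRUTH, REDDOT1_TRUTH], optics,
                                seed=int(rng.integers(0, 2**31 - 1)))
    ps.append(quantify_field(field, truth.labels,
                             dapi_model=dapi, reddot_model=reddot).p)
pooled = pool_proportions(ps)
print(f"organellar proportion: {pooled.p:.4f} +/- {pooled.se:.4f} (n={pooled.n_cells})")

# 3. convert to absolute kinetoplast DNA content (diploid nucleus: 77.9 Mbp)
est = infer_content(77.9, pooled, reddot)
print(f"kinetoplast DNA: {est.organelle_mbp:.2f} +/- {est.se_mbp:.2f} Mbp "
      f"(x{est.bias_low:.2f}..x{est.bias_high:.2f} composition band)")
```

Output:

```
RedDot1 response: f(AT) = 0.707 + 0.293*AT
worst-case composition error: 17.1%
organellar proportion: 0.0506 +/- 0.0007 (n=20)
kinetoplast DNA: 4.15 +/- 0.06 Mbp (x0.85..x1.21 composition band)
```

The simulated cells carried a true organellar fraction of 0.0509
(4.18 Mbp of kinetoplast DNA next to a 77.9 Mbp diploid nucleus); the
pipeline recovers both within its standard error. The composition band
says that if the quantified DNA were at an extreme base composition, the
true amount could differ by up to the stated factors — a systematic
bound, separate from the statistical SE.

The same stages are available from the shell via the `kdnaquant` CLI
(`simulate`, `calibrate`, `unmix`, `quantify`, `infer`, and `run` for
the whole pipeline from a YAML config); `kdnaquant --help` lists the
flags.

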