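# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fociquant`. Units are pixels for geometry and detector
counts for intensities unless stated otherwise.

## Quality gating

Cells arrive as per-object multi-page TIFF stacks (pages cycle through the
channels cell by cell). Four brightfield features decide inclusion:

| feature | definition | default threshold |
|---|---|---|
| area | pixel count of the object mask | > 175 |
| mean pixel | mean(mask) − median(2-px border ring) | > −20 |
| gradient RMS | RMS Sobel magnitude inside the mask | > 50 |
| aspect ratio | minor/major axis of the mask's second-moment ellipse | ≥ 0.85 |

The object mask is the largest connected component of an Otsu threshold
applied to |image − median(image)| — the absolute-deviation transform
handles brightfield cells that are darker *or* brighter than background.
The defaults are the vendor-software values for 60× ImageStream data and
are unit-dependent: data from any other instrument needs recalibrated
thresholds (they are plain constructor arguments). Area, mean pixel and
gradient RMS gate strictly (`>`); aspect ratio is inclusive (`≥`).

Size standardization brings all stacks to the per-axis 99th percentile of
input sizes: larger images are center-cropped, smaller ones padded with
Gaussian noise whose mean/SD are estimated from the image's own 2-px
border (clipped at zero) — the recipe for "padding that matches the
background and noise level" is this package's choice. The operation is
idempotent. Network crops are 64×64 around the γH2AX intensity center of
mass (clamped at borders) and min-max normalized to [0, 1]; a constant
crop maps to zeros.

## Simulated foci and the training set

A focus is an isotropic 2D Gaussian
F(x, y) = A/(2πσ²)·exp(−((x−x₀)² + (y−y₀)²)/2σ²) with σ uniform in
[0.75, 2.25] px and integrated amplitude A = 3σ³ — the width–amplitude
coupling keeps the peak SNR of wide and narrow spots in a comparable,
learnable regime. Per augmented image the spot count is uniform on
{0, …, 10}; centers are uniform inside the central cell region, ≥ 3 px
from the crop edge (truncated truth spots would poison the supervision).

The synthetic base cell emulates an untreated cell: the γH2AX channel is a
raised-cosine radial profile (peak `background_level`, zero outside
`cell_radius`) plus additive Gaussian read noise clipped at zero; the
brightfield channel is a textured bright disk that passes the default
gate. Defaults — 80×80 frame, radius 22 px, background 200 counts, noise
SD 6 counts (3% of peak) — were chosen once as a plausible 60×
hematopoietic cell and define the study conditions for every test in this
repository. Poisson noise is available but off by default; no noise model
is prescribed upstream.

Training pairs: each of 200 base cells is cropped, normalized, and
augmented 8 times (1,600 pairs). Spots are injected on the normalized
scale (A = 3σ³ directly); the input is re-scaled by its new maximum back
into [0, 1]. The target heatmap contains one Gaussian per true spot with
the spot's own σ but **unit peak height**: the network's job is detection,
not photometry — amplitudes are re-measured later on the original image.
Evaluation fixtures are generated on the counts scale
(`amplitude_scale = background_level`, so A ∈ [253, 6834] counts) at the
network size (64×64), which makes truth coordinates coincide with crop
coordinates and makes the 100-integrated-count intensity threshold
meaningful. The whole data stream is a pure function of its seed.

What the generator does *not* emulate: chromatin texture, pan-nuclear
staining at extreme damage, optical aberrations, spectral bleed-through,
or spatial clustering of break sites. Passing tests therefore demonstrate
that the algorithmic chain recovers what it assumes — Gaussian puncta on a
smooth noisy background — not that it is calibrated for any particular
instrument.

## The U-net

Encoder–decoder with six 3×3 convolutions: three encoder stages (the
second and third stride-2), a mirrored decoder with nearest-neighbor
upsampling and skip connections concatenating same-size encoder features,
batch normalization + PReLU after each of the first five convolutions, and
a linear output convolution. Channel widths default to (4, 8, 16) — the
training task saturates at this size (width 6 reaches the same training
loss) and the compact net trains on one CPU core in minutes. Everything is
implemented in numpy with numba direct-convolution kernels (channels-first
layout, stride-1 kernels specialized so the inner loops vectorize);
training is deterministic given the seed.

Loss is mean squared error against the target heatmaps, optimized with
Adam. Two schedules are used:

* **reference**: 250 epochs, lr 1e-5, betas (0.99, 0.999) — the
  long-horizon configuration, the estimator's defaults;
* **short (CPU) profile** (`SCALED_DOWN_PROFILE`): 30 epochs, lr 3e-3,
  β₁ 0.9, batch 24. The reference learning rate is tied to its long
  schedule (1,500 Adam steps at 1e-5 move parameters by ~10⁻², too little
  to converge); the short profile was selected on synthetic validation
  data and is used by the test suite and the acceptance script.

Inference clips negative outputs at zero (the raw map is retrievable).
At these settings the trained net's heatmap MSE is ~10× below the
predict-zero baseline and ~300× below an untrained net.

## Focus calling

Per cell, with the heatmap H and the original counts image I:

1. **Smoothing.** H is blurred with a σ = 0.5 px Gaussian. The short
   -schedule net's bumps are slightly lumpy at the pixel level; without
   smoothing, single emitters occasionally split into two local maxima or
   fail the R² gate. The blur widens fitted σ by at most
   √(σ² + 0.25) − σ ≈ 0.04–0.15 px. Set `heatmap_smoothing_sigma=0` to
   disable.
2. **Candidates.** Pixels strictly above the 85th percentile of H, reduced
   to local maxima ≥ 2 px apart (plateaus collapse to one candidate). A
   constant heatmap yields none. Local maxima, rather than one candidate
   per connected region, are required so that two spots ≥ 6 px apart
   sharing one supra-percentile region are still resolved.
3. **Localization.** For each candidate, a 2D Gaussian plus constant
   offset is least-squares fitted (analytic Jacobian, σ bounded to
   [0.3, 6]) over a 9×9 patch of H (patch shifted inward at borders;
   such foci carry `border=True`). R² = 1 − SS_res/SS_tot on the patch;
   a flat patch returns R² = −∞. Dense fields use greedy
   fit-and-subtract: candidates are fitted brightest-first with each
   fitted emitter removed from a working map, then every candidate is
   re-fitted twice on the residual with only its own light restored —
   without this, a neighbor inside the patch drags R² below threshold for
   ~10% of true spots at 7–10 foci/cell.
4. **Photometry.** The integrated amplitude A is re-fitted on I by linear
   least squares at the frozen (x₀, y₀, σ) — the heatmap is
   amplitude-distorted by design, so brightness must come from the
   original image. Neighbor light inside the photometric patch is *not*
   subtracted; in dense cells focus intensities are accordingly
   upper-biased by a few percent.
5. **Filters.**
   * σ plausibility: fitted σ must lie in [0.4, 3.0] px. A focus is a
     diffraction-limited spot; fitted widths far above the simulated
     σ-range mark smooth background structure (measured: spurious
     candidates fit at σ ≥ 3.6, true foci ≤ 2.3).
   * R² ≥ 0.85 — discard.
   * confidence ≥ 100 — discard. The upstream description of the
     confidence score is not recoverable, so the package **declares** its
     own: `confidence = max(A, 0) · max(R², 0) / (residual RMS + 1e-9)`,
     with the residual RMS taken from the localization fit. It is
     monotone in amplitude and in fit quality, zero for non-positive
     amplitude, and a clean A = 100 spot at the simulated SNR scores
     orders of magnitude above the threshold. Both the formula and the
     threshold are configurable.
   * intensity: A < 100 integrated counts → the focus is **kept but not
     counted** (`counted=False`); it still enters the focus-intensity sum,
     where dim spurious spots are intrinsically deweighted.
6. **Deduplication.** Candidates whose fitted centers coincide within 2 px
   collapse to the highest-confidence one. This happens *before*
   thresholding, so raising any of the R²/confidence/intensity thresholds
   can never increase the counted number (the monotonicity property the
   test suite asserts). Two true spots closer than 2 px merge into one
   called focus — the documented resolution floor; called counts never
   exceed truth for well-separated spots.

Per-cell metrics: `n_foci` = counted foci; `focus_intensity` = Σ max(A, 0)
over all retained foci; `cell_intensity` = Σ I (the flow-cytometry
equivalent measurement). Sample summaries report mean ± SEM (sample SD /
√n; a single-cell sample reports SEM 0 with a warning) and the fraction of
cells with ≥ k foci (default k = 5). The repeatability statistic
`relative_error` is the coefficient of variation SD/mean.

### Performance of the full chain

With truth heatmaps substituted for the network, counts 0–10 and spots
≥ 6 px apart, recovery is exact over hundreds of cells. With the
short-profile trained network and *unconstrained* spot placement, the
held-out count MAE is ≈ 0.85–0.96 and untreated cells average ≤ 0.2 false
foci; the oracle-heatmap MAE under the same unconstrained placement is
≈ 0.8, i.e. most of the residual error is physical overlap of spots below
the resolution floor, not detector failure. (All figures recomputed by
`tests/test_acceptance.py` and `scripts/acceptance.py` at run time.)

## Expected cut sites per cell

For a guide RNA with per-site editing efficiencies p₁…p_n (fractions,
panel rows below the 0.05% reporting cutoff dropped at load time), the
cut count per cell is modeled as a sum of independent Bernoulli(pᵢ) —
a Poisson-binomial distribution. The exact pmf is computed by dynamic
programming (convolving with [1−pᵢ, pᵢ] site by site, O(n²)); the mean
equals Σpᵢ identically. `simulate_cells` is the Monte-Carlo twin
(independent per-cell draws, chunked to bound memory). Independence
across sites and cells is an assumption, not a measurement: linked loci
on one allele or cell-to-cell delivery differences would correlate
events.

The bundled reference panels (`fociquant.panels`) are **synthetic
stand-ins**: only each guide's published summary figures (on-target
efficiency, site count, summed activity — e.g. RAG2: 94.8%, 50 sites,
149.6%) are public here, so off-target tails are reconstructed as a
geometric decay above the cutoff that reproduces those sums exactly. The
mean cuts/cell depends only on the summed activity and is therefore
exact for the stand-ins; pmf shapes beyond the mean are illustrative.

## Numerical and degenerate-input conventions

* Coordinates are 0-based (row, col) = (y, x) with pixel centers at
  integers; sub-pixel positions are real-valued.
* Min-max normalization of a constant image returns zeros; gating of an
  empty object mask returns all-zero features (rejected on area).
* The Gaussian-fit sentinel for singular/flat patches is R² = −∞; such
  candidates are unconditionally rejected.
* Training aborts with a diagnostic on non-finite loss.
* Pipeline runs write a manifest (config hash, seeds, versions); a rerun
  from the same manifest is bit-identical.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the study at: 200 base cells ×
8 augmentations (1,600 pairs), one 30-epoch short-profile training, 200
held-out mixed cells plus 50 untreated cells for detection transfer, 200
cells for oracle count recovery, 50 patches for the grid-search fit
oracle, 2²⁰-outcome enumeration for the Poisson-binomial check, and
100,000 simulated cells for the Monte-Carlo mean. These sizes are the
package's own choices for a single-CPU run of the full study.

## Known limitations

* Gating thresholds are vendor-unit-bound; no automatic unit conversion.
* The confidence formula is a declared stand-in (see above), not a
  reproduction of the upstream score.
* Foci closer than ~2 px are fundamentally merged; counts in cells with
  many foci are lower bounds (the paper-equivalent regime where cell
  intensity takes over).
* Photometry ignores neighbor light inside the 9×9 patch.
* The U-net is intentionally compact; for GPU-scale retraining on real
  data, widths and schedule are constructor arguments, but no GPU path is
  provided.
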