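# fociquant

Quantification of the DNA-damage response (DDR) in single cells from
imaging flow cytometry, aimed at screening genome-editing reagents
(CRISPR-Cas9 guide RNAs, rAAV6 donor doses) for genotoxicity.

After a double-strand break, phosphorylated histone H2AX (γH2AX) spreads
over the surrounding chromatin and, immunolabeled, appears as a
diffraction-limited punctum — a *focus*. An imaging flow cytometer
photographs thousands of cells per minute; counting the γH2AX foci in each
cell image measures how much damage a treatment caused. `fociquant`
implements that measurement end to end:

1. **Gating** — cells are read from multi-page TIFF stacks and kept only if
   four brightfield features pass quality thresholds (area > 175,
   background-subtracted mean pixel > −20, gradient RMS > 50, aspect ratio
   ≥ 0.85 in the vendor's units; all configurable), removing debris,
   doublets and defocused objects.
2. **Background suppression** — a six-convolutional-layer U-net (batch
   normalization + PReLU after each of the first five layers, skip
   connections between same-size stages) maps the normalized 64×64 γH2AX
   crop to a heatmap in which each focus is a near-unit-height Gaussian
   and cellular background is suppressed. Because no ground truth exists
   for real cells, the net is trained on zero-focus cell images augmented
   with simulated foci

       F(x, y) = A/(2πσ²) · exp(−((x−x₀)² + (y−y₀)²) / 2σ²),
       σ ~ U[0.75, 2.25] px,  A = 3σ³,  counts per cell ~ U{0..10},

   200 base images × 8 augmentations = 1,600 labeled pairs.
3. **Focus calling** — heatmap pixels above the 85th percentile yield
   candidate peaks; a 2D Gaussian plus offset is fitted over a 9×9 patch
   (sub-pixel x₀, y₀, σ, R²); the integrated amplitude A is then re-fitted
   on the *original* image at the frozen geometry. Candidates are filtered
   by fit quality (R² ≥ 0.85), a confidence score (≥ 100) and integrated
   intensity (≥ 100 counts); foci failing only the intensity filter still
   contribute to the focus-intensity metric, where dim spurious spots are
   intrinsically deweighted.
4. **Per-cell metrics** — the number of counted foci, the focus intensity
   (sum of fitted amplitudes over all retained foci) and the cell
   intensity (total γH2AX signal, the flow-cytometry equivalent), plus
   per-sample means ± SEM and the fraction of cells with ≥ 5 foci.
5. **Cut-site simulation** — given a per-site editing-efficiency panel for
   a guide RNA (on-target + off-targets, e.g. from multiplex amplicon
   sequencing), the number of cut sites per cell is Poisson-binomial;
   both the exact distribution (dynamic programming) and a per-cell
   Monte-Carlo simulation are provided, linking sequencing-derived editing
   activity to the expected DDR.

The U-net and its training loop are a self-contained numpy/numba
implementation (direct-convolution kernels, Adam, MSE), deterministic for
a fixed seed and fast enough to train the full 1,600-pair set on one CPU
core in a few minutes.

## Worked example

```python
import numpy as np
from fociquant import (SyntheticCellSpec, inject_spots, make_base_cell,
                       call_foci, compute_cell_metrics)
from fociquant.io_gating import GH2AX
from fociquant.synthetic import target_heatmap
from fociquant.cutsim import exact_distribution
from fociquant.panels import reference_panel

# one treated-like cell with 4 simulated foci
rng = np.random.default_rng(7)
cell = make_base_cell(SyntheticCellSpec(image_size=64, rng_seed=7))
img, truth = inject_spots(cell.channels[GH2AX], n_range=(4, 4), rng=rng,
                          amplitude_scale=200.0)
heatmap = target_heatmap(truth, 64)          # stands in for the network here
foci = call_foci(heatmap, img)
m = compute_cell_metrics(foci, img)
```

prints, via the obvious formatting:

```
foci counted: 4
focus intensity (sum of fitted amplitudes): 4047 counts
cell intensity (total channel signal): 100618 counts
  focus at (23.75, 43.78)  sigma=1.49  A=  1804  R2=1.000
  focus at (53.97, 31.30)  sigma=1.28  A=  1120  R2=1.000
  focus at (30.28, 50.40)  sigma=1.17  A=   726  R2=1.000
  focus at (37.37, 35.80)  sigma=0.87  A=   397  R2=1.000
```

All four injected foci are recovered with sub-pixel localization; their
fitted integrated amplitudes (in detector counts) sum to the cell's focus
intensity, and the cell intensity is the plain channel sum. For the
sequencing side:

```python
d = exact_distribution(reference_panel("VEGFA"))
print(f"mean cuts/cell = {d.mean:.3f}, P(>=1 cut) = {d.pmf[1:].sum():.3f}")
# mean cuts/cell = 1.839, P(>=1 cut) = 0.866
```

— the VEGFA guide's summed editing activity of 183.9% across its 105-site
panel translates into 1.839 expected cuts per cell.

To train a model and run the full pipeline from the shell:

```sh
fociquant simulate --n-cells 200 --pairs-per-base 8 --seed 7 --out train/
fociquant train --data train/ --epochs 30 --lr 3e-3 --seed 7 --out model.npz
fociquant run --config run.yaml     # gate -> predict -> call foci -> metrics
fociquant cutsim --panel panel.csv --cells 100000 --seed 7 --out dist.csv
```

## Scope

Proprietary cytometer formats (.rif/.cif) are out of scope — TIFF stacks
exported via Bio-Formats are the ingestion boundary. The package does not
resolve the high-damage regime where foci merge into pan-nuclear staining
(the cell-intensity metric covers it), and the synthetic cells emulate the
statistical structure the detector assumes, not real chromatin texture
(see `docs/methods.md` for what that implies).
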