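# tvmar

Projection-domain total-variation metal artifact reduction for
parallel-beam CT.

When a CT scan contains metal — security scans of luggage are the
canonical case, where essentially every bag holds unknown metallic
objects — beam hardening depresses the line integrals of exactly those
rays that cross the metal, and filtered backprojection (FBP) turns the
inconsistency into dark undershoots and streaks around the bright
objects. Classical corrections need the material's attenuation
spectrum or replace the corrupted rays by interpolation; `tvmar`
instead *re-estimates* the corrupted sinogram values directly, using
only the image-domain total variation of the reconstruction as the
objective.

## Method

Let $f$ be the FBP reconstruction of sinogram $p_{t,\theta}$ and

$$T(f) = \sum_{i,j}\sqrt{(f_{i,j}-f_{i,j+1})^2 + (f_{i,j}-f_{i+1,j})^2}$$

its TV norm, with smoothed gradient $U_{i,j} = \partial T/\partial
f_{i,j}$ (a small $\varepsilon$ under the square roots keeps it defined
on flat regions). The pipeline is:

1. reconstruct the raw FBP image;
2. segment a binary metal image $f_{\text{metal}}$ by thresholding at a
   fraction (default 1/3) of the image maximum;
3. build the projection-domain metal trace
   $\mathrm{mask}_{\text{metal}}$ — the support of
   $\Re\{f_{\text{metal}}\}$, where $\Re$ is the Radon transform — and
   iterate

   $$p^{\text{new}}_{t,\theta} = p^{\text{old}}_{t,\theta} -
     \lambda\,\mathrm{mask}_{\text{metal}} \cdot
     \Re\{U_{i,j}\,(1-f_{\text{metal}})\}$$

   re-reconstructing $f = \mathrm{FBP}(p)$ each iteration;
4. reconstruct the final image from the restored sinogram.

The factor $(1-f_{\text{metal}})$ hides the metal pixels from the
descent direction so the metal objects survive; the mask confines every
update to the unreliable rays, so all other measurements remain
bit-identical to the input. No spectrum model, no material assumptions,
no interpolation, no training data.

Because a relaxation parameter is only meaningful relative to an
operator normalization, $\lambda$ defaults to 0.001 against this
package's normalized projector pair (line integrals in cm,
FBP ≈ inverse), the calibrated monotone-descent regime of the stock
geometry; it is exposed everywhere.

Since real metal-corrupted scans ship with neither ground truth nor
redistribution rights, the package includes a polychromatic Beer-Lambert
simulator (`tvmar.simulate`) that generates bag-like ellipse phantoms
with known monochromatic ground truth and a five-point X-ray spectrum,
reproducing the key corruption: rays through metal carry depressed
line-integral values while all other rays are essentially accurate.

## Worked example

```python
from tvmar import MARConfig, auto_roi, make_reference_scenario, roi_min, run_mar

sim = make_reference_scenario(seed=20200721)          # 128x128, 90 views
result = run_mar(sim.sino_poly, sim.geometry, MARConfig())

roi = auto_roi(result.metal, sim.geometry.image_size)
print(f"metal pixels segmented : {result.metal.n_pixels}")
print(f"TV norm                : {result.trace.tv_values[0]:.1f} -> {result.trace.tv_values[-1]:.1f}")
print(f"ROI minimum (FBP)      : {roi_min(result.raw_fbp, roi):+.4f}")
print(f"ROI minimum (restored) : {roi_min(result.final_image, roi):+.4f}")
```

prints

```
metal pixels segmented : 252
TV norm                : 763.7 -> 383.1
ROI minimum (FBP)      : -0.3622
ROI minimum (restored) : -0.2270
```

The TV norm of the reconstruction falls monotonically over the 400
iterations as the streaks dissolve. The figure of merit is the minimum
pixel value in a 40×40 region of interest placed on the undershoot next
to the largest metal object: more negative means a more severe
artifact, so the restored image (−0.227) is markedly less corrupted
than the conventional FBP (−0.362). Values are attenuation
coefficients in cm⁻¹ (the soft background reconstructs near +0.21).

The same pipeline is available from the shell:

```bash
tvmar simulate --seed 20200721 --out-dir scenario/
tvmar run --sinogram scenario/sino_poly.tif --iters 400 --out-dir out/
tvmar evaluate --seed 20200721 --out report.csv
tvmar plot-trace out/trace.csv
```

`tvmar run` writes the final and raw reconstructions, the metal and
mask images, the restored sinogram (float32 TIFF + JSON geometry
sidecars), the TV-vs-iteration trace as CSV, and a run manifest.

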