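# Methods

## The restoration model

`tvmar` treats metal artifact reduction as a *measurement restoration*
problem rather than an image reconstruction problem. The model
assumptions are:

* the scan is parallel-beam, with line-integral measurements
  $p_{t,\theta}$ on an evenly sampled $(t,\theta)$ grid;
* most measurements are accurate; a small subset — the rays crossing
  metal — carry nonlinearly depressed values (beam hardening removes
  low-energy photons preferentially, so measured log-attenuation is
  sub-linear in path length);
* the inconsistency of those few rays is what creates streak and
  undershoot artifacts in the FBP image, and those artifacts raise the
  image's total variation.

The objective is therefore the TV norm of the FBP reconstruction, a
pure figure of merit with no data-fidelity term, minimized *over the
corrupted sinogram entries only*. The update direction is the Radon
transform of the image-domain TV gradient, masked twice: by
$(1-f_{\text{metal}})$ in the image domain (so the descent cannot
dissolve the metal objects themselves) and by the metal-trace mask in
the projection domain (so reliable measurements are never touched). The
final image is a single conventional FBP of the restored sinogram — the
method is not an iterative reconstruction algorithm and assumes no
knowledge of the spectrum or the materials.

This regime has limits, which the implementation inherits: the method
helps when few measurements are severely damaged and the rest are good;
it is not a denoiser and will not help when error is spread across all
measurements.

## Operators and normalization

`radon_forward` and `fbp` wrap `skimage.transform.radon`/`iradon`
(linear-interpolation rotate-and-sum projector, ramp-filtered
backprojection with the standard $\pi/(2\,n_{\text{views}})$ factor)
behind geometry-aware types. Conventions, frozen because the iteration
composes the two operators on one grid:

* row index down, column index right; angles from the image x-axis,
  evenly spaced on $[0^\circ, 180^\circ)$; $t = 0$ at the detector
  center (pixel index $N/2$);
* reconstruction restricted to the inscribed circle, outside set to 0;
  `radon_forward` zeroes the image outside the circle before
  projecting, so the operator is well defined on arbitrary grids;
* `radon_forward` multiplies the discrete sums by `pixel_spacing`, so
  sinograms are physical line integrals (attenuation × cm) and
  `fbp(radon_forward(f)) ≈ f` in attenuation units (measured round-trip
  relative RMSE on a smooth 128×128 phantom: 7×10⁻⁴; recorded test
  tolerance 2×10⁻³);
* the geometry supports two detector extents: `fov="circle"`
  (n_channels = N, the default) and `fov="diagonal"` (the projector's
  padded diagonal, e.g. 594 channels for a 420×420 grid);
* `backproject` is the unfiltered backprojection; it equals the true
  adjoint of `radon_forward` up to the single constant
  $2\,n_{\text{views}}/\pi$ (verified to ~1% on smooth fields). The
  image-domain baseline uses it directly as the fidelity descent
  direction — a fixed positive rescaling of the gradient, which is far
  better conditioned than the raw adjoint (the composition
  backproject∘radon has spectral radius ~N instead of
  ~N·n_views).

## TV norm and gradient

The TV norm sums $\sqrt{\Delta_x^2 + \Delta_y^2}$ over forward
differences with replicate-edge (Neumann) boundaries: differences past
the last row/column are zero. The gradient collects, per pixel, the
three terms in which that pixel appears, each denominator stabilized by
$\varepsilon = 10^{-8}$ under the square root. With this boundary
convention the smoothed gradient is the *exact* derivative of the
smoothed norm — verified against central finite differences to below
10⁻⁴ — which matters because the projection-domain iteration relies on
the gradient's sign structure near flat regions. The reported
`tv_norm` uses the exact (unsmoothed) sum; the smoothed variant exists
for gradient checking.

## Choice of the relaxation parameter

A step size for the update $p \leftarrow p - \lambda\,\Re\{U\}$ has no
absolute meaning: rescaling the projector pair by $c$ and its inverse
by $1/c$ leaves every reconstruction unchanged but rescales the update
by $c$ — equivalently, the choice of length unit changes the effective
step. Published values for this class of iteration therefore do not
transfer across discretizations.

The package calibrates its default against the observable dynamics the
method is meant to have: a smoothly, monotonically decreasing TV-vs-
iteration curve over hundreds of iterations. At the stock geometry
(128×128, 90 views, cm units) that regime is $\lambda = 0.001$ —
measured 100% non-increasing steps over 400 iterations across all
tested seeds, with the curve still descending at iteration 400. A 10×
larger step makes the trace oscillate with period 2 from the first
iteration and settle at a *higher* TV floor, the classic signature of
overshoot in fixed-step descent of a nonsmooth objective. $\lambda$ is
exposed in `MARConfig` and the CLI; `mar_iterate` aborts with a
diagnostic `DivergenceError` (carrying the partial trace) if the TV
norm ever exceeds 10× its initial value, and the image-domain baseline
additionally halves its steps after five consecutive objective
increases.

## Metal segmentation

Segmentation thresholds the raw FBP at
$\max(\tfrac{1}{3}\,f_{\max},\; \mu_{\text{floor}})$. The fractional
rule alone can never return "no metal" on a positive image (the maximum
pixel always exceeds a third of itself), so the absolute floor
$\mu_{\text{floor}} = 0.6$ cm⁻¹ decides metal presence: it sits above
every common non-metal material at diagnostic energies (water ≈ 0.2,
aluminum ≈ 0.55 cm⁻¹) and far below metals (iron ≈ 5 cm⁻¹). In scenes
that do contain metal the fractional threshold is the larger of the two
and governs, matching the usual fraction-of-max rule. If segmentation
marks more than half of all pixels, the pipeline aborts ("threshold too
low") rather than smooth the whole image away. Both masks are computed
once from the raw FBP and frozen; there is no per-iteration
re-segmentation.

The metal trace tests the metal projection `> tol` with
`tol = 1e-6 × max` by default, because an interpolating projector never
produces exact zeros at the trace boundary.

## The beam-hardening simulator

`make_reference_scenario` emulates a baggage scan at desk scale: a
large soft ellipse (the bag) with a few internal soft ellipses and 2–3
metal inserts with semi-axes 3–9 px (0.3–0.9 cm at the default 0.1 cm
pixel spacing), all placement seeded. Two materials are shipped, with
invented but qualitatively shaped attenuation tables: water-like
"soft" (nearly flat, 0.27→0.15 cm⁻¹ over 40–140 keV) and "metal"
(steeply decaying, 15→1.3 cm⁻¹, ~50× soft at 40 keV). The source is a
five-point 120 kVp-like spectrum; measurements follow polychromatic
Beer-Lambert,
$p = -\ln \sum_k w_k e^{-\sum_m \mu_m(E_k) L_m}$, evaluated with
log-sum-exp for stability, with per-material path lengths from the
forward projector. Rasterization is pixel-center membership with no
anti-aliasing, so pixel counts are exactly testable. Noise is off by
default (the method addresses bias, not noise); optional Poisson
transmission noise is seeded.

The monochromatic reference energy is 60 keV, the spectrum's effective
energy: there $\mu(E_{\text{ref}})$ is at least the spectrum-weighted
mean attenuation of both materials, so by Jensen's inequality every ray
satisfies $p_{\text{poly}} \le p_{\text{mono}}$ — corruption is a pure
depression, the regime the method assumes. The insert sizes were chosen
so the conventional FBP shows clearly negative undershoot minima next
to the metal (ROI minima of roughly −0.07 to −0.47 cm⁻¹ across seeds
against a +0.2 cm⁻¹ background), i.e. artifacts severe enough to be
worth removing; single tiny inserts produce nearly consistent sinograms
and almost no streaks.

What the simulator does *not* model: scatter, detector blur and
response, tube filtration, fan/cone geometry, content-rich bags
(the bag interior is uniform soft material), or noise by default.
Passing tests therefore demonstrate the algorithm's behavior under
idealized single-cause corruption — they do not certify performance on
real scanner data, where the corruption is confounded with noise,
scatter and geometry effects.

## Evaluation

The figure of merit is the minimum pixel value in a square ROI (40×40
default) placed on the dark undershoot: larger (closer to zero) is
better, and values are never compared across scenes. For determinism
the harness auto-places the ROI centered at the centroid row of the
largest connected metal component, 10 px beyond its right edge, clipped
into the image. `compare_methods` shares one raw FBP across the three
methods and iteration-matches the baseline to the MAR run. Figure
export windows images from the minimum value to 0.3× the maximum.

## Problem sizes

The stock scenario is 128×128 with 90 views (detector = image width,
circle field of view) — large enough for streak artifacts with
realistic structure, small enough that the full 400-iteration pipeline
runs in ~20 s and the complete three-method comparison in under a
minute on one CPU. The unit-test scenario is 64×64 with 60 views.

## Known limitations

* Restoration quality depends on the segmentation: missed metal leaves
  its trace un-masked and uncorrected; over-segmentation shrinks the
  trusted data.
* The TV objective is indifferent to the DC depression of the metal
  trace: it removes the *inconsistency* (streaks), while the absolute
  bias inside the trace is only partially corrected (masked-region RMSE
  improves but does not vanish).
* The calibrated $\lambda$ was set at desk scale; very different
  geometries may need rescaling (the divergence guard catches gross
  mismatches).
* Detector channel counts are tied to the projector: N for the circle
  field of view, the padded diagonal (e.g. 594 for a 420×420 grid) for
  full coverage; scanners that rebin to other channel counts need
  resampling upstream.
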