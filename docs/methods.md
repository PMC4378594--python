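# Methods

`odseg` segments the optic disc (optic nerve head) in color fundus
photographs. The pipeline is classical computer vision throughout — no
learned components — and every stage is exposed as a library function with
its own contract. This note records the model, the numerical choices, the
defaults and why they were chosen, and what the synthetic test fixtures do
and do not establish.

## Pipeline overview

1. **Localization.** The HSI intensity channel I = (R+G+B)/3 is matched
   against a 401×401 bright-disc template by Pearson correlation (the
   template-matching score is invariant to affine intensity changes, so
   only shape matters). The correlation argmax seeds a 900×900 region of
   interest (ROI); Canny edges (Gaussian σ = 5 px, high hysteresis
   threshold 0.4 × the maximum gradient magnitude) feed a circle Hough
   transform over radii 140–230 px in steps of 15, whose global accumulator
   maximum yields the disc center and an estimated radius.
2. **Vessel removal.** Blood vessels cross the disc boundary and would
   imprint false edges on any texture measure. Given a binary vessel mask,
   vessel pixels (mask dilated by 2 px to cover halos) are replaced by the
   solution of the discrete Laplace equation with Dirichlet data from the
   surrounding pixels — harmonic (diffusion) inpainting, applied per color
   channel. Grayscale closing (disc SE, radius 15) and neighborhood-mean
   replacement (window 31) are provided as alternatives.
3. **Texture.** The red channel of the devesseled ROI is filtered with the
   38-kernel Root Filter Set; each oriented family × scale collapses to its
   maximum response magnitude over the 6 orientations, giving the 8
   rotation-invariant MR8 maps. The snake's potential comes from MR8
   response #3 (the odd edge-of-Gaussian family at the largest scale,
   (σ_long, σ_short) = (12, 4)), enhanced by CLAHE (clip 0.01, 8×8 tiles).
4. **Noise suppression.** Inside a disc-centered analysis circle of radius
   (estimate + 50) px, each pixel gets a 3-vector of texture features —
   Schmid #1 (σ=2, τ=1), MR #5 (even bar family, middle scale), MR #7
   (Gaussian) — z-scored over the region and split into two fuzzy-c-means
   clusters. The larger cluster is declared background, opened with a
   radius-5 disc, complemented within the circle, and the largest
   8-connected component of the complement becomes the edge region. The
   CLAHE-enhanced potential is then diffusion-inpainted over the background
   region, which erases the cup-boundary ring and residual vessel edges
   while keeping the potential smooth (a constant fill would create new
   extrema that stop the contour).
5. **Balloon snake.** A closed contour starts as a circle of *half* the
   estimated radius — safely inside the disc — and evolves by

       du/dt = α u_ss − β u_ssss − ρ n_out − ξ ∂P/∂u,

   with P the negated, min-max-normalized clean texture. Tension/stiffness
   are solved semi-implicitly (cyclic pentadiagonal system inverted once),
   pressure and texture force explicitly, with bilinear force interpolation
   and the image-force magnitude capped at 1. The contour is resampled to
   uniform arc length every 10 iterations and stops when the mean
   displacement over a 20-iteration window falls below 0.05 px. The final
   contour is rasterized by the even-odd pixel-center rule.

Starting inside and inflating outward is what makes the method robust to
peripapillary atrophy (PPA): the crescent lies *outside* the disc, so the
balloon meets the disc-boundary texture ridge first and never needs to
cross it, whereas contours initialized near the boundary (classical
gradient snakes) readily latch onto the PPA rim.

## Parameter defaults and rationale

| parameter | default | units | rationale |
|---|---|---|---|
| template side / core / softness | 401 / 320 / 40 | px | disc widths span 260–380 px at this resolution; core at the midpoint; exact template pixel values are irrelevant to Pearson matching beyond shape |
| ROI side | 900 | px | comfortably contains disc + PPA + analysis margin |
| Canny σ / high / low | 5 / 0.4·max / 0.4·high | px, fraction | σ suppresses vessel-scale noise; 0.4 of the strongest edge keeps only firm boundaries |
| Hough radii | 140…230 step 15 | px | spans half the disc-width range with one-step resolution |
| inpaint dilation / tol / max iter | 2 / 1e-8 / 5000 | px, rel. residual | halo coverage; tolerance far below intensity quantization |
| Schmid pairs | (2,1)…(10,3) | σ px, τ cycles | the canonical 12-filter bank |
| RFS scales / support / iso σ | (3,1),(6,2),(12,4) / 49² / 10 | px | the standard published convention for this bank |
| CLAHE clip / tiles | 0.01 / 8×8 | fraction | mild clipping: enhance weak boundary ridges without amplifying flat-region noise |
| FCM m / tol / max iter | 2 / 1e-5 / 100 | — | textbook fuzzifier; objective change threshold |
| analysis margin | 50 | px | guarantees the true boundary lies inside the clustered region |
| opening SE | 5 | px | smaller than the boundary-ring thickness, larger than speckle |
| snake α, β, ρ, ξ | 0.02, 0.01, 0.1, 5.0 | — | chosen on synthetic fixtures: ρ must exceed the tension pull-back on a disc-sized circle (≈ α·R·(2π/n)² ≈ 0.02) yet stay below the weakest usable boundary force ξ·|∇P| (ridge gradients run 0.03–0.07 after enhancement, so ξ = 5 gives a wide trapping margin) |
| snake dt / n / resample / stop | 1.5 / 120 / 10 / 0.05 px over 20 it | — | semi-implicit internal solve is unconditionally stable; dt sets the inflation speed (ρ·dt ≈ 0.15 px/it crosses the ~90 px inflation distance in ≈ 600 iterations, within the 2000 cap) |

All of these are exposed through `PipelineConfig` (TOML-loadable); the
effective configuration is serialized next to every CLI output.

## Numerical choices

- **Pearson matching** runs coarse-to-fine: 4× block-mean downsampling for
  the global search, exact correlation at full resolution in a 64 px
  refinement window. Constant windows (0/0 correlation) score 0 so flat
  regions never win.
- **Hough accumulation** is a convolution of the edge map with a
  midpoint-circle perimeter stamp (computed via FFT and rounded back to
  integer votes), one accumulator per radius, each smoothed with a 3×3 box
  mean before the argmax; ties break toward the smallest radius, then
  row-major order.
- **Harmonic inpainting** solves the 5-point Laplace system over the masked
  pixels by conjugate gradients (Jacobi-scaled, x0 = mean of known
  pixels) to a 1e-8 relative residual. The converged solution satisfies
  the discrete maximum principle; tests allow a 1e-5 slack for the finite
  residual. An iterative relaxation sweep would reach the same fixed point
  but needs O(R²) sweeps over disc-sized regions, which is why the linear
  solver is used.
- **MR8 orientation collapse** takes the maximum of the response
  *magnitude* for the two oriented families: the odd (edge) kernels flip
  sign under a 180° orientation shift, so a signed maximum would not be
  invariant under quarter-turn image rotations. With magnitudes, MR8
  responses are exactly invariant under 90°/180° rotations (the orientation
  set is closed under them), which the property suite checks to 1e-6.
- **Filter responses** share one padded image FFT per bank; boundary
  handling is symmetric (edge-reflecting) padding; true convolution
  semantics (all bank kernels are symmetric or antisymmetric, so this
  coincides with correlation up to sign conventions tested explicitly).
- **FCM** uses seeded random membership initialization; on the well-
  separated texture clusters the optimum is insensitive to the seed, and
  the seed is part of the pipeline config so runs are bit-reproducible.
- **Degenerate inputs**: empty inpainting masks are identities; an
  all-background clustering raises a dedicated error that the pipeline
  catches, logging a fallback to the unsuppressed texture; an empty Canny
  edge map aborts localization with a diagnostic; self-intersecting
  contours are rejected at rasterization with the offending segment pair.

## Synthetic fixtures

Real fundus datasets with expert disc masks are not redistributable, so
the test bed is a seeded generator of fundus-like scenes: a vertically
slightly oval bright disc (width uniform in [264, 376] px, elongation
2–7%), a brighter interior cup (ratio 0.35–0.55), a linear illumination
tilt plus a low-frequency random field plus i.i.d. Gaussian noise
(σ = 0.012), branching random-walk vessels (width 6–12 px) darkening
whatever they cover, and optionally a PPA crescent of intermediate
brightness spanning ±80° on the temporal side. Edges are error-function
ramps (half-width 5 px) so boundaries are fuzzy rather than ideal steps.
Every sample is bit-reproducible from its spec, and ground-truth masks for
disc, cup, vessels and PPA come for free.

The elongation cap deserves a word: a fixed-radius circle Hough quantized
at 15 px steps estimates "the" disc radius meaningfully only while the
ellipse's osculating radii (b²/a and a²/b) stay within about one step of
the mean semi-axis, i.e. for mildly oval discs — which is exactly the
regime the method is designed for. More elongated discs would need an
elliptical voting scheme.

What the fixtures do **not** emulate: exudates and hemorrhages, reflectance
artifacts, the choroidal texture of real retina, camera vignetting, or
inter-subject variability of PPA shape. Passing the synthetic benchmark
therefore shows the pipeline's stages compose correctly and that the
balloon-from-inside strategy avoids PPA of the modeled kind; it does not
certify clinical accuracy on photographs.

## Known limitations

- Localization assumes the disc is the dominant bright circular structure;
  large exudates can hijack the template match (a failure mode the method
  inherits by design).
- Vessel removal consumes an external vessel mask; without one the texture
  stage sees vessel edges and accuracy degrades (the pipeline still runs,
  flagged `vessel_removal_skipped`).
- The FCM noise-suppression step assumes the background cluster is larger
  than the edge cluster and that the boundary ring forms the largest
  connected edge component; heavily fragmented boundaries would fall back
  to the unsuppressed potential.
- The gradient-snake and FCM+ellipse baselines are faithful comparators,
  not tuned competitors: the ellipse baseline in particular fits the
  boundary-texture annulus's radial midline, which presumes a roughly
  elliptical disc.
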