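# Methods

This note documents the models, numerical choices and limitations behind
`sptread`. Units are millimetres throughout; grids are row-major with the
origin at the top-left corner, x along columns and y along rows.

## Input model

The input is a camera-aligned topography of the volar forearm: a regular
grid of elevations with square pixel pitch (default phantoms use 0.2 mm,
matching a megapixel camera imaging a ~150 × 250 mm field). Invalid cells
(dropouts) are NaN on disk and carried as a validity mask; before any
pyramid processing they are infilled by normalized convolution (Gaussian
weighting of valid neighbours with escalating width), and the mask is
reapplied to every product.

## Global surface removal

A standard Gaussian–Laplacian pyramid with a 5-tap binomial kernel
g = (1, 4, 6, 4, 1)/16 (the expand kernel is the same taps scaled to sum 2
so that zero-insertion upsampling preserves the mean). Depth n = 7;
Laplacian bands {2, 3, 4, 5} are kept. The halving convention is
ceil-half with per-level shapes recorded, so arbitrary (non power-of-two)
grids round-trip exactly: collapsing with every band reproduces the input
to machine precision, and this perfect-reconstruction property is the
backbone invariant of the module.

Two conditioning steps surround the pyramid inside
`remove_global_surface`; both only touch content the kept band discards:

* **Polynomial detrend (total degree 6).** A Laplacian band of a smoothly
  curved surface is not zero but a near-constant proportional to the local
  curvature times the squared blur width. For an arm-like cylinder
  (R = 40 mm) the kept-band reconstruction would carry smooth offsets of
  order 1 mm and curvature "ridges" that rival the wheals themselves.
  Subtracting a global least-squares polynomial first (fitted on valid
  cells, evaluated on normalized coordinates) leaves a residual flat
  enough that the band output is curvature-free; a degree-6 surface cannot
  follow 3–12 mm bumps of 0.1–0.5 mm amplitude over a 140 × 60 mm field,
  so wheals pass through unaffected. With this step the band-pass residual
  of a pure cylinder phantom is ~0.005 mm RMS.
* **Odd-reflection padding (2^n pixels).** Plain reflective extension of a
  sloped surface creates a crease at the border whose band-pass energy
  dwarfs the wheals; antisymmetric reflection continues the slope
  smoothly. The pad is cropped after collapse.

Within `expand`, the coarse level is border-extended *before* zero
insertion; reflecting the interleaved array would place duplicated samples
next to zeros and break constant preservation at the edges.

The band-selected surface S′ is defined only up to a smooth local offset
(see detrend discussion above); downstream stages treat it accordingly.

## Wheal detection

Scale-normalized LoG: response = −σ²∇²(G_σ ∗ S′), computed at a geometric
ladder of 12 scales from σ = 1.0 to 5.0 mm. Defaults were calibrated on
phantom fields so that the ladder covers the clinical wheal range
(3–12 mm): for the super-Gaussian profile used here (d = 4σ_bump) the
scale-space peak tracks the bump width σ_bump = d/4, so the ladder covers
d ≈ 4–20 mm directly and smaller wheals peak at the ladder floor. The
response threshold is 0.03 mm, about half the band-passed amplitude of the
smallest (0.1 mm) wheals and well above the residual background.

Candidates are strict 3×3×3 maxima of the (σ, y, x) stack; ties are
suppressed so plateaus cannot produce duplicate detections. Maxima on the
coarsest scale plane are excluded: responses of residual large-scale
background grow monotonically with σ and accumulate there, while a genuine
blob inside the ladder peaks at an interior scale. Overlap pruning then
greedily drops the weaker of any pair whose circles of radius σ√2 overlap
by more than 50% of the smaller circle. Centers are integer-pixel; the
subsequent fit re-estimates them continuously. Patches are square windows
of half-width round(2·σ√2/pitch) pixels, clipped (and flagged) at borders.

The mean of the field is removed before filtering and the Gaussian kernel
is truncated at 6σ, which keeps the discrete operator's response to
constant and linear fields at the 1e-8 level.

## Parametric fitting

`center_patch` subtracts the patch median as a local baseline (see above),
converts cells to (x, y, z) points, shifts to the center of mass weighted
by max(z, 0), and takes the principal axis of the weighted second-moment
matrix as the rotation initialization θ₀ (mapped to [−π/2, π/2); the model
rotates coordinates, so θ₀ is the negative of the spatial axis angle).
Patches with no height above the baseline or fewer than 8 usable points
are rejected as degenerate and dropped from the pipeline with a warning.

Both models are fitted with `scipy.optimize.least_squares`
(trust-region-reflective, bounds below, ftol = xtol = gtol = 1e-8,
max 500 iterations; one restart at θ₀ + 45° on failure). Unweighted
residuals.

* **Paraboloid.** Only the products wx²c, wy²c and β are identifiable, so
  the fitter pins c ≡ 1 and absorbs the scale into wx, wy; reported
  diameters d = max{2a, 2b} with a = wx√(βc) are unaffected. Because f₁
  diverges to −∞, residuals are evaluated only on cells above 5% of the
  patch peak plus a one-pixel dilation ring — otherwise the flat
  background dominates the cost and shrinks the ellipse.
* **Super-Gaussian.** All eight parameters (center, σx, σy, βx, βy, γ, θ)
  are fitted on the full patch.

Initialization: γ₀ (or β₀) = patch peak; σ₀ from the weighted moment SDs
along the rotated axes; flatness exponents start at 1; for the paraboloid
w₀ = 2σ₀/√peak puts the initial zero-crossing near twice the moment SD.
Bounds: centers within the patch extent; widths ∈ [0.25, 15] mm; flatness
∈ [0.5, 10]; heights ∈ (0, 2·peak]; θ ∈ [−π/2, π/2]. The axis-swap
degeneracy is resolved after fitting by relabelling so that σx ≥ σy
(θ shifted by 90°, center rotated accordingly), giving a unique canonical
form. If the optimizer fails or the diameter leaves [1, 20] mm, the
detection scale supplies a fallback diameter 2√2·σ (reported with
`converged = False`, `fallback_used = True`).

A measurement is flagged positive at d ≥ 3 mm (configurable). The flag
never filters: sub-visual wheals are reported with their flags, since a
depth-sensitive system legitimately detects wheals a human reader misses.

## Phantoms

The forearm phantom is the package's stand-in for real scans: a cylinder
section (R = 40 mm default) along the grid's long axis spanning a 60 mm
camera-facing strip (wider strips imply surface slopes beyond what fringe
projection can reconstruct), plus super-Gaussian wheals (diameters
3–12 mm, heights 0.1–0.5 mm, flatness 1–2.5, aspect 0.6–1, centers
≥ 15 mm apart and ≥ 10 mm from borders), band-limited micro-texture
(0.02 mm SD, 1 px correlation — pores/follicles at scales the pyramid
discards) and white sensor noise (0.01 mm SD, the depth accuracy of the
imaging class emulated). Everything is a pure function of (config, seed).

Choosing the super-Gaussian as the generating shape makes model-2 fitting
self-consistent and model-1 fitting a genuine model-mismatch test; what
the phantoms do **not** emulate — pseudopods and irregular outlines, hair,
perspective distortion, two-camera seams, skin deformation between poses —
bounds what passing tests say about real scans: they validate the
numerical pipeline, not the biological shape model.

Validation objects: spherical caps (z = √(R²−ρ²) − (R−h) over a base
circle, R = (r² + h²)/2h, default h = 2 mm, apexes snapped to grid nodes)
and a staircase of equal-width bands at 0.1 mm increments. Caps are
measured by an algebraic least-squares sphere fit to cells above 10% of
the local peak, intersected with the base plane (d = 2√(R²−z_c²)) — chosen
over a thresholded-footprint count because it is unbiased under noise.
Steps are measured as region means relative to the base band.

## Accuracy attained on phantoms

Numbers the test suite recomputes (not guarantees about real skin):
cap diameters within 0.003 mm of truth (bound tested: 0.1 mm, the
transversal accuracy of the emulated system class); step heights within
0.0005 mm (bound tested: 0.01 mm); detector recall 1.00 / precision ≥ 0.99
over 200 seeded phantoms (bounds tested: 0.95/0.90, 2 mm match radius);
end-to-end diameters within 0.7 mm on a seeded 8-wheal phantom and within
0.3 mm on isolated noiseless wheals — the band-pass distorts wheal shape
slightly, an inherent cost of measuring on S′; per-wheal CV ≤ ~4.5% across
5 rigid re-posings (bound tested: 5.24%).

## Known limitations

* Diameters of large (≥ 9 mm) wheals are biased low by a few percent
  because part of their spatial spectrum falls outside the kept band.
* The paraboloid model forces an elliptical outline; on irregular wheals
  it under-covers protrusions, which is precisely why the super-Gaussian
  is the default model.
* True scattered point clouds are out of scope; gridded PLY only.
* The σ ladder tops out at 5 mm: isolated structures much wider than
  ~20 mm are deliberately not detected.
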