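# Methods

## Problem setting

A microlens-array (MLA) light-field microscope records, in a single
snapshot, both the position and the propagation direction of fluorescence
arriving at the sensor: each lenslet forms a micro-image whose pixels
`(i, j)` sample viewing angle, while the lenslet indices `(k, l)` sample
lateral position. `epilocate` recovers the 3D positions of compact
fluorescent sources (beads, neuronal somata) from one such frame, without
reconstructing a volume. The chain is: calibrate the raw frame, decode it
into the two-plane-parameterized 4D light-field `I4D(i, j, k, l)`,
extract epipolar-plane images (EPIs), and match them against a simulated
depth-aware EPI dictionary by convolutional sparse coding.

The physical facts the method rests on:

* a point source at depth `z` traces a tilted line in an EPI whose slope
  grows with `z` (in-focus sources give a vertical line);
* shifting the source laterally shifts the line along the spatial EPI
  axis without changing its slope — which is exactly what convolution
  against a dictionary of depth-indexed line templates exploits.

## Wave-optics forward model

Samples at the micron scale are semi-transparent, so diffraction cannot
be ignored; the simulator is a scalar wave model rather than ray optics.
For a point source at `p = (p1, p2, p3)` (object space, µm; `p3 = 0` at
the native focal plane, positive deeper):

1. **Objective field.** The wavefront at the native object plane is the
   circular-aperture scalar Debye integral with half-angle
   `α = asin(NA/n)`, sine-condition apodization `sqrt(cos θ)`, and
   defocus phase `exp(i k n p3 (1 − cos θ))` (`k = 2π/λ` in vacuum,
   `n` the medium index). The 4-f relay inverts and stretches it:
   `U_i(x) = U_o(−x/M)`, so the source appears at image coordinate
   `−M (p1, p2)`. The radial profile is evaluated by 200-node
   Gauss–Legendre quadrature and interpolated onto the 2D grid; at low
   NA it reproduces the closed-form Airy pattern to three decimals.
2. **MLA mask.** A phase-only thin-lens mask
   `exp(−iπ‖x_local‖²/(λ f_ML))` tiled with pitch `d` (full square
   cells).
3. **Propagation to the sensor** over the lenslet focal length via the
   paraxial transfer function `exp(−iπλz‖f‖²)`, which has unit modulus
   and therefore conserves energy exactly (Parseval).
4. **Intensity.** The sensor records `|h|²`; extended sources are
   incoherent, so a volume with emitter density `g` produces
   `f(x) = Σ_p |h(x, p)|² g(p)` — exactly linear in `g`.

Fields are simulated on a grid oversampling the sensor by an integer
factor (default 4) and integrated down to sensor pixels, keeping the
lenslet quadratic phase sampled. A spacing coarser than twice the
intensity Nyquist step `λM/(4 NA)` raises an error (the field amplitude
itself aliases there); between 1.05× and 2× it warns.

Because the Debye field is strictly band-limited by the NA, a laterally
shifted source is obtained *exactly* by a Fourier phase ramp applied to
one cached on-axis spectrum per depth. This makes rendering a
discretized ball one FFT triple per grid point and is the only
optimization in the forward path; it changes no physics.

## Calibration

Real frames are rotated by a small angle and the lenslet grid phase is
unknown. All three detectors work on an ordinary out-of-focus frame (no
white image) and are deterministic:

* **Rotation** maximizes the intensity contrast (max − min) of the
  high-pass-filtered column-sum profile over a coarse ±5° sweep at 0.1°,
  then a ±1° fine sweep at 0.01°. The filter is a Butterworth high-pass
  of order 3 (cutoff 0.02 cycles/pixel — removes the DC and envelope,
  passes any plausible lenslet frequency); only the central 70% of the
  rotated frame is summed, since the extrapolated corners of a rotated
  frame otherwise bias the contrast at larger angles. Failure is
  declared when the rotation-corrected column sum shows no distinct
  spectral peak (≥ 5× median magnitude) — a contrast-curve flatness test
  proved unable to separate noise from a true grid.
* **Pitch** is the reciprocal of the dominant non-DC frequency of the
  column-sum signal, Hann-windowed, with parabolic interpolation of the
  spectral peak (~10⁻³ px on clean fixtures).
* **Centres**: binarize (Otsu by default, threshold overridable),
  convolve with a disc kernel of diameter one pitch (or a 3×3 multi-disc
  kernel, the robust default — a darkened lenslet is then still located
  by its eight neighbours), march a window of one pitch from the global
  response maximum snapping to local maxima within ±pitch/4, and finally
  average along each row and column so the centre map is exactly
  rectangular. Two numerical details matter: the response is *flat*
  wherever the kernel fully contains a micro-image disc, so the "largest
  value" is read as the centroid of the ≥ 98 %-of-max region (this also
  resolves ties symmetrically); and the binarized image is mirror-padded
  by the kernel size before convolution, because with the grid half a
  pitch from the frame edge the reflection continues it periodically and
  removes an ~2 px border bias.

## Decoding and EPIs

Decoding cuts the `N_i × N_j` window around each detected centre
(rounded to the nearest pixel — no resampling, preserving photometry)
into `I4D(:, :, k, l)`; windows clipped by the sensor edge are
zero-filled and flagged. Re-tiling the micro-images reproduces the raw
frame exactly, and total intensity is conserved.

EPI conventions (fixed throughout the package, axis 0 angular, axis 1
spatial): horizontal `I4D(:, j0, :, l0)` in `(i, k)`; vertical
`I4D(i0, :, k0, :)` in `(j, l)`. By default the pair of EPIs passing
through the brightest pixel of the central sub-aperture image is
localized, so each EPI contains few epipolar lines.

**Scattering purification.** Sub-aperture images are vectorized into the
columns of a matrix `A`; the leading singular triplet
`B = u σ_max vᵀ` models the diffuse scattering background and `A − B` is
the foreground. A limitation worth stating precisely: the best rank-one
approximation of `background + foreground` absorbs the foreground's
projection onto the background's row and column spaces, *independently
of the amplitude ratio*. A foreground present uniformly in all views
over an all-positive view profile therefore loses a fixed double-digit
percentage of its energy to the subtraction. Quantitative foreground
recovery holds only when foreground and background are nearly orthogonal
(e.g. a source confined to views where the vignetted background is
faint); the localization pipeline, however, is robust to this structured
leak — sparse coding needs the epipolar line's shape, not its exact
photometry — as the end-to-end scattering test shows. Per-row/per-column
max-projection profiles are available as a diagnostic but are not
applied before sparse coding. No denoising is applied by default.

## Depth-aware dictionary

Each atom is the central EPI of a 10 µm diameter ball (the scale of a
neuronal soma) discretized on a uniform lattice and rendered on the
optical axis at one depth of a sweep (default 0–48 µm in 4 µm steps,
13 atoms; the sweep granularity is configurable, and the axial
quantization error is bounded by half the step since depths are reported
as the selected atom's depth without interpolation). Atoms share one
spatial crop — the bounding box of the deepest line plus a 2-sample
margin — and are normalized to unit ℓ₂ norm (standard sparse-coding
practice, so map energies are comparable across atoms). The horizontal
and vertical atoms of an on-axis ball are identical by symmetry, which
the tests assert. The fitted line slope is negative under this package's
axis conventions; all monotonicity statements are about its magnitude.

Object-space transverse sampling: one lenslet corresponds to `d/M`
(5 µm for the default configuration), the super-resolved grid of
deconvolution methods to `d/(M N_i)` (0.26 µm). This package localizes
on the lenslet grid; peak positions are therefore quantized at `d/M`.

## Convolutional sparse coding

The observed EPI `Y` is decomposed against the dictionary by

```
min_z  1/2 ‖Y − Σ_m d_m ∗ z_m‖₂² + β Σ_m ‖z_m‖₁
```

solved by ADMM in the Fourier domain: the quadratic `Z`-step
diagonalizes per frequency bin into a rank-one-plus-identity system
solved by the Sherman–Morrison identity; the `T`-step is the elementwise
soft threshold `S_λ(x) = sign(x)(|x| − λ)₊` with `λ = β/µ`; the dual
update is standard. Initialization is zero everywhere (no randomness);
the returned maps are the exactly-sparse `T` variable. Stopping: 200
iterations or relative primal residual `‖Z − T‖/max(‖Z‖, ‖T‖) < 10⁻⁴`.
Defaults `β = 0.05 · max_m ‖Y ⋆ d_m‖_∞` (scale-free; the cross-
correlation bound is the LASSO null threshold) and `µ = 10β` were fixed
once and used everywhere.

The Fourier route is cross-checked against an independent spatial-domain
solver (FISTA on an explicit circulant convolution matrix, no FFTs):
final objectives agree to ~10⁻⁹ relative on small 1D instances once both
are run to convergence.

Circular convolution wraps; observed EPIs are therefore zero-padded by
the atom size on each border, and source selection is masked to
placements that align the atom's angular extent with the observed rows
and keep the line centre inside the un-padded spatial range.

**Selection, weights, fusion.** Map energies `e_m = ‖z_m‖₂²` are ranked;
the `S` sources are the top energies after suppressing atoms within one
dictionary depth step of an already-selected atom (one physical source
otherwise consumes adjacent-depth atoms). `S` is a user input; an
energy-gap heuristic (largest relative drop in sorted `e_m`) is provided
but off by default. The selected atom indexes the depth lookup table;
the map peak gives the lateral lenslet position, converted to object
space with image inversion (`x = (centre − l) d/M`). Each EPI pair
yields two 3D estimates `p_h, p_v` with reliability weights
`w = ‖Z_Ω‖_F² / ‖Z‖_F²`; sources are matched across the two lists by
nearest depth and fused as the convex combination
`p = (w_h p_h + w_v p_v)/(w_h + w_v)` — the weights are renormalized so
the fusion cannot scale positions.

## Synthetic fixtures: what they emulate and what they do not

`fixtures.make_fixture` renders ground-truthed frames and layers on
acquisition imperfections: global MLA rotation (bilinear), a rank-one
scattering-like background (smooth spatial bump × smooth per-view
vignette — exactly rank one in the sub-aperture matrix, i.e. the model
the purification step assumes), an optional depth-growing Gaussian blur
as a crude scattering surrogate, and seeded Gaussian (fraction-of-peak
or SNR-dB) or Poisson noise. A fixed seed gives byte-identical frames.

Not emulated: multiple anisotropic scattering (the real background is
only approximately rank one), aberrations beyond the modelled optics,
sensor nonlinearity, and vectorial/polarization effects. Passing tests
therefore demonstrate correctness of the algorithmic chain under its own
forward model and robustness to the listed corruptions — not performance
on real tissue.

## Simulation scale and problem sizes

All tests and the acceptance script run a desk-scale preset chosen so
the suite completes in a few minutes of one CPU: 15 × 15 lenslets,
19 × 19 pixels per lenslet (sensor 285²), field oversampling 2×, ball
lattice step 2 µm (81 points per 10 µm ball; `discretize_ball` defaults
to 1 µm for production use), 13 dictionary depths. At this scale the
deepest sources' epipolar lines are truncated by the field of view —
deliberately retained, since the slope fit and the matching must cope
with truncation; the slope estimator uses per-row peak-window centroids
and drops rows whose peak touches the spatial border for exactly this
reason. The recovery experiment uses 20 beads at uniformly random
on-grid depths and lateral positions within ±1.5 lenslets.

## Known limitations

* Depth estimates are quantized to the dictionary grid; lateral
  estimates to the lenslet pitch `d/M`.
* The emission wavelength (0.52 µm) and medium index (1.33) of the
  default configuration are plausible for green fluorescence in aqueous
  media and are configurable.
* Rank-one purification removes the foreground's projection onto the
  background subspace (see above).
* Sources deeper than ~28 µm at the desk scale have truncated epipolar
  lines; localization still succeeds on-axis and near-axis, but beads
  far off-axis at extreme depth lose more of their line to the field
  edge than the dictionary atom does.
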