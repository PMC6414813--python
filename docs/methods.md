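# Methods

This note records the model as implemented, the choices that were genuinely
open, and what the synthetic-data pipeline does and does not establish.

## Cascade architecture

The system maps a luminance image `x⁰` (cd/m², with explicit samples/degree)
through four linear+nonlinear stages to a cortical response vector `x⁴`.

**Layer 1 — brightness.** Pointwise Naka–Rushton compression
`B = L^a / (L^a + b₁^a)` with exponent `a = 0.6` and semisaturation
`b₁ = 40 cd/m²`.  Rejects nonpositive luminance when enabled.

**Layer 2 — local contrast.** `C = (B − μ) / (s₂ + μ)` with `μ` a Gaussian
local mean (width 0.5 deg, `s₂ = 0.1`): a divisively normalized contrast
signal that adapts to the local light level.

**Layer 3 — CSF and spatial masking.** A radial contrast-sensitivity filter
`g(f) = (f/f_p)^a · exp(a(1 − f/f_p))` with peak `f_p = 4` cpd and shape
`a = 1` (gain ≈ 0.2 at 16 cpd, matching the qualitative human attenuation at
high frequency), times a Gaussian cutoff at 40 cpd; then divisive
normalization by locally pooled rectified signal,
`F / (s₃ + k₃ · G_{0.2°} * |F|)` with `s₃ = 0.12`, `k₃ = 4`.  This stage is
the model's frequency-*agnostic* masking: any high-contrast background
suppresses whatever is superimposed on it.

Every stage is bypassable; with all bypasses the front end is exactly
`L/mean(L) − 1`.  These front-end values are documented qualitative defaults
(they reproduce the CSF ordering and contrast uniformization the cortical
stage needs), not quantities fitted to data.

**Layer 4 — steerable pyramid + divisive normalization.** See below.

## Steerable pyramid

Frequency-domain construction: raised-cosine radial masks with one-octave
transitions and angular masks `∝ |cos(θ − θ_k)|^{K−1}` normalized so the
squared masks tile the plane.  Between scales the band-limited lowpass
spectrum is cropped exactly (the mask vanishes at the crop boundary), so the
analysis/synthesis pair is a tight frame and reconstruction is exact to
machine precision (measured ≈ 4·10⁻¹⁶ of the dynamic range).  The angular
factor uses the absolute cosine (even symmetry), which keeps all filters and
coefficients real.

Layout: highpass residual, then 3 oriented scales × {0°, 45°, 90°, 135°}
fine-to-coarse at their native resolutions, lowpass residual last — 14 bands,
25 664 coefficients at 64×64.  Band center frequencies at 64 samples/deg:
32 (highpass, nominal), 16 / 8 / 4 (oriented scales), 2 (lowpass, nominal) —
residuals sit one octave beyond the adjacent oriented scale and are
orientation-neutral in the kernel (orientation factor ≡ 1).  Coefficient
positions are corner-aligned dyadic grids in degrees, origin at the image
center; this nesting is what lets the kernel operator below be exact.

## Divisive normalization

Energies `e = |y|^γ`.  Model A: `x = sign(y) ⊙ e/(b + H·e)` with `H`
block-diagonal (spatial Gaussian within each band).  Model B:
`x = sign(y) ⊙ K(e*) ⊙ e/(b + H_G·e)` with
`H_G = D_c·[H_p ⊙ H_f ⊙ H_φ ⊙ C_int]·D_w` and
`K(e*) = κ ⊙ (b + H_G·e*)/e*`.  The bracket placement in `K` is fixed by the
normative property that the response at `e = e*` equals `κ` elementwise for
*any* parameter setting; this identity holds in the implementation to
< 10⁻¹² relative error and is the boundedness guarantee: however large the
kernel amplitudes, the output dynamic range stays anchored.

Spatial distances in the kernel are toroidal (consistent with the circular
boundary handling of the pyramid); frequency distance is `|log₂(f_i/f_j)|`
octaves; orientation distance is circular with period 180°.

The dense matrix is the literal definition and is only materialized for
small indices.  At full size (N ≈ 2.6·10⁴, a dense kernel would be ~5 GB)
an exactly equivalent matrix-free operator is used: each source band is
embedded on the finest grid, circularly convolved with the spatial Gaussian
via FFT, weighted by the per-band-pair scale/orientation/coupling factor,
and resampled onto each target grid.  Equivalence with the dense definition
is asserted in the tests at machine precision.

**Jacobians.** Analytic sensitivities of the Model B response for the blocks
`b, c, w, κ, γ`, with `K(e*)` differentiated through its definition.  The
`b`, `c` and `κ` blocks are diagonal; `w` is dense; `γ` is a vector
(`e* ` is treated as a fixed reference, not a function of `γ`).  A direct
consequence of differentiating through `K`: with a zero kernel the `b`
sensitivity vanishes identically, because `K = κ·b/e*` cancels the
semisaturation (`x = sign(y)·κ·e/e*`).  All blocks agree with central finite
differences to ~10⁻⁹ relative on random instances.

## Presets and calibration

The reference energy `e*` is the mean energy of ten seeded 1/f fixture
images passed through the front end (floored at 10⁻⁶ of its maximum so the
Model B division is well posed).  The output scale `κ` is the per-band mean
Model A response at `e*`, which transfers Model A's low-frequency-dominant
response profile — the carrier of the CSF ordering — into Model B.

Preset magnitudes are this package's own hand calibration; only their
direction is principled:

- `γ = 1` in the presets (the `NormParams` default is 2 and everything
  accepts arbitrary `γ`).  With quadratic energies a test added in phase to
  a same-band pedestal produces a facilitation ("dipper") regime in the
  response increment ‖Δx⁴‖ at low contrast; with magnitude energies the
  coherent increment is neutral and divisive pooling makes masking strictly
  attenuating, which is the regime the qualitative checks describe.
- Kernel row amplitudes per scale-group {highpass, scale1, scale2, scale3,
  lowpass} = {8, 8, 2, 1, 1}; saturated responses scale like 1/amplitude,
  preserving the low-frequency > high-frequency response ordering against
  the 16× larger sensor count of the finest band.
- Model A semisaturations `b = r ⊙ mean-band(e*)` with
  `r = {150, 150, 4, 2, 2}`: large at the fine scales, so the intra-band
  pool there is too weak to produce frequency-specific masking — the
  characteristic failure of the database-style calibration — while the
  coarse scales mask strongly and specifically.
- Model B naive: `b`, row amplitudes and `σ_p = 0.08°` imported from
  Model A; interaction lengths one octave across scale and 30° across
  orientation; `C_int` all-ones; `w = 1`.
- Model B tuned: `b` multiplied by {0.02, 0.02, 0.3, 1, 1} (largest
  reductions at high frequency), `w` per scale-group {3, 3, 1, 0.3, 0.2}
  (high-pass), row gains re-normalized with `w` in place and then doubled
  for the fine scales; `C_int` stays all-ones.

## Masking experiments

Default battery: Hann-windowed test patches at the coarsest and finest
oriented-scale centers (4 cpd vertical, 16 cpd horizontal at the default
geometry), full-field backgrounds at both frequencies × {0°, 45°, 90°},
background contrasts {0, 0.1, 0.2, 0.4}, eight log-spaced test contrasts in
[0.01, 0.5].  Additive luminance composition about the shared mean, clipped
to [0, 2L₀] with the clipped fraction reported; a battery clipping more than
1% of pixels fails loudly.  Sampling at 64 samples/deg keeps all stimulus
frequencies far from Nyquist.

The readout is ‖Δx⁴‖₂ over the subband tuned to the *test*, restricted to
the test patch's spatial support, with Δx⁴ = x⁴(background+test) −
x⁴(background).  The verdict's six checks: monotone growth in C; compressive
saturation (top-grid slope below bottom-grid slope); pointwise decay with
background contrast; CSF ordering of the unmasked peaks; and
frequency-specific masking for each test (matched-frequency background
attenuates more than the cross-frequency one at the same orientation, using
the attenuation ratio at mid-grid contrast).  Ordering checks carry a
configurable 5% relative margin; the monotonicity checks tolerate
deviations up to 5% of the curve peak, absorbing front-end intermodulation
ripple without hiding real facilitation.  The paper-pattern result —
intra-band and naive kernels fail only the high-frequency specificity
check, the tuned kernel passes everything — is deterministic.

## Synthetic data

Reference images are seeded 1/f^α noise fields (α = 1 by default, RMS
contrast 0.15, mean-luminance normalized): they reproduce the second-order
statistics of natural scenes and nothing else — no phase structure, edges
or objects.  Distortions cover the signal-independent/signal-dependent
taxonomy: additive white noise, high-frequency noise, Gaussian blur,
8×8 block-DCT quantization, and contrast-masked noise whose local amplitude
follows the background's local contrast.  Ratings are simulated as
MOS = link(oracle distance) + N(0, σ/√n_observers); the default link is the
exact negation (strictly decreasing and bijective in floating point, so
noiseless ratings preserve the full rank structure).

Consequently, a perfect Spearman correlation on these fixtures demonstrates
pipeline correctness — that the metric recovers the generating ordering —
not perceptual validity on photographic content; evaluation against real
databases is an I/O adapter (`load_rated_set`) left to the user.

## Numerical choices and limitations

- All computations in float64; FFT-based convolutions throughout, hence
  circular boundaries everywhere (stimuli are windowed or full-field
  periodic, so wrap-around is benign by construction).
- Degenerate inputs are rejected rather than coerced: aliased gratings,
  nonpositive luminance, zero `e*` entries, nonpositive denominators,
  constant MOS, empty sensor selections.
- Problem sizes: 64×64 px / 1° field for all headline experiments (the
  smallest geometry whose three oriented scales keep the two test
  frequencies two octaves apart and far from Nyquist); toy indices with
  N ≤ 64 for dense Jacobian validation.
- The tuned preset demonstrates *a* re-weighting that restores
  cross-masking, not an optimal or unique one; no fitting to human
  thresholds is performed anywhere.
- Chromatic processing, temporal stimuli and maximum-differentiation
  stimulus synthesis are out of scope.
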