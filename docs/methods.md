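# Methods

`chromatie` simulates and inverts single-shot quantitative phase imaging
(QPI) by spectral multiplexing of defocus. This note records the model, its
assumptions, the parameters that matter, and the boundaries of what the
synthetic experiments demonstrate.

## The forward model

**Scalar paraxial optics.** Light is a scalar envelope field
E = √I·e^{iφ} on a pixel-centred grid (all lengths in µm internally).
Propagation over a signed distance z uses the Fresnel kernel; numerically,
the transfer-function (frequency-chirp) path whenever the anti-aliasing
bound λ|z| ≤ N·Δ² holds, and the sampled impulse-response kernel beyond it.
Fields are mirror-padded by a factor of two before the FFT by default to
suppress periodic wraparound. Energy conservation, the exact z → −z
inverse, and the semigroup property hold to machine precision on the
unpadded (periodic) path, which is what the property tests exercise; the
padded path trades a ≲10⁻⁶-level crop loss for wraparound immunity.

**The metalens.** A hyperboloid metalens imparts
φ(r) = (2π/λ)(√(r²+f²) − f); being a diffractive element, its focal length
disperses as λ·f = const (δf/f = −δλ/λ). A lens designed for f = 1 mm at
530 nm therefore focuses 625 nm light ≈180 µm shorter and 455 nm light
≈295 µm longer. The ideal single-focus profile is modelled; fabrication
artifacts (the weak secondary focus seen in real lenses) are not.

**Channels as defocus planes.** Because the Fresnel pattern of a fixed
field depends only on the product ζ = λz, the three channels of a color
camera behind the lens sample the object's through-focus stack in one
exposure. `channels_from_train` assigns each channel the equivalent
defocus f·(λ−λ_G)/λ_G from the chromatic focal law — the separation an
empirical through-focus calibration recovers (≈179 µm for red–green at
f = 1 mm). Green defines z = 0 at the sensor; red (focusing earlier) is
recorded past its focus, blue before it. Conjugate-plane bookkeeping and
the slight per-channel magnification disparity of a single-lens train are
deliberately idealized into this one number, because that is also exactly
how the solver interprets the data; an optional per-channel affine rescale
(`SolverParams.rescale_channels`) exists for captures where the disparity
matters, and is off by default.

**Partial coherence.** The illumination is a white LED filtered by the
Bayer mosaic, so each channel has a finite linewidth (σ ≈ 27 nm for the
packaged curves). `simulate_capture` integrates each channel over a
7-node quadrature of its source×filter spectral product, each node with
its own 1/λ phase and its own focal-law defocus. This is not a cosmetic
detail: the defocus spread within one channel (≈±30 % for red) washes out
the high-frequency defocus fringes, which both matches the physical
instrument and keeps the inverse problem within reach of the first-order
solver — under fully coherent (single-λ) captures of strong binary
targets, intensity caustics reach ≈5× the background and the residual
iteration stalls well short of the true phase. The monochromatic limit is
available (`spectral_samples=1`) and is used by propagation-level oracle
tests.

**Detection.** Optional RGGB Bayer sampling with bilinear demosaic (off
by default: planes are co-registered as the solver assumes), Poisson
photon noise plus Gaussian read noise under a fixed seed, and an optional
coherent fiber bundle: a hexagonal lattice of intensity-only cores
(default 3 µm cores at 8.0 µm pitch, reconciling 18,000 cores/mm² with
the stated core size) that box-averages the intensity per core and
re-emits it flat, imprinting the honeycomb signature at 2π/pitch on every
channel identically.

## Phantoms

Phantoms are height maps h(x,y) (µm) with an index contrast δn; phase is
φ = 2π·h·δn/λ, exactly ∝1/λ. Pure-phase targets are unit-intensity at
focus.

- **Siemens star** — binary, hard-edged (ground truth exactly known);
  defaults match a 250 nm step in n = 1.52 material (δn = 0.52 in air).
- **Precision diffuser** — Gaussian random screen with Gaussian
  autocorrelation (1/e width = `feature_size`), scaled so the RMS phase
  gradient equals tan(divergence)·2π/λ, i.e. the far-field scattered beam
  has the stated half-width. Defaults (7 µm, 5°) emulate the commercial
  calibration part — deliberately a *strong* scatterer.
- **Filament phantom** — overlapping raised-cosine ribbons with a 60 µm
  helical height modulation (a chloroplast-band spiral pitch), peak-to-peak
  phase normalized exactly to `max_phase_range`. The smooth cross-profile
  bounds the phase gradient by ≈π·range/diameter, as a membrane-bounded
  cell does. Note that a 10π range at δn = 0.14 and 530 nm implies a
  ≈19 µm peak height (h = φλ/2πδn).

## The inverse solver

The spectral derivative dI/dλ is the through-focus derivative in disguise
(λdz = −zdλ). `estimate_dI` forms it from two channels (default red–green,
the pair with the best SNR in practice; (I_R−I_G)/95 nm) or from a
per-pixel weighted least-squares slope over all three unequally spaced
wavelengths (exact for planes linear in λ).

`tie_invert` then solves the transport-of-intensity equation
dI/dz = −(λ/2π)∇·(I∇φ) by the Helmholtz substitution I∇φ = ∇ψ and two
FFT-Poisson solves: ψ from ∇²ψ = −(2π/λ)dI/dz with Tikhonov constant ε,
then φ from ∇²φ = ∇·(∇ψ/I) with ε′, flooring I at `intensity_floor`
(default 0.05) before the division. Each solve divides by −(k²+ε) in the
Fourier domain, attenuating mode k by k²/(k²+ε); the zero mode is the
gauge (returned phase is mean-zero) and all derivatives inside the solver
are spectral, consistent with the Fourier inversion. The integration is
inherently unwrapped — no [0, 2π) constraint ever appears.

Defaults: ε = ε′ = 4·(2π/(N·Δ))², four times the fundamental mode's k²,
calibrated once on the star target and held fixed between calibration and
measurement. Iteration: `max_iterations` 10, `relative_tolerance` 10⁻³.

**Iterative refinement.** Starting from zero phase, each iteration
forward-propagates √I_G·e^{iφ·λ_G/λ_c} to every channel's equivalent
defocus (the 1/λ phase scaling makes the model exact for dispersionless
height objects; conveniently the same scaling cancels the λ factor of the
TIE at first order, so even the single-pass estimate is chromatically
unbiased), forms the intensity residual, re-estimates its spectral
derivative, and adds its TIE inversion to the phase. Iteration stops at
tolerance, at the iteration cap, or when the residual grows twice in a
row (the best iterate is returned, flagged non-converged).

**Update gain shaping.** The plain TIE linearization is valid only while
the defocus contrast-transfer argument γ = λ|z|k²/4π is small; the exact
linearized transfer of the channel-difference estimator,
T(k) ∝ Σ_c a_c sin(γ_c)·λ_G/λ_c, oscillates and changes sign past γ = π.
Refinement updates are therefore weighted by the regularized inverse
T/(T²+α) (α = `ctf_wiener`, default 0.05) — sign-correct in every lobe and
bounded at the transfer zeros — with two physical guards: a coherence
envelope exp(−(γσ_λ/|λ_c−λ_G|)²/2) per channel (σ_λ =
`channel_linewidth_nm`, default 27 nm) that encodes how the finite
linewidth erases high-γ contrast, and a hard freeze of modes where
|T| < 0.1, where the data carry no phase information and inversion would
only amplify model noise. All three are spectral filters on the *update*;
the fixed point of the iteration — where predicted intensities equal
measured ones — is untouched by them.

**Calibration.** `calibrate_channel_defocus` locates a channel's
equivalent defocus by normalized cross-correlation against a through-focus
stack of the same scene (experimentally: step the object, record the
channel), with parabolic sub-step interpolation. A pure-phase scene gives
the at-focus channel no contrast, so only off-focus channels (red, blue)
are calibratable — which is also all the solver needs.

## Validity domain, and what the tests do and do not show

The solver family is first-order in the defocus transfer. Its validated
regime, and the regime of every passing test, is bounded by three numbers:

- **Caustic onset.** Quantitative inversion requires pre-caustic captures.
  A screen with feature size p caustics near 2p²/λ only at unit phase
  strength; stronger screens caustic earlier (the local-lens distance
  ℓ/(σ_slope·λ/π·…) shrinks with slope). The 5°/7 µm calibration diffuser
  operates *beyond* onset at every channel defocus — by design, since
  calibration wants maximal contrast — and is therefore used only for
  correlation-based calibration, never for quantitative recovery. The
  parameter-recovery ensemble uses screens inside the validity band
  (14 µm, 0.5°).
- **Strong-phase saturation.** For multi-radian targets the recovered
  range saturates ≈10–15 % low: the residual-update direction stops
  descending even though the true phase is a stable fixed point of the
  iteration (verified directly). A curvature-aware (Gauss–Newton) update
  would close the gap but is a different algorithm family. The ~10π
  filament recovery lands at ≈12 % range error, not the 5 % one might
  hope for; the recovered maps are smooth and unwrapped (ranges far
  beyond 2π with no wrap artifacts).
- **Coherence band.** Information beyond the channel-linewidth envelope
  is physically absent from a broadband capture; recovered spectra are
  frozen there.

Within that domain the pipeline is quantitatively accurate without
per-target tuning: the 250 nm binary star recovers its plateau to ≈8 %
through the full synthetic instrument; weak-phase recovery is linear to
0.1 %; gentle random screens recover their band-limited phase to ≲4 % of
the screen's RMS.

The synthetic data are idealized in ways real captures are not: perfect
channel co-registration (no magnification disparity unless simulated), no
aberrations beyond defocus, exactly known spectra, shot/read noise only,
and inverse-crime consistency between the simulator's and solver's
propagators (modulo the deliberate poly/mono split). Passing tests
demonstrate the algorithm's correctness and its intrinsic limits, not
robustness to instrument imperfections.

## Numerical choices

- FFT-periodic boundaries with optional ×2 mirror padding (default on for
  captures and refinement; off in invariant tests).
- Second-order central differences for the forward rate evaluators
  (`tie_rhs`, `tpe_rhs`); spectral derivatives inside the solver. The
  transport-of-phase rate carries the factor dφ/dz = (λ/4π)[−|∇φ|² + …]
  that makes the pair the exact first-order expansion of Fresnel
  propagation (verified against finite differences of the propagator to
  <2 %).
- Degenerate inputs: all-zero derivatives return zero phase with a logged
  notice; intensities below the floor are clamped and counted; identical
  channel wavelengths, under-resolved features, and peak-at-boundary
  calibrations raise.
- Problem sizes: unit tests run at 128–256²; the end-to-end star
  validation at 512² (≈10 s); the 20-screen ensemble at 256²
  (≈45 s). The acceptance script completes in well under a minute.
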