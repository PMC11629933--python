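# Methods

`slmscat` is a scalar Fourier-optics simulator of an interferometric
scattering (iSCAT) microscope whose pupil is programmable: a spatial light
modulator (SLM) at a conjugate back-focal plane imposes an 8-bit
amplitude or phase pattern on the spatial-frequency content of the image.
On top of the simulator sits the quantitative pipeline used to evaluate the
filtering modes: contrast-optimising high-pass filtering, holographic-lens
focus control, live defocus-division background correction, and
directional-filter orientation estimation for anisotropic scatterers.

## Image formation model

The camera intensity is

    I(r) = | F⁻¹[ T(ν) · A(ν) · (B(ν) + S(ν)) ] |²

where `F⁻¹` is the unitary, DC-centred inverse discrete Fourier transform,
`T` the complex transmission displayed on the SLM, `A` the hard circular
pupil aperture (with a paraxial defocus phasor `exp(iπλz|ν|²)` for stage
translations), `B` the pupil spectrum of the background (reference) field
and `S` the coherent sum of the scatterers' fields.  The reference field is
the coverslip reflection itself — a common-path geometry, so no separate
reference channel exists.  All spatial frequencies are sample-plane
frequencies in cycles/μm; positions are in μm from the field-of-view corner
with the optical axis at array index n/2.

A point scatterer of amplitude `s` contributes an aperture-limited plane-
wave ramp for its position, weighted by the local illumination envelope and
normalised by the in-focus PSF peak, so its unfiltered interference
contrast is `2·s·cos(φ) + s²` wherever it sits in the envelope.  Nanorods
carry two orthogonal in-plane scattering modes with pupil-azimuth weights
|cos(ψ−α)| (longitudinal) and |sin(ψ−α)| (transverse).  The default rod
preset uses equal mode amplitudes with a π interferometric offset — the
minimal model that reproduces a 90°-periodic contrast-magnitude modulation
under a rotating directional filter, consistent with the rod's two
perpendicular symmetry axes.  A consequence worth knowing: with exactly
equal amplitudes the two modes cancel in the unfiltered image, so rods are
(nearly) invisible without a directional filter; real rods are not, but no
unfiltered-visibility observable is analysed here.

## PSF-width calibration

The pupil radius is parameterised as an *effective* numerical aperture.
Real iSCAT instruments image wider spots than the diffraction limit of
their objective; rather than modelling the aberrations responsible, the
aperture is shrunk until the simulated spot matches the measured width.  A
least-squares Gaussian fit to the azimuthally averaged radial profile of
the intensity PSF obeys σ ≈ 0.21·λ/NA_eff for a hard aperture; matching the
measured σ = 0.61 μm at λ = 0.640 μm calibrates NA_eff = 0.2196
(`CALIBRATED_EFFECTIVE_NA`), i.e. a pupil cutoff ν_NA ≈ 0.343 cycles/μm.
The choice of fitting the *intensity* profile (not amplitude) is a
convention; the amplitude fit would give a different constant.

This calibration has a far-reaching consequence: spatial periods shorter
than 1/ν_NA ≈ 2.9 μm cannot pass the aperture at all.  For any hard
aperture the contrast-maximising high-pass period is therefore bounded
below by 1/ν_NA ≈ 4.8σ, whereas the instrument measurement being
reproduced reports an optimum of ≈ 1.1σ (0.67 μm).  The two reported
values — PSF width and optimal cutoff — are mutually incompatible in a
scalar hard-aperture model; this package follows the PSF-width calibration
and reports the optimum its own physics produces (periods of 3–5 μm, see
the high-pass experiment), rather than adjusting either number.

## Synthetic scenes

The generator emulates spin-coated gold nanoparticle samples:

* **Particles** — 5/10/20/40 nm presets; scattered amplitude follows the
  volume law `s(d) = s₀·(d/40 nm)³` with `s₀ = 0.05` relative to the unit
  reference (≈10% unfiltered contrast at 40 nm).  Placement is uniform
  with a 3 μm minimum separation inside the illuminated core (±6 μm):
  coherent imaging makes the diffraction tails of close particles
  interfere, visibly displacing apparent spot positions below ~3 μm
  spacing.
* **Background** — a Gaussian reference envelope (1/e² intensity radius
  8 μm) times `1 + speckle`, where the speckle is correlated complex
  Gaussian noise (RMS 3% of the envelope peak, 1/e field-autocorrelation
  length 0.7 μm) standing in for coverslip roughness.  Each speckle draw is
  rescaled so its realised RMS equals the requested value exactly.
* **Camera** — full well 10 000 e⁻, read noise 5 e⁻ RMS, 16-bit; the
  exposure is metered once per acquisition so the noiseless maximum pixel
  sits at 87.5% of full well (midpoint of the 85–90% operating rule).
  Metering per-frame instead would imprint a global scale modulation on
  displaced stacks and bias every contrast downstream.

What the generator does **not** model: Mie/plasmon spectra, substrate
Green's functions, Brownian motion, vectorial/polarisation propagation,
SLM crosstalk and flicker, camera fixed-pattern noise.  Passing tests show
the pipeline recovers what this forward model produces; they do not certify
performance on real camera data.

## Measurement pipeline

1. **Acquisition** — stacks displace all particles laterally by 2 μm per
   frame over the static background.  The step must exceed the ~2.4 μm spot
   diameter, otherwise the per-pixel median retains particle signal (a 0.5
   μm step biases baselines by up to 50%).  Under a directional filter the
   spot becomes a streak perpendicular to the filter angle; the
   displacement is then taken *along* the filter angle so frames vacate
   each pixel.
2. **Normalisation** — each frame is divided by the per-pixel median
   projection.  Ratios are evaluated only where the reference holds light
   (median counts > 1% of maximum); a dark pixel divided by a dark pixel
   carries no contrast information.
3. **Detection** — deviations |I−1| are standardised by the local noise
   scale (× counts/√(counts+σ_read²)), band-passed with a PSF-matched
   Gaussian minus a 6σ median surround (a median surround ignores
   neighbouring spots, which a Gaussian surround would subtract), and
   thresholded at max(64th percentile, 5× the robust noise scale; the MAD
   of folded half-normal deviations equals 0.3986σ).  Secondary maxima in
   the diffraction-ring zones of stronger peaks are suppressed
   (< 0.35 within 3σ, < 0.10 within 8σ, < 0.05 anywhere).  Positions are
   centroid-refined.
4. **Contrast** — a line profile through the detected spot is fitted with
   `Ib + A·sinc((x−x0)/w)` (normalised sinc, first zero at w; x0 bounded to
   ±2σ around the detection so the fit cannot latch onto a neighbour);
   `C = (Is−Ib)/Ib` with `Is = Ib + A`.  Dark particles keep A < 0; the
   sign is never folded.
5. **Aggregation** — sweeps report the mean contrast per filter setting
   with a seeded 1000-resample bootstrap CI95 over particles; missing
   particles are propagated as missing, never imputed.

## Experiments

* **High-pass sweep** — 20 cutoffs spanning periods 0.3–5 μm plus the
  unfiltered baseline; 3 random scenes of 12 particles per size preset,
  noise off (the 5 nm preset's 2·10⁻⁴ contrast is far below single-frame
  shot noise; the stochasticity under study is scene placement).  The
  optimum is the argmax of mean contrast (ties to the smallest cutoff);
  the enhancement factor is mean contrast at the optimum over baseline.
  Under the calibrated aperture every nonzero cutoff in this range removes
  the entire reference envelope (its spectrum dies by ν ≈ 0.1 cycles/μm),
  so the whole sweep operates in the dark-field limit where the measured
  contrast is set by the 3% speckle floor: optima land at multi-micrometre
  periods and enhancement factors an order of magnitude above what partial
  reference suppression would give (the acceptance script reports both).
* **Lens calibration** — mean contrast versus lens power pf at fixed
  stage, matched by interpolation against contrast versus stage z; the
  fitted slope is the device constant κ (default 50 μm per unit pf, chosen
  so the full defocus range used by background correction stays within the
  zone-sampling limit of the simulated pupil raster), and one 8-bit step
  changes focus by κ/256 ≈ 0.195 μm.
* **Background correction** — alternating frames with and without a
  Fresnel lens at the first defocus null z = 2/(λν_NA²) ≈ 26.6 μm
  (pf = 0.53125), where the defocus phase completes one turn across the
  aperture and a particle's on-axis image vanishes.  The focused frame is
  divided by the defocused one.  The <10% residual-contrast precondition is
  achievable only in sparse fields: at this low NA a defocused particle
  becomes a ring of radius λzν_NA ≈ 5–9 μm that crosses neighbours'
  positions in dense scenes, and the protocol then refuses with an
  explicit insufficient-defocus error.
* **Orientation** — the directional band (default thickness 0.2 cycles/μm,
  wide enough to pass the reference envelope's spectrum whole; thinner
  bands clip it and imprint a spurious 180°-period modulation) rotates
  from −90° to +90° in 5° steps.  Each rod is imaged in its own field of
  view: the band stretches every particle into a streak of length
  ~1/thickness = 5 μm, comparable to the illuminated area, so dense fields
  corrupt each other's curves.  Per-rod contrast-magnitude curves are
  normalised to their own maximum, aligned at their maxima, merged, and
  fitted with a free-period sine.  Band edges are anti-aliased over one
  frequency pixel: a binary strip's pixel count on the coarse simulated
  raster beats against the grid by ±36% as it rotates.  The axis estimate
  is reported modulo 90° (the rod model's symmetry makes orientations 90°
  apart indistinguishable); a modulation depth below 0.5 yields an
  explicit "no orientation" result; isolated-sphere controls sit well
  below that threshold and rods well above it (both are asserted in the
  acceptance suite).

## Numerical choices and limitations

* Unitary DC-centred FFTs; Parseval holds to <1e−10 relative on every
  transform.
* The free-period sine fit applied to a rectified cosine over a finite
  window is intrinsically biased low (88.8° for ideal |cos 2θ| sampled at
  5° over ±90°); fitted rod periods of ~88–94° are expected and within the
  reproduction tolerance.
* `fresnel_pattern` quantises both the lens power (steps of 1/256) and the
  phase levels (256 levels) and rejects powers whose phase would alias
  across one pupil pixel at the pattern edge.
* Degenerate inputs are explicit: fully blocked filters return flagged
  zero frames; zero median pixels, non-square stacks, infeasible
  placements and insufficient defocus raise named errors.
* Problem sizes default to 512² grids, 12 particles per field and 3 scene
  seeds; all experiments complete in minutes on one CPU and every stage of
  the pipeline runs end to end at those sizes.
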