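# slmscat

Adaptive Fourier-plane filtering for interferometric scattering (iSCAT)
microscopy, in software: a desk-scale scalar-optics simulator of an iSCAT
instrument whose back focal plane is programmable via a spatial light
modulator (SLM), plus the quantitative analysis pipeline that evaluates
what such filtering buys.

iSCAT images nanoscopic, label-free objects through the interference
between a reference field (the coverslip reflection) and the light a
particle scatters; the observable is the contrast `C = (Is − Ib)/Ib` of a
particle's signal against its local background.  Placing an SLM at a
conjugate back-focal plane turns the pupil into a programmable complex
mask `T(ν)`, and the camera records

    I = | F⁻¹[ T(ν) · A(ν) · (B(ν) + S(ν)) ] |²

with `A` the (calibrated) pupil aperture, `B` the background spectrum and
`S` the scattered field.  The package generates the 8-bit device patterns
(high/low/band-pass, directional bands, Fresnel zone-plate lenses, fork
and grating holograms), renders camera frames of synthetic nanoparticle
samples with realistic noise, and measures what each filter does:

* **Contrast optimisation** — high-pass sweeps with per-particle sinc-fit
  contrast, optimal-cutoff and enhancement-factor estimates;
* **Focus control** — Fresnel lens power ↔ stage defocus calibration and
  focus restoration without moving parts;
* **Background correction** — alternating focused/defocused acquisition
  with live frame division;
* **Orientation detection** — rotating directional filters that modulate
  nanorod contrast with a ~90° period, yielding sub-diffraction in-plane
  axis estimates.

It is aimed at people building or modelling iSCAT/SLM instruments who want
to prototype pupil filters and analysis settings before touching hardware.

## Worked example: orientation of a single nanorod

```python
import numpy as np
from slmscat import (
    GridSpec, make_rod_scene, AcquisitionConfig,
    orientation_sweep, estimate_orientation, align_merge, fit_sine,
)

grid = GridSpec(n=512, pixel_size=0.1)        # calibrated PSF sigma 0.61 um
scene = make_rod_scene([30.0], seed=2, grid=grid)   # one rod, axis at +30 deg
config = AcquisitionConfig(n_frames=6, noise=False, seed=1)

curves = orientation_sweep(scene, config=config)    # -90..90 deg in 5 deg steps
est = estimate_orientation(curves.thetas, curves.curves[0])
theta, rel = align_merge(curves)
fit = fit_sine(theta, rel)

print(f"axis estimate: {est.alpha_deg:+.0f} deg "
      f"(modulation depth {est.modulation_depth:.2f})")
print(f"fitted period: {fit.period:.1f} deg")
```

Output:

```
axis estimate: +30 deg (modulation depth 1.00)
fitted period: 91.5 deg
```

The rod is diffraction-limited — its image looks like a sphere's — yet the
rotating band filter modulates its contrast magnitude with a ~90° period
(two perpendicular symmetry axes), and the angle of maximum contrast reads
out the in-plane axis to within one 5° filter step.  The axis is only
defined modulo 90° under this symmetry; an isotropic sphere gives a flat
curve and an explicit "no orientation" result.

A command-line surface wraps the same experiments:

```bash
slmscat simulate --preset aunp40 --seed 1 --out-dir out/
slmscat sweep-highpass --preset aunp40 --seed 1 --out-dir out/
slmscat sweep-angle --preset aunr --seed 1 --out-dir out/
slmscat export-pattern fresnel --rf 40 --pf 0.25 --out-dir out/
```

Each command writes its outputs (16-bit TIFF stacks with JSON sidecars,
per-particle CSVs, device-ready 8-bit pattern bitmaps) plus a JSON summary
and the fully resolved configuration, so every artifact is reproducible
from its log.

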