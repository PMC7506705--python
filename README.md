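# fireflysim

Forward model, synthetic-scene generator and characterization toolkit for
FIREFLY (fluorescence imaging of red and far-red light yield), an airborne
imaging spectrometer built to retrieve solar-induced chlorophyll
fluorescence (SIF).

## The scientific problem

SIF is the faint re-emission (650–850 nm, peaks near 685 and 740 nm) of
solar energy absorbed by vegetation — typically only 1–5 % of the upwelling
radiance in the red/far-red. Retrieving it from spectroscopy therefore
demands an instrument characterized to an unusual standard: band centers,
spectral response widths (FWHM), radiometric response, shot noise, dark
current and stray light all leave fingerprints comparable in size to the
signal. Two retrieval archetypes bracket most practical methods:

* **direct** — subtract an estimated non-SIF baseline from the observed
  spectrum, band by band; the residual is SIF;
* **indirect (FLD-style)** — exploit the in-filling of an absorption
  feature: if a SIF-free reference gives the proportional depth
  `k = L_valley / L_peak` of a Fraunhofer line or telluric oxygen band,
  an additive signal `F` is recovered from observed radiances as

  ```
  F = (L_valley − k · L_peak) / (1 − k)
  ```

  which is immune to anything that scales both bands equally, but
  amplifies unequal influences (noise, spectral slopes) by `1/(1 − k)`.

`fireflysim` packages the characterized FIREFLY instrument (2160 bands at
0.0512 nm over 670–780 nm, 266 spatial pixels, 16-bit sCMOS) as a
configurable forward model: a linear band map `W = 5.12·10⁻² B + 670.12`,
a clipped polynomial FWHM surface over (pixel, wavelength) spanning
0.12–0.2 nm, a linear responsivity `R = −185.67 W + 173943` DN per
W m⁻² sr⁻¹ nm⁻¹, a shot-noise power law `σ = a·R^0.5295` anchored at
σ(16.88) = 0.4 mW m⁻² sr⁻¹ nm⁻¹, and a dark-current smile
(100 DN center / 105 DN edges / 115 DN corners, SD 2 DN). On top of it:

* a three-Gaussian parametric SIF emission model (two photosystem-II lobes
  + one photosystem-I lobe), calibrated to a 2.5 mW m⁻² sr⁻¹ nm⁻¹ apex at
  740 nm and anchor radiances 1.17 / 1.26 at the oxygen-A/B valleys;
* a synthetic high-resolution (0.0005 nm) spectrum generator with
  Fraunhofer-like lines, oxygen A/B and water-vapor clusters, panel and
  red-edge reflectances, Gaussian band synthesis, and full scene cubes with
  per-pixel ground truth — calibrated so the vegetation scene reproduces
  the characterized oxygen statistics (O2-A valley 16.88, depth 0.11;
  O2-B depth 0.757);
* absorption-feature discovery (±3-band valley/peak pairing with unique
  peaks), spectral-region tagging, sampling-resolution depth-loss analysis
  and feature-peak drift tracking;
* both retrieval archetypes, NDVI masking, and least-squares fitting of the
  emission model to per-feature estimates;
* closed-form and Monte Carlo error propagation (uniform/sloped/random
  influences, CI-vs-sample-size curves, spatial-aggregation experiments,
  observed-vs-expected coefficient-of-variation residuals);
* a characterization pipeline for monochromatic laser scans: absolute
  spectral responsivity (ASR) estimation, equivalent-width and half-max
  FWHM, band-center/response line fits, FWHM-surface fits, stray light,
  linearity and dark statistics — with a scan simulator for closed-loop
  parameter-recovery validation.

## Worked example

```python
import numpy as np
from fireflysim import (InstrumentModel, default_sif_params, sif_value,
                        default_scene_config, make_scene_cube,
                        oxygen_feature, indirect_retrieve, ndvi)

inst = InstrumentModel()
params = default_sif_params()
print(f"SIF(740 nm)      = {sif_value(740.0, params):.3f} mW m-2 sr-1 nm-1")

cube = make_scene_cube(default_scene_config(noise_on=False), inst)
spec = cube.pixel_spectrum(133)
v, p, k = oxygen_feature(spec, "o2a", inst)
print(f"O2-A valley band = {v} ({inst.band_wavelength(v):.3f} nm), "
      f"radiance {spec[v-1]:.2f} mW m-2 sr-1 nm-1")
print(f"O2-A depth k     = {k:.3f}")
print(f"NDVI (pixel 133) = {ndvi(spec, cube.wavelengths):.3f}")

baseline = spec - sif_value(cube.wavelengths, params)   # SIF-free reference
k0 = baseline[v-1] / baseline[p-1]
est = indirect_retrieve(spec[v-1], spec[p-1], k0)
print(f"FLD SIF estimate at the O2-A valley = {est:.3f} "
      f"(truth {sif_value(inst.band_wavelength(v), params):.3f})")
print(f"expected shot noise at the valley   = {inst.noise_sigma(spec[v-1]):.3f}")
```

prints

```
SIF(740 nm)      = 2.500 mW m-2 sr-1 nm-1
O2-A valley band = 1777 (761.102 nm), radiance 16.88 mW m-2 sr-1 nm-1
O2-A depth k     = 0.110
NDVI (pixel 133) = 0.798
FLD SIF estimate at the O2-A valley = 1.128 (truth 1.159)
expected shot noise at the valley   = 0.400
```

The noise-free vegetation scene reproduces the characterized oxygen-A
statistics (valley 16.88 mW m⁻² sr⁻¹ nm⁻¹, proportional depth 0.110); a
single-pixel FLD retrieval against a SIF-free baseline recovers the
injected emission to within its wavelength-offset bias (the valley and the
shoulder peak sample the smooth SIF curve ~3 nm apart), and the shot-noise
model predicts a per-sample standard deviation of 0.4 mW m⁻² sr⁻¹ nm⁻¹ at
the valley radiance — of the same order as the signal, which is why
indirect retrievals need spatial aggregation or repeated looks.

## Command line

A thin CLI wraps the library:

```bash
fireflysim make-scene --seed 7 --out scene7        # ENVI BSQ cubes + truth CSV
fireflysim sif-curve --out sif.csv
fireflysim features --cube scene7 --pixel 133 --out catalogue.csv
fireflysim retrieve --method indirect --cube scene7 --features catalogue.csv --out est.csv
fireflysim montecarlo --n-max 10000 --out ci.csv
fireflysim aggregate --factor 6 --reps 20 --out agg.csv
fireflysim calib-scan --seed 2 --out scan.csv
fireflysim characterize --scan scan.csv --out-prefix char
```

Every run logs the config hash, seed and version; identical seeds reproduce
outputs byte-for-byte (DN) or to float32 (radiance).

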