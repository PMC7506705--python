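# Methods

This note documents the models implemented in `fireflysim`, the reasoning
behind the open design choices, what the synthetic data do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Instrument forward model

**Band grid.** Wavelength is linear in band index,
`W = 5.12·10⁻² · B + 670.12` nm, `B = 1…2160`; spatial pixels run 1…266.
All indices are 1-based to match the instrument's own numbering, and every
file the toolkit writes carries explicit wavelengths so the convention
cannot leak.

**FWHM surface.** The characterized fit over spatial pixel `D` and
wavelength `W` is, as printed, `2·10⁻⁶ D − 7·10⁻⁴ D − 7·10⁻⁴ W + 0.76405` —
two linear `D` terms, which is degenerate (they would simply sum). The
default implementation reads the first term as quadratic,
`2·10⁻⁶ D²`, keeping every printed coefficient; the literal degenerate form
remains selectable (`FwhmSurface(form="literal")`). Neither reading stays
inside the characterized 0.12–0.2 nm range over the whole detector, so the
evaluated value is clipped to that range — the clip is part of the model
contract, not a safety net. The fit's residual SD (7.32·10⁻³ nm) is carried
as metadata.

**Radiometric response.** `R(W) = −185.67·W + 173943` DN per
W m⁻² sr⁻¹ nm⁻¹, positive across 670–780 nm, with a linear DN uncertainty
`U(W) = 2·10⁻⁴·W − 0.1005`. Radiances are mW m⁻² sr⁻¹ nm⁻¹ everywhere in
the package; the per-W response is divided by 1000 internally. Linearity is
modelled as exact (the real detector is linear to 0.3 % over
10,000–50,000 DN; a vendor non-linearity correction exists upstream and is
out of scope), so simulated DN deviate from a line only by quantization.

**Shot noise.** `σ(R) = a · R^0.5295` in radiance units. The printed
amplitude (365.99) is dimensionally inconsistent with every worked
(R, σ) pair of the characterization (it would give σ ≈ 1634 at R = 16.88
where 0.4 is reported). The default `units_mode="physical-anchored"`
therefore rescales the amplitude to `a = 0.4 / 16.88^0.5295 ≈ 0.0896`,
reproducing the (16.88 → 0.4) anchor exactly while keeping the
characterized exponent; the printed amplitude remains available as
`units_mode="printed"` for traceability. Note the worked pairs would imply
an exponent nearer 0.47–0.49; the printed exponent is retained
deliberately.

**Dark current.** A parabola over the spectral axis through 100 DN at the
central band and 105 DN at bands 1 and 2160 (three printed anchors admit a
quadratic uniquely), flat across the spatial axis, with the four detector
corners overriding to 115 DN; frame-to-frame variability is Gaussian,
SD 2 DN, quantized to integer DN.

**DN simulation.** `DN = round(clip(R·L/1000 + dark + N(0, σ·R/1000),
0, 65535))`; saturation is flagged, never raised; the inverse subtracts
dark and divides by response, so noise-free round trips are exact to the
quantization step.

## 2. SIF emission model

`SIF(λ) = A·[s_PSII·(g(λ;685,10) + m·g(λ;μ₂,18)) + s_PSI·g(λ;740,20)]`
with unit-peak Gaussians `g`, so the scale factors read as peak ratios, and
`A` chosen so `SIF(740) = apex_740`. Because of that normalization the two
scale factors enter only through their ratio — a deliberate
identifiability trade-off, handled in fitting by bounded multistart and by
asserting recovery on the curve rather than the raw scales.

The published shape table for the second PSII lobe is not available, so its
mean `μ₂` is left free and the model is calibrated against three anchor
radiances of the benchmark emission curve: 2.5 mW m⁻² sr⁻¹ nm⁻¹ at 740 nm,
1.17 at 760.9488 nm (oxygen-A valley band), 1.26 at 687.1696 nm (oxygen-B
valley band). With the second-lobe mix weight fixed at 1 (nowhere stated;
equal peak weight is the neutral choice), the anchor system has two roots,
μ₂ ≈ 722.3 and ≈ 733.5 nm; the solver brackets the upper root, which sits
in the physically expected far-red-shoulder range. The calibrated ratio
`s_PSII/s_PSI ≈ 0.876` gives a curve with exactly two local maxima on
670–780 nm and negligible energy beyond 840 nm.

## 3. Synthetic scenes

**What is emulated.** A flat continuum (optionally tilted) multiplied by
`∏(1 − dᵢ·profileᵢ(λ))` on a uniform 0.0005 nm grid over 665–785 nm:

* 150 Fraunhofer-like Gaussian lines (deterministic catalogue, fixed
  internal seed; depths 0.05–0.65, widths 0.025–0.08 nm, minimum spacing
  0.25 nm so lines stay resolvable at FIREFLY FWHM);
* oxygen A: a saturated flat-bottomed trough centered on the characterized
  valley band (760.9488 nm) with a sharp blue edge toward the 756–759 nm
  shoulder, plus a decaying discrete branch to 770.4 nm; oxygen B: a
  narrower trough at 687.17 nm with a small red branch;
* water-vapor lines below 747 nm;
* reflectances: flat panels (white 1.0, gray 0.20, black 0.05) and a
  logistic vegetation red edge (0.05 at 670 nm → 0.5 by 756 nm, midpoint
  715 nm, scale 8 nm).

Band synthesis is a normalized Gaussian resampling with
`σ = FWHM/2.3548`; the half-max conversion is the package's choice for
*synthesis* (the source only says σ is "derived from" the FWHM function),
while the equivalent-width convention belongs to the *measurement* side
(section 5 below). Convolution windows extend ±5σ using an instrument-wide σ bound so
band values are identical whether a subset or the full grid is computed.

**Scene calibration.** The in-flight oxygen statistics over vegetation are
the scene's calibration targets: O2-A valley radiance 16.88
mW m⁻² sr⁻¹ nm⁻¹ with proportional depth 0.11, and O2-B depth 0.757 —
measured on the *total* radiance (baseline + SIF), as they were in flight.
The solve is sequential and exact: the O2-A trough depth and continuum
level are found jointly (valley/peak bands selected self-consistently on
the total radiance; the level pins the selected valley to 16.88, a 1-D root
solve pins the ratio to 0.11), then the O2-B depth is a second 1-D root
solve at the fixed level. Solved values for the default catalogue:
continuum ≈ 305 mW m⁻² sr⁻¹ nm⁻¹ at unit reflectance, trough depth scales
≈ 0.897 (A) and ≈ 0.281 (B). SIF is injected additively at the sensor (the
335 m path is treated as non-attenuating for the emission), after band
synthesis, evaluated at band centers — valid because the emission curve is
smooth at the 0.2 nm scale.

**Default scene layout.** 24 spatial pixels centered on reference pixel
133: 12 vegetation (with the default emission truth), 4 each white/gray/
black panels; DN are generated per-pixel from seeds spawned from the scene
seed. The aggregation experiments use a 36-vegetation-pixel variant. These
sizes are the package's desk-scale study conditions; all statistics that
matter are per-pixel, so pixel count trades only Monte Carlo smoothness.

**What is not emulated** (and hence what passing tests cannot show about
real data): true solar line statistics and line-shape physics (Voigt
profiles, pressure broadening), radiative-transfer atmospheres, BRDF and
view-angle effects, canopy structure and reabsorption, temperature-driven
spectral shift/squeeze, and spatial stray light. The synthetic continuum is
flat by default, so continuum-shape systematics are absent by construction.

## 4. Features, retrieval, uncertainty

**Feature discovery.** Valleys are strict local minima of band radiance
(plateau ties yield no feature; the "upward inflection" operator is read as
local minimum — the only reading that yields valley bands directly). Each
valley pairs with the band within ±3 bands (±0.153 nm) giving the lowest
valley/peak ratio; peak conflicts resolve deterministically in favour of
the deeper feature, the loser re-searching its window — so no two features
share a peak. Region tags (O2-A 759–770.5, O2-B 686–715, water vapor
< 747, leaf slope 686–756, split window 756–759 ∪ 770.5–774.5, polynomial
SIF > 774 nm) are closed at printed endpoints, with the shared endpoints
759.0 and 770.5 assigned to O2-A; every wavelength gets at least one tag
("unflagged" as fallback).

**Broad oxygen features.** The oxygen bands as wholes exceed the ±3-band
window; `oxygen_feature` takes the minimum-radiance band inside the region
and the maximum on the blue shoulder (756–759 nm for A, 684–686 nm for B).

**Sampling-resolution depth loss.** Decimating the band comb re-measures
each feature as a coarse observer would: lowest retained sample adjacent to
the true valley, highest retained sample within the same ±3-band
*wavelength* window (the window is a spectral span and does not widen with
coarser sampling). Under this operationalization a coarser comb can only
miss extrema, so every feature's depth is reduced or preserved — the
qualitative claim the toolkit asserts; the quantitative loss is
spectrum-specific and not pinned.

**Peak drift.** For each feature the radiance maximum within ±3 bands of
its nominal peak is located per acquisition; offsets are reported from the
modal band, and monotone offset sequences with net change are flagged as
candidate spectral shift. Tracking is meaningful for features whose summit
dominates its neighbourhood; nominal peaks on a monotone slope pin to the
window edge and cannot register drift (the tests select dominant-summit
features accordingly).

**Retrieval.** Direct: `observed − baseline` per band. Indirect:
`F = (v − k·p)/(1 − k)` — the unique single-pair form consistent with a
proportional SIF-free baseline. Its error algebra is asserted exactly:
uniform influences pass one-to-one; a valley-only influence is amplified by
`1/(1 − k)`; a slope `m` with signed valley→peak distance `d` gives error
`−k·m·d/(1 − k)` (negative when the peak is raised relative to the valley,
growing with |m|, |d| and k); independent Gaussian band noise propagates to
a Gaussian error with SD `√(σ_v² + k²σ_p²)/(1 − k)`. The linear form makes
the noise-driven error distribution Gaussian; a bimodal distribution has
been described for this configuration elsewhere, but it does not follow
from the single-pair algebra, so the toolkit reports the empirical
distribution without asserting bimodality. NDVI uses 670–680 nm (red) and
770–780 nm (NIR) window means — no specific bands are prescribed anywhere,
so the windows are configurable.

**Emission-curve fitting.** Weighted least squares over (apex, s_PSI,
s_PSII) with shape constants fixed at the default calibration, bounds
scales ∈ [0,1], apex ≥ 0, and ≥ 5 seeded starts (the scale-ratio
degeneracy and the bounded box can strand a single start). Weights default
to 1/σ² from the noise model. Aggregation experiments average *retrieved
per-feature estimates* over factor² vegetation pixels (NDVI-masked at 0)
before fitting; radiance-first averaging is available as an option.
Indirect estimates carry a small wavelength-offset bias (valley and
shoulder sample the smooth emission curve at slightly different
wavelengths), so "exact" recovery claims are reserved for the direct path.

**CV residuals.** Repeated stable-target series are split into windows of
100; windows whose mean trace has a linear time trend significant at
p < 0.01 are trimmed (operationalizing "sections with trends were
removed"), then per-band CV minus the model CV `σ(R)/R` is reported.

## 5. Characterization pipeline

**Scan simulation.** The default plan mirrors the characterized campaign:
four 0.05 nm ranges (690–694.5, 707–711.5, 725–729.5, 760–764.5), five
0.15 nm ranges (the source table lists 742–746.5 twice; the plan
deduplicates), and a 1 nm sweep 690–1000 nm for stray light. Open frames
respond to a narrow Gaussian laser line through each band's SRF
(σ_eff combining SRF width and 0.004 nm laser width), plus dark and noise;
shuttered background frames interleave every 5 open frames. The simulated
sphere radiance (0.05 W m⁻² sr⁻¹ nm⁻¹) puts peak responses mid-dynamic-
range.

**ASR estimation.** Open frames are background-adjusted against the mean
of the nearest background blocks on both sides; records with laser
wavelength SD > 0.03 nm are excluded (units read as nm). Per band, samples
within ±0.8 nm of the strongest response are Gaussian-fitted and
interpolated to the 0.001 nm grid. "Insufficiently sampled central peaks"
are excluded by rule rather than inspection: fewer than 5 samples within
±2σ of the fitted center, or fewer than 2 on either side of it, drops the
band. The ±2σ window (rather than ±1σ) makes the sample-count threshold
satisfiable at the 0.05 nm scan step, where a ±1σ window can hold at most
3 samples; the per-side requirement removes the one-sided peaks at scan-
range edges, whose fitted centers are biased by several millinanometers.

**FWHM estimators.** Band responsivity is `Σ ASR·Δλ` (Δλ = 0.001 nm);
the equivalent-width FWHM divides it by the peak ASR, and the direct
half-max width is reported as a diagnostic. On a Gaussian the two differ
by exactly `√(2π)/(2√(2 ln 2)) ≈ 1.0645`; the equivalent-width estimator
feeds the FWHM surface, for fidelity to the characterized values.

**Fits.** Band centers vs band index and band responsivity vs wavelength
are ordinary least squares with R², residual SD, and a residual-magnitude
line (the uncertainty model's form). The FWHM surface fit is linear least
squares on the [D², D, W, 1] design (or [D, W, 1] in literal form) with a
rank check that rejects collinear samples such as a single spatial pixel.
Closed-loop recovery from a simulated scan — the pipeline's validation
contract — recovers the band-map slope/intercept within 0.1 % and the
response slope within 1 % at default noise.

**Stray light, linearity, dark.** The signal-distribution matrix
normalizes every band's background-adjusted response to the in-band
maximum per laser wavelength; off-diagonal medians (bands > 0.5 nm from
the line) quantify the stray floor, and 800–1000 nm records give far-field
mean/SD. Linearity reports the maximum fractional deviation from a line
fitted over the 10,000–50,000 DN window. Dark statistics are element-wise
means/SDs with spectral and spatial profiles.

## 6. Numerical conventions and limitations

* Random draws flow from explicit seeds (`numpy` `default_rng`/
  `SeedSequence`); per-pixel and per-rep seeds are spawned from the
  top-level seed, and identical configurations reproduce DN byte-for-byte.
* Root solves use Brent's method (tolerances 10⁻⁹–10⁻¹²); the SIF
  calibration validates all three anchors to 10⁻⁶ relative and reports
  diagnostics when infeasible.
* Proportional depths near 1 (saturated trough floors) are numerically
  degenerate: ratios between two nearly-zero radiances. Monotonicity
  claims about depth vs FWHM are therefore asserted for features with
  k < 0.99.
* ENVI cubes are BSQ, uint16 (DN) or float32 (radiance), single-line
  pushbroom frames with explicit wavelength lists; truth tables ride as
  CSV sidecars.
* Known limitations: no atmospheric radiative transfer or BRDF; no
  spectral smile/keystone *correction* (drift detection hooks only); the
  fitted-scale degeneracy means individual photosystem scale factors from
  `fit_sif_params` are only ratio-identified; the synthetic line catalogue
  is statistically, not astronomically, realistic.
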