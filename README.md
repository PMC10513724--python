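# fgscheck

Bench-characterization metrics for open-field fluorescence-guided-surgery
(FGS) imaging systems, with a synthetic phantom generator so every metric
can be exercised — and its estimators validated against known ground
truth — without instrument access.

FGS cameras overlay the emission of a near-infrared contrast agent
(typically indocyanine green, ICG) on the surgical field. Different
FDA-cleared systems differ widely in resolution, illumination uniformity,
lens distortion, depth of field, sensitivity and background rejection,
and those differences are invisible in vendor spec sheets. `fgscheck`
implements a standardized nine-test protocol over simple phantom images
and spectrometer traces:

1. **Excitation band** — peak wavelength and FWHM of the source spectrum.
2. **Illumination power density** — recorded power-meter metadata (echoed
   into reports, never measured here).
3. **Spatial resolution & sharpness** — USAF-1951 bar targets scored with
   the contrast transfer function

   `CTF(%) = 100 · (max(r) − min(r)) / (max(r) + min(r))`,

   where `max(r)` / `min(r)` are the means of the top / bottom 20% of
   pixel values in the element region, and a USAF element in group G,
   element E resolves `2^(G + (E−1)/6)` line pairs per mm
   (line width in µm = `1000 / (2·lp/mm)`).
4. **FOV uniformity** — column-mean profile over a ±50-row central band
   of a homogeneous fluorescent slab, normalized to its maximum.
5. **Spatial distortion** — subpixel spacings between equidistant
   fluorescent dots along mid-height rows, normalized by the largest
   spacing (an undistorted grid reads 1.0 everywhere).
6. **Depth of field** — CTF of the 1.0 lp/mm element versus signed
   distance z from the plane of focus; the in-focus range is read off at
   a 60% CTF threshold.
7. **Concentration sensitivity** — well-plate dilution series
   (1000…1 nM ICG-equivalent + blank + QD800 room-light control): noise
   floor, limit of detection (`mean > control + 3σ`), saturation flags.
8. **Imaging depth** — wells under 0.5–6 mm of tissue-mimicking
   overburden: deepest detectable well and an exponential attenuation fit
   `mean − floor = I₀·exp(−d/d_att)`.
9. **Signal-to-background ratio** — `10·log₁₀` of the mean-square power
   in a well disk over its surrounding annulus (outer radius 1.5×), in dB.

The synthetic generator (`fgscheck.synth`) renders each phantom through a
forward camera model (defocus blur, radial vignette, Brown distortion,
Poisson–Gaussian noise, optional display LUT, bit-depth quantization) and
returns a ground-truth sidecar sufficient to re-render the fixture
bit-identically, so recovery tests are exact.

## Worked example

The package is used from Python; `examples/` has one narrative script per
capability. Uniformity, for instance (`examples/03_uniformity_vignette.py`)
images a homogeneous slab through a camera with 30% vignetting and sensor
noise, then inverts the radial fall-off model:

```
min profile value      : 0.807
columns >= 0.9         : 71.9%
center / edge ratio    : 1.239
vignette strength      : true 0.30, estimated 0.301
```

Intensity at the lateral field edges drops to ~81% of the center, and the
estimator recovers the generating vignette strength to three decimals.
`examples/08_full_protocol.py` runs all nine tests from YAML configs for
two synthetic systems and prints the side-by-side comparison table.

## Acceptance script

`scripts/acceptance.py` recomputes the analytic USAF-1951 target
arithmetic (line widths and lp/mm of the coarsest and finest standard
elements, plus an intermediate sixth-octave step) directly from the
package's element calculator:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/fgscheck/io_config.py` — images (TIFF/PNG/JPG/MP4 frames), spectra
  CSV, ROI/well layouts (YAML/JSON), the shared data model.
- `src/fgscheck/synth.py` — phantom renderer + ground-truth sidecars.
- `src/fgscheck/spectral.py`, `resolution.py`, `field.py`, `wells.py` —
  the nine metrics.
- `src/fgscheck/report.py` — protocol orchestration, provenance-hashed
  reports, cross-system comparison.
- `docs/methods.md` — models, estimator choices, numerical conventions
  and known limitations.
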