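# Methods

This note records the models behind each metric, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that make results reproducible.

## Data model and conventions

Pixel coordinates are 0-based, row-major, origin top-left; rectangles are
half-open so they slice arrays directly. Images carry their container bit
depth; all metrics operate on float copies and never mutate inputs. Color
inputs are reduced to a scalar channel by the unweighted channel mean
("luminance") or a named channel — vendor display renders carry no
defensible RGB weighting, so no perceptual weights are applied. JPEG
sources are accepted (some systems export only JPEG) but flagged lossy in
provenance. For video containers the first frame is quantified by
default, with an explicit frame index as escape hatch.

Vendor display overlays map detected intensity through look-up tables
(LUTs); the package *emulates* monotone LUTs in the simulator (to study
their effect on perceived floor and saturation) but never attempts to
invert them — quantification assumes scalar-intensity inputs.

## Forward camera model (synthetic phantoms)

Fixed application order: scene → defocus blur → vignette × gain → noise →
LUT → quantization.

- **Defocus**: Gaussian blur with σ(z) = σ₀ + s·|z|, z in cm from the
  plane of focus. No optical prescription is claimed; monotone blur
  growth is the only property the depth-of-field test needs.
- **Vignette**: V(r) = 1 − v·(r/r_max)², r_max the half-diagonal. A
  radial quadratic rather than cos⁴ keeps a single recoverable strength
  parameter v ∈ [0, 1).
- **Distortion**: Brown radial model about the image center,
  r_d = r_u·(1 + k₁r_u² + k₂r_u⁴), radii normalized by the half-diagonal.
- **Noise**: Poisson(scale·latent)/scale plus Gaussian read noise; both
  default to zero so exact tests are possible.
- **Quantization**: round and clip to [0, 2^bit_depth − 1]; 16-bit by
  default.

Every render is a pure function of (parameters, seed); the ground-truth
sidecar re-renders the fixture bit-identically and doubles as the layout
(ROI) source for the metric modules.

Defaults describe a plausible bench scene, chosen once: USAF bars at
10–40 px/mm over a dark background; an 18×18 cm-equivalent slab larger
than the field; a 2×9 dot lattice at 40 px spacing rendered as Gaussian
blobs (σ 1.5 px) so peaks are subpixel-defined; nine-well plates of
1 cm-equivalent wells (radius 18 px, pitch 60 px) in a 3×3 grid. The
concentration plate uses floor 100 DN and 250 DN/nM so the 1000 and
300 nM wells clip at the 16-bit ceiling — the saturation pattern real
systems show — and the depth plate uses I₀ = 40000 DN with attenuation
length 2 mm over a 0.5–6 mm overburden series (eight depths plus a 6 mm
blank control). The QD800 well renders above floor only when a visible
room-light leak is configured: it is a control channel, not an ICG
signal. The physical phantoms' optical coefficients (µa ≈ 0.018 mm⁻¹,
µs′ ≈ 1.4 mm⁻¹ at 800 nm) are metadata only; mapping them to pixel
intensity is not modelled — the generator states image-level intensities
directly.

## Excitation FWHM

Baseline = median of the lowest decile of intensities (robust to dark
signal and ND-filter offsets), subtracted before peak finding. The peak
is the sample maximum; a tie plateau resolves to its wavelength centroid.
Half-maximum crossings are linearly interpolated between bracketing
samples on each side. No smoothing by default — smoothing biases width —
with an optional 3-point moving median for spiky traces. The estimator is
scale invariant, so whether a trace was max-normalized for display is
recorded but never matters. A peak at the window boundary or a missing
crossing raises an unresolved-band error rather than returning a number.

## CTF, sharpness, depth of field

`compute_ctf` uses the percentile form of the contrast formula: max/min
are means of the top/bottom 20% of ROI values, counts rounded up (≥ 1
pixel), stable sort. The 0.1–0.4 background threshold delineates target
extent only; it never removes pixels from the percentile statistics,
because dark bars legitimately fall below it — the recorded
`threshold_used` (default 0.2, midpoint of the allowed band) makes runs
auditable. An all-dark ROI yields an explicit degenerate result, not an
exception. Horizontal- and vertical-bar regions are always scored
separately and averaged; the same convention is used for the sharpness
ladder and the DOF curve.

Two intrinsic properties of this estimator are worth knowing:

- With blur present, the 20% tails include shoulder pixels, so even
  "mild" blur of 0.2 bar widths reads ≈ 92–93%, not ≥ 95%; values ≥ 95%
  require blur ≲ 0.1 bar widths.
- Under heavy blur (bar width ≲ 2σ) the CTF stops tracking the bars and
  floors at ≈ 25–30%: the tails then measure macro gradients of the
  blurred block against its dark surround. CTF is strictly decreasing in
  spatial frequency (and in σ) only in the informative regime; resolving
  limits and DOF thresholds (40% and 60% defaults) sit well above the
  floor, so summaries are unaffected, but raw curves should not be
  over-read below ~30%.

The in-focus range is the widest contiguous z interval at or above
threshold, ties broken toward the interval containing z = 0; an empty
range is signalled, not raised. Stacks may be asymmetric (e.g. a
proximity interlock trimming the near side).

## Uniformity and distortion

The uniformity profile is the per-column mean over mid-height ± 50 rows,
normalized to its maximum. Logo masks are excluded from the statistics
(never zeroed into them); a fully masked column is interpolated from its
neighbors. `estimate_vignette_strength` inverts the radial-quadratic
model analytically from the profile extremes, accounting for the band's
mean squared row offset — exact on noise-free slabs.

Dot spacings: the two dot rows nearest mid-height are auto-detected from
the row-mean profile (or given explicitly); per band, dots are peaks of
the column-mean profile with prominence ≥ 0.2 of the profile range and a
minimum separation of half the median spacing, refined to subpixel
positions by 3-point parabolic interpolation (pixel-quantized peaks alias
spacing estimates). Spacings are normalized by the *maximum* spacing so
an undistorted grid reads exactly 1 and deviations read < 1; two bands
with equal dot counts are averaged, otherwise the band nearest mid-height
is used. The distortion index is 1 − min(normalized spacing); the side
flag compares worst deviations in the left and right halves.

## Well panels

Wells are circular ROIs (a pixel belongs if its center is within the
radius); means and standard deviations are over disk pixels, normalized
to the panel's maximum well mean. The QD800 well is reported separately
and excluded from the ICG normalization. Detectability uses the
conventional 3σ limit-of-detection rule (`k_sigma` is a parameter and is
recorded). Saturation combines two rules: raw mean ≥ 0.99 of full scale,
and a plateau walk *downward from the highest concentration* flagging
consecutive wells whose means differ by < 1% of full scale, stopping at
the first real step. The downward walk is deliberate: applied pairwise
everywhere, the 1%-of-full-scale rule would also flag wells
indistinguishable down at the noise floor, which is not saturation.

Depth panels report the deepest well above the detection criterion and,
when ≥ 3 detectable non-saturated wells remain, a log-linear fit of
(mean − floor) against depth whose negative inverse slope is the
attenuation length; the control-well mean serves as the floor.

SBR uses area-normalized power — mean of squared pixel values — in the
well disk versus the annulus (r, 1.5r], in dB (10·log₁₀ of the power
ratio). Mean-of-squares rather than raw sums keeps the ratio independent
of the (unequal) disk and annulus areas; "0.5 units more than the well
radius" is read as outer radius = 1.5× the well radius, the only
unit-free interpretation. Annuli must not intersect other well disks and
must retain at least a quarter of the disk's pixel count.

## Reports

Tests run as independent stages in protocol order; one failure never
aborts the rest, and unconfigured tests are marked skipped with a reason.
No cross-test correction is applied (e.g. no flat-fielding of well panels
from the uniformity profile) — coupling stages would change what each
metric means. Reports carry the tool version, a hash of the
configuration, per-input file hashes and every decision parameter; JSON
serialization is deterministic (sorted keys, no timestamp), so identical
inputs produce byte-identical reports. Multiple vendor display modes are
treated as separate reports.

## What a green test establishes — and what it does not

The generator's phantoms are geometric stand-ins, not light-transport
simulations: no Monte-Carlo photon migration, no spectral response, no
surface topography, no motion or specular artifacts, and the depth model
is a single-exponential with a stated attenuation length rather than
diffusion theory. Green recovery tests therefore establish that the
estimators are correct and well-conditioned on their stated models at
realistic noise levels — they do not certify any physical instrument.
Real-system quantities printed alongside (FWHM of a few nm, saturation
above 100 nM, reliable recovery at 4 mm depth, panel SBR above 20 dB)
are plausibility anchors used to set synthetic defaults, not reproduced
measurements.

## Known limitations

- MP4 frame extraction requires an imageio ffmpeg/pyav backend at run
  time; without one it fails with an explicit format error.
- Element ROIs come from layout files or the generator; there is no
  automatic USAF chart registration.
- Single-band spectra only; multi-peak deconvolution is out of scope.
- The dot-grid analysis quantifies spacing compression along mid-height
  rows; it does not fit a full 2-D distortion field or undistort images.
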