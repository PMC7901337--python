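# Methods

This note records the models behind `aframan`, the defaults that matter,
and the choices made where the underlying protocol leaves the design
open. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic specimen model

The phantom stands in for fresh breast excision surfaces pressed against
a waveguide slide. It models only what the analysis consumes.

**Tissue mosaics.** Labelled grids over
{background, adipose, stroma, tumour, fibrosis}, painted from geometric
primitives (rectangles, discs, annuli) on pixel centers. Background is
exactly the complement of the specimen; painting background over
previously painted tumour is rejected rather than silently carving the
lesion. Default pixel pitch is 50 µm/px, matching typical Raman sampling
step sizes for this kind of instrument. The demo layout — an adipose
field with a stroma-haloed central tumour — mirrors the common
presentation of an excision surface.

**Emission profiles (365 nm excitation).** Each class is a fixed mixture
of Gaussian components on a 1 nm grid (400–700 nm), stored in a
versioned table (`profiles.py`): adipose 475/500 nm (dominant pair) plus
550 nm (lipopigments) and 595 nm (porphyrin); stroma and tumour a single
broad NAD(P)H-like band at 460 nm (σ 38 and 37 nm — deliberately
near-identical, <1 % RMS apart after normalisation, since 365 nm-excited
emission does not separate them); fibrosis adds a 520 nm component to a
stroma-like base. Published figures give peak positions but normalised
amplitudes only, so the widths and amplitudes are calibration constants
fixed once so that the Filter1/Filter2 band-integral ratios land in the
screening bands: adipose 0.642, stroma 1.527, tumour 1.585 (all in
their 0.2–0.8 / 0.8–2 bands with comfortable margin) and fibrosis 0.934
(just below 1, so fibrosis-mode screening at 1 ≤ T < 2 excludes it).
The adipose component amplitudes (1.0/0.80 for the 475/500 pair, σ 9 nm)
were chosen so the *summed* profile's argmax stays at 475 nm on a 1 nm
grid despite component overlap; widths much above ~10 nm shift the
compound maximum off-grid toward the 500 nm component.

**AF image rendering.** Per pixel, each channel is the exact (erf
closed-form) band integral of the class profile over the filter
passband, times optional blood-transmission (0.6–1) and contact-quality
(0.7–1) fields, plus Gaussian noise of sd 2 % of the brightest
intensity, clipped at zero. Both fields multiply both channels —
channel-common to first order, which is precisely the variation the
ratio cancels (the test suite asserts invariance to 1e-9 noiselessly).
Soret-band (blood) absorption *differences* between the two channels are
not modelled: the choice of 365 nm excitation exists exactly so that the
ratio cancels blood to first order, and modelling a second-order
channel asymmetry would add a free parameter with no data to constrain
it.

**Raman spectra.** Per-class Gaussian band sums on a 1 cm⁻¹ grid
(600–1800 cm⁻¹) scaled to 1000 counts for a unit-amplitude band, plus a
random cubic baseline bounded at 30 % of the tallest band, white noise
(sd 8 counts), and with probability 0.1 a single 1–3-channel cosmic-ray
spike of 10–20× the tallest band. Band tables: adipose is
lipid-dominated (1441 strongest, 1655, 1260/1275, 1080–1095, 1301,
1745 cm⁻¹); stroma collagen-rich (860/938 ≈ 0.6 with 1004 at 0.42);
tumour phenylalanine-dominated (1004 at 0.80 over collagen at ~0.2).
A small `InstrumentModel` applies what the processing chain must undo: a
parabolic relative-intensity response (curvature 0.3) and an axis
mis-set (+2 cm⁻¹ offset by default).

What the phantom does **not** emulate: optics (evanescent-field depth,
waveguide coupling, vignetting), spatially mixed tissue within a pixel,
spectral overlap between classes at a point, H&E appearance, DCIS-scale
foci, or detector nonlinearity. Passing tests therefore demonstrate that
the *software chain* is correct and self-consistent under realistic
statistics — not that the classifier would reach any particular clinical
performance.

## Screening

The specimen mask applies an intensity threshold to the Filter 2 channel
(the brighter channel for adipose-rich specimens). The threshold is the
operator's to set; `suggest_mask_threshold` offers Otsu's value as a
starting point, but Otsu optimises between-class contrast and, when the
background area is small, can split bright adipose from dim
stroma/tumour instead of tissue from background. Unattended runs
therefore use `auto_mask_threshold`: 15 % of the 99.9th-percentile
intensity, which sits several noise standard deviations above the dark
background yet below the dimmest tissue over the phantom's blood/contact
range.

Division uses ε = 1 count on the denominator; pixels at or below ε are
removed from the mask and counted in provenance. All ratio bands are
half-open `[lo, hi)`: a pixel at exactly T = 0.8 is retained, because
over-retention only costs measurement time while screened-out tumour
would be missed. Ratios ≥ 2 are out of range and excluded. No spatial
smoothing is applied by default; a 3×3 median filter is available for
noisy inputs.

## Sampling

K = max(1, round(retained area / target segment px)), the derivation
consistent with reported segment counts emerging from specimen area and
a user segment size (1000 px for small samples, 5000–12000 px for wide
excisions). k-means runs on pixel coordinates (k-means++ with a fixed
seed, single init; ids relabelled canonically by lowest pixel index), so
segments are compact spatial tiles of roughly the requested size; an
optional `spatial+ratio` feature space appends the ratio value at 10 %
of the spatial scale. The underlying study does not state its k-means
feature space; spatial-only is this package's declared default.

Scheduling: every segment gets min_points = 3; headroom up to
⌊budget/t_acq⌋ spectra (257 at 900 s and 3.5 s) is apportioned by
largest remainder on segment areas and capped at the segment's pixel
count. If the floor alone exceeds the budget the plan is still produced
with `budget_exceeded` set and the overrun reported — the floor is never
traded away. Placement is the segment centroid (snapped into the
segment) followed by farthest-point sampling with ties broken by lowest
pixel index; this within-segment rule is this package's own choice.
Degenerate segments with fewer pixels than allocated points collapse to
the available pixels and are flagged.

## Spectral processing

Fixed order, recorded in each spectrum's provenance: cosmic-ray removal
→ response correction → wavenumber calibration → background subtraction
→ smoothing → QC.

- **Cosmic rays:** residual from a 5-channel median filter, flagged when
  it is both a robust-z outlier (z > 8 on 1.4826·MAD) and larger than
  30 % of the spectrum's dynamic range; flagged channels (±1) are
  linearly interpolated. The amplitude gate keeps sharp band curvature
  from being flagged on noiseless spectra; it assumes spikes are ≳10×
  band height, which the generator guarantees and real cosmic rays
  typically exceed.
- **Response:** multiply by certified/smoothed-measured standard
  (Savitzky–Golay 31/3; error ~1.5e-7 on the synthetic curve). The
  output is in the standard's relative-intensity units — scale-free, as
  downstream scores are ratios. The shipped certified curve is a smooth
  synthetic stand-in (so named in code); real certificates load via CSV.
- **Wavenumber:** peaks detected in a measured polystyrene spectrum
  (prominence 5 % of range, parabolic sub-channel refinement), matched
  to the ASTM E1840-convention shift table within 15 cm⁻¹, least-squares
  linear (default) or quadratic map to true shift, then resampling onto
  the canonical 600–1800 cm⁻¹ grid; residual RMS kept in metadata.
- **Background:** iterative modified polynomial (order 5): fit, clip
  spectrum to the fit, refit; stop when the baseline RMS change drops
  below 1e-4 of the spectrum scale (≤100 iterations). The iteration tail
  decays like O(1/n), so a 1e-6 relative tolerance is unreachable in 100
  iterations; at 1e-4 the fit converges in ~45 iterations with residual
  baseline drift below 0.2 counts on a 1000-count spectrum. Tighter
  tolerances remain available per call.
- **Smoothing:** Savitzky–Golay, window 9, order 3 — narrow enough to
  move well-resolved peak positions by less than one channel.
- **QC:** SNR = counts at the channel nearest 1450 cm⁻¹ divided by the
  sample standard deviation (ddof = 1) of 1370–1410 cm⁻¹; fail reasons
  `low_snr` (SNR strictly below 15.5 — a spectrum at exactly 15.5
  passes) and `high_fluorescence` (counts at 780 cm⁻¹ above 3000,
  evaluated on the *raw* spectrum, since the rule exists to reject
  saturating acquisitions and the response-corrected scale is relative).
  QC runs after smoothing by default; a flag moves the SNR check before
  it. The intensity at 1450 cm⁻¹ is a single channel, not a band
  integral — the simplest reading of the definition. Note the source
  protocol states both 3 s and 3.5 s acquisition times in different
  places; this package uses 3.5 s as the planning default.

## Classification and margin

Band height h(ν) = maximum within ±8 cm⁻¹ minus a straight line through
the window edges (clipped at zero; the 1004 reference is floored at
1e-9 of the spectrum maximum so absent bands give large, not undefined,
ratios). Rules: adipose if h(1441)/h(1004) > 2, else stroma if
(h(860)+h(938))/h(1004) > 1, else tumour. Thresholds are configurable
and were calibrated on the phantom only; noiseless class spectra score
far from both boundaries (adipose ratio ≫ 2 with no phenylalanine band;
stroma collagen score ≈ 1.3; tumour ≈ 0.24).

The margin is the minimum Euclidean distance from any tumour-labelled
point to the specimen edge, where the edge is the outermost ring of
specimen pixels (distance transform of the background-padded mask minus
one, so an edge point reports 0 mm — a positive margin), converted to mm
via the pixel size. Tumour extent is the union of segments with ≥2
tumour calls; single-call segments are flagged low-confidence instead.

## Orchestration and reproducibility

A pydantic-validated JSON config (schema version 1) carries every stage
parameter, defaulting to the protocol values (0.2/0.8/2 bands, 3 points,
3.5 s, 900 s, 3000 counts, SNR 15.5). One global seed expands to
per-stage seeds as seed + stage index; per-spectrum seeds add the point
index. `run_all` writes a manifest with the package version, stage
seeds and SHA-256 of every output; two runs with the same seed are
byte-identical, which the test suite asserts.

## Problem sizes used in tests

Test phantoms are 100–260 px on a side with segment targets of 450–5000
px and budgets of 200–900 s; population checks use 20 seeds (screening
safety, end-to-end recovery) and 100 spectra per class (band-ratio
recovery within 10 % median absolute deviation). These sizes keep the
statistical content of the checks — multi-segment plans, hundreds of
processed spectra, tumours spanning several segments — while remaining
desk-scale.

## Known limitations

The classifier is a phantom-calibrated rule set, not the clinical
model; per-point spectra are rendered from the pixel's single true
class, so class-mixture ambiguity is untested; stage-motion ordering,
autofocus, and high-wavenumber acquisition are out of scope; and the
margin is measured on the analysed (cruciate) surface only, inheriting
the sampling limitations of any single-surface assessment.
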