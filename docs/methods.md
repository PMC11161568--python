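# Methods

## The model

A helicoidal cell wall is modelled as a chiral Bragg reflector characterised
by its pitch *p* (nm, one full 360° rotation of fibril orientation), its
handedness, the number of full turns *N* in the stack, and the ordinary and
extraordinary refractive indices *n*ₒ, *n*ₑ of the wall material.  Derived
quantities: mean index *n*ₘ = (*n*ₒ + *n*ₑ)/2, birefringence Δ*n* = *n*ₑ − *n*ₒ.

At normal incidence the stack selectively reflects circularly polarized light
of its own handedness in a band

* centred at λ_c = *n*ₘ·*p*,
* spanning the chiral stop band *n*ₒ·*p* … *n*ₑ·*p*, i.e. FWHM ≈ Δ*n*·*p*,
* with saturating peak reflectance A = tanh²(*N*·π·Δ*n* / (2·*n*ₘ)), the
  standard coupled-wave result for chiral reflectors.

The amplitude law makes thin walls (*N* ≈ 5) weakly reflective (A ≈ 0.07) and
70-turn walls nearly total reflectors (A ≈ 0.997), matching the qualitative
relationship between helicoid counts and colour vividness in real epidermes.
The band *shape* is not specified by the centre rule, so the generator uses
the minimal smooth unimodal choice — a Gaussian parameterized by that centre
and FWHM on top of a flat baseline.  A full 4×4 transfer-matrix solution
(side lobes, defect modes, oblique incidence) is deliberately out of scope.

Under TEM, section banding repeats every **half**-pitch, because fibril
orientations 180° apart are indistinguishable; all microscopy quantities in
the package are therefore half-pitches, and the optical prediction is
λ/(2·*n*ₘ).  A section tilted by θ from the true transverse plane stretches
the apparent repeat by 1/cos θ; an oblique cut at angle α maps stack depth to
in-plane distance by 1/sin α and exposes the nested-arc texture.

## Defaults and parameters

| parameter | default | why |
|---|---|---|
| *n*ₘ | 1.50 | best available estimate for hydrated plant cell walls; configurable (resin- or water-saturated walls differ) |
| *n*ₒ, *n*ₑ | 1.475, 1.525 | only *n*ₘ is constrained by measurement; Δ*n* = 0.05 is a typical cell-wall birefringence, giving ~16 nm bands at *p* = 320 nm |
| panel size | 10 cells | the survey convention: ten adaxial epidermal cells per species |
| pitch CV | 0.05 | cell-to-cell pitch variability producing the ±15–30 nm peak SDs seen in per-species spectra |
| spectral grid | 350–900 nm, 1 nm | spectroradiometer-style coverage; peak *analysis* restricts to 400–800 nm |
| spectrum noise | σ = 0.005, baseline 0.02 | white-reference-normalized spectrometer noise scale |
| band image | 2 nm/px, 256×2048, contrast 0.5, σ = 0.05 | ≥ 17 band repeats in frame so the groups-of-ten protocol has material to work with |
| arc image | cut 30°, 6000 segments, 256×256 | arc repeat (*p*/2)/sin α ≈ 1.6 repeats per frame |

## Analysis choices

**Peak finding.** Centered moving average (odd window, default 5 samples),
global maximum within the analysis window, ties to the lowest wavelength.
Prominence is the peak minus the larger of the two flanking minima.  A
maximum sitting on a window boundary has zero prominence and is reported
*undefined* — the band is centred outside the window, not at the edge — as is
any peak whose prominence stays below a configurable floor (default 0.01
reflectance units in the full per-cell analysis).  Undefined cells are
excluded from panel summaries rather than contributing a boundary artefact.
Panel statistics use the sample SD (n−1); whether the survey's printed ±
figures are SD or SE is not stated anywhere, so the more conservative sample
SD is used.

**Analysis window.** Real surveys report visible peaks, so the default window
is 400–800 nm and near-UV peaks are flagged, not analyzed.  Recovery studies
on synthetic panels analyze over the full simulated instrument window
(350–900 nm): at *p* = 280 nm the per-cell band centre (420 ± 21 nm)
straddles the 400 nm edge, and truncating there would bias the panel mean
upward by construction rather than measure the estimator.

**Selectivity.** Channel means over a ±10 nm window at the peak; ratio
dominant/other (ε-floored), DOCP = (L−R)/(L+R).  A cell is *selective* when
the ratio ≥ 2 and the dominant channel's relative prominence ≥ 0.05 — both
configurable; the underlying field criterion is qualitative, so these are
explicit conventions.

**Colour bins.** Half-open intervals violet [400,450), blue [450,500), green
[500,570), long [570,800]; the boundary 450 nm goes to the upper bin since
published range definitions print it in both violet and blue.

**Band-period estimation.** Profiles are extracted along the band normal
(structure-tensor mean orientation with image pre-smoothing; a coherence
< 0.2 raises an isotropy error and a manual orientation override is always
accepted; rotations within 0.5° of 0°/90° skip interpolation).  The profile
is detrended by a moving-average baseline of ~3 periods, autocorrelated with
**unbiased** lag normalization (the raw triangular taper biases short-profile
estimates low), and the first peak refined by a three-point parabola.  The
dominant zero-padded-FFT frequency serves as a cross-check; >10 %
disagreement flags the estimate ambiguous.  The groups-of-ten protocol
locates successive same-sense extrema (sub-sample refined), spans ten
consecutive half-pitch intervals per measurement, and reports mean ± sample
SD across disjoint groups — mirroring the bench practice of measuring ten
half-helicoids at once to suppress local lattice variation.

**Arc score.** The image is cut into 8 px horizontal strips; each strip's
doubled-angle orientation phasor (structure tensor, coherence-weighted) forms
a sequence along the section axis.  For true arcs that sequence is a single
complex exponential (orientation rotates uniformly, wrapping each half-pitch),
so the score is the peak FFT magnitude of the mean-subtracted sequence per
strip, zero-padded ×8 to avoid scalloping loss.  Straight banding (constant
orientation) and unstructured noise (incoherent strips) score near 0; the
generator's arc images score ≈ 0.73.  A constant image raises a degeneracy
error.

**Agreement rule.** The survey literature says predicted and observed
half-pitches "correlate well" without quantifying it; the package's explicit
stand-in is |pred − obs| ≤ max(√(sd_pred² + sd_obs²), 0.08·pred).  The 8 %
relative floor admits every published row (loosest: predicted 150 vs observed
158 nm) while rejecting gross mismatches; it is configurable and flagged as a
convention in rendered tables.

**Display rounding.** Half-to-even to integer nm.  This reproduces 18/20
published predicted half-pitches exactly; the two off-by-one rows (536→178,
458→152) and two SD cells (17/3→5, 40/3→14) are not reproducible from the
printed inputs under any standard rounding and were presumably computed from
unrounded means — the discrepancy is reported, not forced.

**Verdict.** Step 1 requires a majority of defined cells selective (gating
proxy: single-handedness CP reflection); handedness is the dominant channel.
`confirmed` requires all four steps affirmatively true; any affirmative
failure gives `not_supported`; missing evidence caps the verdict at
`partial`.  The verdict is monotone: downgrading a step never upgrades the
outcome.

## What the generators do and do not emulate

Emulated: handedness-exclusive reflection bands centred at *n*ₘ·*p* with
per-cell pitch variability; saturating band amplitude with turn count;
half-pitch lamellar banding with section-tilt stretch; nested-arc textures
whose concavity mirrors with handedness; seeded, bit-reproducible panels.

Not emulated: stop-band side lobes and defect modes; stain gradients,
knife chatter and other TEM artefacts; curved cell surfaces and non-planar
lamellae; wavelength dependence of *n*; hydration-state changes; absorbing
pigments beneath the epidermis.  Passing round-trip tests therefore
demonstrates the estimators' correctness on idealized lamellar/chiral
geometry, not robustness to every preparation artefact of real micrographs.

## Problem sizes and determinism

Synthetic studies use ten-cell panels, 256×2048 px band images and 256×256 px
arc images; the acceptance script's stochastic checks use three panels
(pitch 280/320/360 nm), 20 arc/band/noise replicates and 50 estimator-oracle
draws.  All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); per-cell seeds are the master seed plus stable
offsets, so every panel regenerates bit-identically.

## Known limitations

* The Gaussian band shape and the coupled-wave amplitude are modelling
  conventions — only the band centre rule is empirically anchored.
* Absolute reflectance of published spectra is not recoverable (their
  normalization is undefined), so only wavelengths, not amplitudes, are
  compared to printed values.
* The obliquity of real "oblique" sections is rarely recorded; measured
  half-pitches from near-transverse sections assume tilt ≈ 0, and any
  uncorrected tilt biases the observed half-pitch upward.
* `arc_score` assumes the section axis is the image y-axis (as produced by
  the generator); arbitrary arc orientations would need a pre-rotation step.
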