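# Methods

This note records the models, numerical choices and their rationale, in
the order the analysis runs.

## Spectrum model and the synthetic phantom

A spectrum is intensity on a strictly increasing Raman-shift grid;
the generator uses 400–3300 cm⁻¹ in 2 cm⁻¹ steps, matching a dispersive
785 nm serum acquisition.  A synthetic acquisition is

```
I(w) = gain · [ baseline(w) + Σ markers(w) + Σ subbands(w) ] + ε(w)
```

* **baseline** — cubic polynomial in the normalized coordinate
  `(w−400)/2900`, default coefficients (0.2, 0.5, −0.3, 0.1): a smooth
  drift of ~0.5 relative units across the range, the kind of slowly
  varying background a spline corrector must remove.  The instrument
  baseline of real spectrometers is not characterized here; any smooth
  drift exercises the corrector equally.
* **markers** — Gaussian landmark peaks at the standard serum positions
  (~520 disulfide, ~760 tryptophan, ~830/850 tyrosine, 1003
  phenylalanine, ~1300 amide III, ~1450 CH₂ scissoring, ~1550 amide II,
  ~1650 amide I cm⁻¹), heights relative to phenylalanine = 1.  Only the
  C–H band is quantitatively analyzed, so landmark realism beyond
  position/rough height is unnecessary; Gaussian shapes suffice.
* **sub-bands** — nine Voigt components at 2858, 2877, 2897, 2912, 2924,
  2940, 2960, 2977, 2984 cm⁻¹ with class labels CH₂/CH₃/other.
  Bandwidths sit around the nominal 10 cm⁻¹ (8.2–11.9).  Template areas
  were fixed once such that (a) the base CH₃:CH₂ area-sum ratio is ≈3.3,
  the middle of the physiological range, and (b) every sub-band —
  including the 7 cm⁻¹-spaced 2977/2984 pair — produces a resolvable
  second-derivative minimum for planted ratios across 2.5–4.2.  This
  mirrors the empirical fact the method depends on: all nine components
  are identifiable from curvature analysis of real serum spectra.  A
  template whose sub-bands were not individually resolvable would make
  the second-derivative initialization, and hence the whole procedure,
  inapplicable by construction.
* **planting** — `plant_highwave_band` rescales the four CH₃ areas by a
  common factor so the CH₃/CH₂ area-sum ratio equals the requested value
  exactly; CH₂ and other areas, all centers and all widths are untouched.
* **gain** — one log-normal factor per acquisition (default σ = 0.05),
  modelling laser-power fluctuation; the phenylalanine normalization must
  cancel it exactly, and the area ratio is invariant to it by
  construction.
* **noise** — additive i.i.d. Gaussian, default σ = 5·10⁻⁴ in
  phenylalanine-normalized units (≈0.01 % of the C–H band maximum).
  This represents the very high signal-to-noise of long-integration,
  multi-accumulation serum acquisitions (30 s × 16 accumulations).  The
  level matters: the nine-component free-width fit is ill-conditioned
  (see below), so the generator's default deliberately sits in the
  high-SNR regime the method is designed for.

Cohorts draw one ratio per patient from N(mean, ar_sd) truncated at 0 —
group means default to 3.17 (treated) and 3.42 (non-treated).  No
within-group spread is published for real patients; the default
ar_sd = 0.086 is set so that the *planted* group separation has
theoretical AUC ≈ 0.98, i.e. the cohort-level surrogate study is run at
the discrimination level the statistic is claimed to achieve.  Replicates
(default 3) share the patient's planted band and differ only in gain and
noise.  Ground truth travels in spectrum metadata and a JSON sidecar,
never inside the two-column data files.

What the phantom does **not** emulate: shot noise and detector response,
cosmic-ray spikes, fluorescence photobleaching, instrument-to-instrument
wavenumber offsets, and any biological covariation between the marker
region and the C–H band.  Passing tests therefore demonstrate correctness
of the algorithmic chain under the stated acquisition model, not clinical
performance on real serum.

## Preprocessing

Order is fixed: per-acquisition baseline correction → per-acquisition
phenylalanine normalization → replicate (patient) average → group
average.  Normalizing each acquisition before averaging is what cancels
per-acquisition gain.

* **Baseline**: within each of 12 configurable anchor windows the
  minimum-intensity point is taken as a baseline sample; a cubic spline
  (interpolating by default, `smoothing` > 0 smooths) through the samples
  is subtracted.  Anchor windows sit in peak-free regions and keep
  ≥150 cm⁻¹ clearance from the C–H band edges, because the band's
  Lorentzian tails would otherwise contaminate the anchors.  An
  interpolating cubic spline reproduces a cubic drift exactly, which the
  tests exploit.
* **Normalization**: division by the maximum intensity inside
  995–1010 cm⁻¹ (peak height, not area — the common reading of "peak
  normalization").  A nonpositive window maximum raises: it signals a
  failed baseline or an absent reference peak.
* Spectra on different grids are linearly resampled before averaging.

## Second-derivative center detection

The second derivative of the region is estimated with a Savitzky–Golay
smoothing differentiator; minima with prominence above 5 % of the
maximum absolute second derivative are the candidate centers.  Defaults:
window 11 points (22 cm⁻¹ at the 2 cm⁻¹ grid), polynomial order 7.
The order matters: an order-3 filter of that window attenuates 10 cm⁻¹
features so strongly that the 2977/2984 pair merges into one minimum for
*any* template areas — verified numerically — leaving at most eight
candidates.  Order 7 preserves the pair while retaining enough smoothing
for the high-SNR data the generator emulates.  At substantially higher
noise the filter admits spurious minima; the fit then proceeds with the
detected count and a warning, and the class-assignment distance limit
(below) keeps far-off spurious components out of the ratio.

## Voigt band fit

The region (default 2800–3020 cm⁻¹) is modeled as a sum of Voigt
profiles, one per candidate center, plus one free constant offset.
`scipy.special.voigt_profile` supplies the kernel; the area parameter is
the full-line integral of each component.

* Initialization: centers at the detected minima; total FWHM 10 cm⁻¹
  split evenly between the Gaussian and Lorentzian parts (the nominal
  bandwidth is stated without specifying which width it parameterizes;
  the even split is symmetric and is refined away by the fit); area from
  the local intensity.
* Bounds: center within ±5 cm⁻¹ of initialization (centers are detected,
  not free — the refinement bound keeps components from wandering onto a
  neighbour); σ ∈ [0.2, 12.7], γ ∈ [0, 15] cm⁻¹ (≈ total FWHM between
  0.5 and 30 cm⁻¹); areas ≥ 0.
* Optimizer: trust-region reflective least squares, cost tolerance
  10⁻¹⁰, no random restarts — deterministic for fixed inputs.
* **Local offset**: the global spline is anchored ≥150 cm⁻¹ away from
  the band and cannot observe the level beneath it; the band's own tails
  leak ~10⁻³ normalized units into even distant anchors.  Without the
  offset the planted-truth recovery of the ratio is biased by ≈ −0.02;
  with it the noise-free bias is < 0.002.  Options: `none`, `constant`
  (default), `linear`.

**Conditioning.**  With free widths the nine heavily overlapped
components make the least-squares problem ill-conditioned: neighbouring
components of different classes can trade area along near-degenerate
directions, so the ratio error grows steeply (roughly linearly) with
noise — ≈0.03 at the default noise, but tens of percent already at noise
of ~0.5 % of the band maximum.  This is a property of the model class,
not of the optimizer; it is why the generator's default noise represents
the high-SNR acquisitions the method requires, and why the
noise-degradation property test sweeps only that regime.

## Class assignment and the area ratio

Each fitted component takes the class of the nearest reference center
(ties toward the lower center); components farther than 8 cm⁻¹ from
every reference are left unassigned.  The ratio is
Σ areas(CH₃) / Σ areas(CH₂); the 2912 cm⁻¹ generic C–H component and
unassigned components enter neither sum (a config toggle can fold the
"other" class into the denominator for sensitivity analysis).  The ratio
is computed on the patient-averaged spectrum; averaging per-replicate
ratios instead is available as a toggle.

## Classification statistics

* **AUC**: pair counting, (concordant + ½·ties)/(n₊·n₋), positive class
  = non-treated (higher ratios).  This orientation is what the printed
  operating point implies (sensitivity 10/11 with the 11-patient group
  positive); it is a config flag.
* **Cut-off**: candidate thresholds are midpoints between adjacent
  distinct pooled values (plus one sentinel beyond each extreme);
  classify positive when value > threshold; the Youden index
  J = sens + spec − 1 is maximized, ties broken toward the smallest
  threshold using a 10⁻¹² tolerance so that mathematically equal count
  ratios are not split by float rounding.
* **Proportion intervals**: exact Clopper–Pearson via beta quantiles.
* **AUC interval**: Hanley–McNeil standard error, clipped to [0, 1];
  degenerate AUCs (0 or 1) warn and return the clipped interval.
* **Group summaries**: quartiles by linear interpolation, whiskers at
  1.5 IQR, points outside flagged as outliers.

## Problem sizes used in the validation suite

Noise-free single-phantom recoveries use 3 replicates on the full
1451-point grid; the cohort-level surrogate study uses 20 cohorts of
8 + 11 patients × 3 replicates at the default noise and spread, comparing
the median recovered AUC against the median planted AUC.  Randomized
oracle equivalences (pair-counting AUC, Youden sweep) run on 200 small
instances; the Clopper–Pearson coverage check uses 2000 binomial draws at
n = 11, p = 0.8.

## Known limitations

* The deconvolution's area estimates degrade quickly with noise (see
  Conditioning); applying the pipeline to low-SNR spectra requires more
  accumulations, not looser fit bounds.
* The spline baseline assumes the anchor windows are truly peak-free; on
  real spectra with unexpected bands inside an anchor window the window
  list must be adapted.
* JCAMP-DX support covers the plain fixed-point `XYDATA=(X++(Y..Y))`
  dialect only (no SQZ/DIF/DUP compression).
* Sensitivity/specificity confidence intervals are computed at the
  selected cut-off without correcting for the cut-off itself being
  data-driven; with n = 19 this optimism is substantial, as the wide
  exact intervals make visible.
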