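# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `dyncouple`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Analysis model

**Window scheme.** The sliding window is defined by its length L (default
60 epochs = 108 s at TR = 1.8 s), step (1 epoch) and a Gaussian taper
`w[i] = exp(−(i − c)² / 2σ²)` with `c = (L−1)/2` and
`σ = FWHM / (2√(2 ln 2))`, FWHM = 27.78 epochs. The number of windows is
`⌊(N − L)/step⌋ + 1` (247 for N = 306), the overlap `(L − step)·TR`
(106.2 s). For even L the continuous taper peak (value 1) falls between
samples; the discrete maximum is `exp(−1/(8σ²))` ≈ 0.9991. The 108 s
window corresponds to a frequency threshold of 1/108 s ≈ 0.009 Hz,
conventionally quoted as 0.01 Hz; this equivalence is reported here but
not asserted numerically anywhere.

**Windowed FC.** The taper enters as observation weights inside each
window's Pearson correlation rather than by premultiplying the signal;
this keeps r correctly normalised and reduces the influence of window
edges. Plain (unweighted) windowed correlation is available
(`weighted=False`) because the field uses both conventions. Degenerate
(zero-variance) windows become missing values, are logged, and propagate
into the coupling correlation by pairwise deletion; more than 5% missing
windows for a pair is an error.

**Band power.** Per epoch and channel the PSD is the mean of K = 3 DPSS
eigenspectra with time–bandwidth product NW = 2 (the standard K = 2NW − 1
pairing; only the taper count is fixed by convention, NW is a documented
choice). Epochs are mean-centered before tapering; no further detrending
is applied within 1.8 s epochs. Band membership is inclusive at both band
edges. Band power is the mean PSD over the band's bins divided by the mean
over the 1–40 Hz bins, making it dimensionless and invariant to rescaling
the recording. Power is pooled (arithmetic mean) over P4, P6, P8, PO4,
PO8, O2 and then window-aligned by taper-weighted averaging over exactly
the FC window grid — a window-restricted weighted average, not a
full-length convolution, so both series live on identical window centers.
Deliberately, no hemodynamic-response convolution is applied to the power
series; instead the coupling is evaluated at fMRI-later lags of 0–5 TR
(0–9 s).

**Coupling and lag convention.** Coupling is the ordinary Pearson
correlation across windows (the taper's job ends at series construction),
Fisher-Z transformed. A positive lag k pairs `power[t]` with `fc[t + k]`,
i.e. shifts the fMRI series later relative to the EEG, reflecting
hemodynamic sluggishness; negative lags are rejected. |r| = 1 raises
rather than returning ±∞ (it occurs only in synthetic edge cases). Fewer
than 10 overlapping windows after the lag is an error.

**Group statistics.** Δz = z_post − z_pre per subject; the double contrast
is a pooled-variance two-sample t (active − sham). When a Levene check
rejects variance homogeneity at 0.05 the Welch statistic is substituted
and flagged. The FDR family is the 10 within-DMN pairs for one band and
lag (not pooled across bands or lags). Follow-up one-sample t tests are
one-tailed with the direction read from each group's mean Δz (recorded in
the output as data-driven), run only for FDR survivors, and deliberately
uncorrected — they are protected by the significant double contrast.
Shapiro–Wilk and Levene checks are reported as diagnostics and never block
the analysis. The control analysis subtracts the mean coupling over the 35
DMN × (ECN ∪ SN) pairs from each within-DMN coupling on the z scale.

**BOLD cleanup.** Order center → bandpass → regress (configurable,
logged). "Whitening" is implemented as per-ROI variance normalisation,
not temporal prewhitening — the narrower reading of an ambiguous phrase,
documented and configurable. The bandpass is a zero-phase (forward–
backward) order-4 Butterworth, a common resting-state default; passband
amplitude is preserved within 5% and stopband sinusoids attenuated ≥ 80%
(verified by a least-squares sinusoid-fit oracle). The Friston-24 set is
`[m(t), m(t−1), m(t)², m(t−1)²]` with the lagged blocks zero-filled at
t = 0. With no confound table the regression stage is a pass-through, so
the stage order is exercised but neutral on synthetic data.

## Synthetic study generator

The generator is the package's test bed: it realises exactly the
statistical structure the analysis is designed to detect, with ground
truth recorded per session.

- **Latent state.** White noise band-limited on the run's own DFT grid to
  frequencies strictly below 0.02 Hz, then standardised. Brick-wall
  synthesis (rather than an analog-style filter) is used because the
  finite-window periodogram of a 306-sample series otherwise leaks more
  than 10% of its power above the cutoff on unlucky seeds; with the
  brick-wall construction the in-band fraction is 1 by construction.
- **BOLD.** Per TR, the 12-ROI sample is `L(t)·ε` with `L(t)` the Cholesky
  factor of the instantaneous correlation matrix: base correlation 0.3
  everywhere, ρ(t) = 0.3 + m·β·s(t) on the target pairs (clipped to
  ±0.99, counted and logged). When simultaneous large modulations on the
  two vPCC pairs make the matrix indefinite, the offending TRs are
  repaired by eigenvalue clipping with the diagonal restored (counted in
  the ground truth). The series is then band-limited to 0.01–0.08 Hz.
- **EEG.** 450 samples per epoch at 250 Hz. Occipitoparietal channels
  carry a 10 Hz sinusoid of amplitude a0·max(1 + γ·s(t), 0.05) with fresh
  random phase per epoch (flooring is logged), plus theta (6 Hz) and low
  beta (15 Hz) sinusoids whose amplitudes follow their own slow latent
  envelopes (gain 0.5), independent of s and shared across channels. All
  channels add independent 1/f background noise, synthesised per epoch in
  the frequency domain, band-limited to 0.5–45 Hz (the filter band of
  cleaned EEG; the 1.8 s epoch grid cannot represent anything below its
  ~0.56 Hz first bin anyway) with exact target sd. One
  non-occipitoparietal distractor channel (Cz)
  carries unmodulated alpha. EEG is synthesised and analysed in single
  precision — more than recording precision — which keeps the
  replicate-study suites fast; all BOLD and statistics paths are double
  precision.
- **Why the neighbouring rhythms exist.** Without them, the only coherent
  signal in theta/beta normalised power would be the (inverted) leak of
  the alpha modulation through the 1–40 Hz normalisation; window smoothing
  suppresses the iid estimation noise but not that coherent leak, so the
  generator would show spurious theta/beta stimulation effects that the
  emulated study design does not have. The alpha amplitude (a0 = 0.25,
  ≈ a few percent of global mean power) and the independently fluctuating
  theta/beta rhythms keep the leak far below the bands' own slow variance
  while alpha power still tracks s at r ≈ 0.77 per epoch.
- **Effect sizes.** β = 0.3 and γ = 0.5 with session multipliers
  (active-pre 0, active-post +1, sham-pre 0, sham-post −0.3) were chosen
  once, at design time, so that a default 16 + 16 study produces
  target-pair double contrasts on the order of t ≈ 3 — the scale of a
  real finding of this kind — with the sham group drifting slightly
  negative. Per-subject active-post coupling is then r ≈ 0.4 (sd ≈ 0.3).
- **Seeding.** One master seed per study; child seeds for each
  subject-session's latent, BOLD and EEG streams are drawn from the master
  generator in a fixed order, so studies are bit-reproducible.

## What the simulations do and do not show

The generator reproduces the *statistical* structure: a latent slow state
that simultaneously modulates connectivity and alpha amplitude, a
group × session effect on that coupling, spontaneous band-power
fluctuations, and band-limited BOLD. It does not model hemodynamic
response functions, scanner or gradient/ballistocardiogram artifacts,
head motion (the confound path is exercised with synthetic tables only),
epoch-boundary seams between concatenated scan blocks, or realistic
electrode topography. Passing tests therefore demonstrate that the
pipeline recovers the intended effect under its own assumptions — not
that those assumptions hold in any particular real recording.

## Statistical verification (computed by the suite)

- **Null calibration.** Over 500 zero-effect studies (16 + 16 subjects,
  306 epochs, full pipeline per study), the raw double-contrast rejection
  rate at α = 0.05 must lie in the 95% binomial band [0.031, 0.069]. The
  smoothed series make each subject's coupling r wide-null (Bartlett sd
  ≈ 0.35, verified against the closed form), but Δz remains iid across
  subjects, so the t test stays calibrated.
- **Recovery and specificity.** With the default effect, both target pairs
  survive BH-FDR in a majority of 100 replicate studies; follow-up
  directions match the injected signs in the majority; every non-target
  pair and every theta/beta pair survives in fewer than 20% of studies.
  The mean recovered coupling increases monotonically over a
  β ∈ {0.15, 0.3, 0.45} grid.
- **Oracles.** Weighted Pearson with uniform weights agrees with plain
  Pearson to 1e−12 over 1,000 random instances; BH-FDR agrees with a
  brute-force step-up to 1e−12 over 1,000 random p-vectors; the multitaper
  peak for pure tones agrees with an FFT periodogram within the NW/T
  bandwidth; GLM residuals are orthogonal to the design to 1e−8 relative.

## Problem sizes

Replicate counts used by the suite — 500 studies for calibration, 100 for
recovery, 100 subjects per grid level — were chosen as the smallest sizes
at which the binomial/Monte-Carlo bands above are meaningful; the
acceptance script reports a 150-study calibration and a 40-subject grid as
its standing summary.

## Known limitations

- The "whitening" reading (variance normalisation) and the
  bandpass-before-regression order are conventions; both are configurable
  and logged, and results on synthetic data are insensitive to the order
  because the confound path is neutral there.
- The adjusted (extra-DMN-subtracted) coupling is computed on the z scale
  only; its `r` column is reported as missing.
- The provenance record contains the full config, seeds and warnings but
  deliberately no wall-clock timestamps, so identical runs produce
  byte-identical artifacts.
- Fisher Z of |r| = 1 raises; callers on synthetic degenerate inputs must
  handle the error.
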