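# Methods

`nvcwave` quantifies neurovascular coupling (NVC) in long neonatal
monitoring sessions from two simultaneously recorded signals: scalp EEG
(256 Hz, microvolts, typically the cross-cerebral C3−C4 derivation) and
NIRS-based cerebral tissue oxygen saturation SctO₂ (percent, one sample per
4.78125 s ≈ 0.209 Hz). The analysis chain is

1. raw EEG → amplitude-integrated EEG (aEEG) margin traces, by more than one
   algorithm;
2. aEEG bandwidth (upper minus lower margin) vs SctO₂ → wavelet transform
   coherence (WTC) in the 640–10240 s scale band;
3. count of statistically significant coherence pixels (`Pix_total`) per
   algorithm, and agreement statistics across algorithms.

The scientific question the design serves: aEEG algorithms differ between
devices and publications, and their tracings visibly disagree; is the
WTC-based NVC metric robust to that choice?

## aEEG transforms

All in-package paths share a preprocessing chain:

* **Asymmetric band-pass filter.** A linear-phase FIR whose desired
  magnitude rises at 12 dB/decade across 2–15 Hz (unit gain at 2 Hz) and is
  attenuated outside, emulating the analog front end of cerebral function
  monitors (the rising response compensates scalp/skull attenuation of
  faster rhythms). The taps come from a weighted least-squares fit
  (`scipy.signal.firls`, 401 taps at 256 Hz, 0.5 Hz transitions) to the
  power-law target sampled on 24 log-spaced sub-bands. An equiripple
  (Parks–McClellan) realization was evaluated first but `remez` develops
  deep in-band notches on stepped-slope multiband specifications; the
  least-squares design tracks the slope to within ±1.6 dB, achieves > 30 dB
  attenuation at 0.5 Hz, and is exactly linear-phase by symmetry. Achieved
  in-band ripple above 3 dB raises a design error rather than silently
  degrading.
* **Full-wave rectification**, then **envelope detection** with a 5th-order
  Butterworth low-pass applied forward–backward (zero phase), clipped at
  zero. The cutoff is not a standardized constant; the default is 1 Hz —
  far above the 0.1–1.6 mHz coupling band, low enough to remove
  rectification ripple — and is configurable.
* **Gain**: 2.0 for M1, 1.631 for M2 (the latter applied verbatim from the
  algorithm it reproduces; its provenance is not documented there).

Segmentation then differs:

* **M1**: 90th/10th percentiles (UTP/LTP) of the envelope over overlapping
  15-s windows (3840 samples) stepped by 4.78125 s (1224 samples; overlap
  10.21875 s), followed by a margin smoother. The "curve drawn through"
  the terminal points is not operationally defined in the source
  algorithms; the default is a centered 3-point moving average, with a
  cubic-spline alternative behind the `smoother` switch (recorded in output
  metadata).
* **M2**: the same percentiles over contiguous non-overlapping 1224-sample
  epochs, then a centered 3-point moving average (≈ 15 s of effective
  support). The toolbox M2 reproduces natively uses 3.12-s terminal points
  averaged 5-at-a-time (15.6 s); the 4.78125-s re-segmentation keeps all
  methods on the SctO₂ clock. Note 3 × 4.78125 s = 14.34 s, so "three
  epochs per 15 s" is approximate by construction; the implementation uses
  contiguous epochs over the whole record, which is what yields exactly one
  margin sample per 1224 raw samples.
* **M3**: devices export their own 256 Hz aEEG with undisclosed conversion
  steps; that conversion is *not* reimplemented. The M3 path applies the M1
  segmentation/margin steps to the supplied amplitude series. On synthetic
  subjects, a stand-in "device" trace (band-pass, rectification, a
  deliberately different order-2/0.5 Hz envelope and gain 1.8;
  `synthetic_device_aeeg`) exercises this path with realistic
  between-method heterogeneity.

Step and window sizes are fixed in integer samples: 1224 samples = 4.78125 s
gives a margin rate of 256/1224 = 0.20915 Hz (reported rounded as
0.209 Hz); a non-integer stride would drift against the SctO₂ clock by
about one sample per 20 h. Percentiles use the linear-interpolation
convention between order statistics. All stages are positively homogeneous,
so scaling the raw EEG by k scales margins and bandwidth by exactly k.

Display uses the conventional semi-log aEEG coordinate: identity on
0–10 µV, `10·(1 + log10(v/10))` above (10 µV → 10, 100 µV → 20).

## Wavelet coherence

The bandwidth series UMA − LMA and SctO₂ are mean-removed,
variance-normalized, and transformed with the analytic Morlet wavelet
(ω₀ = 6, Fourier factor ≈ 1.033), computed in the frequency domain with
zero padding to the next power of two. Squared coherence follows the
standard smoothed-spectra construction

    R²(s,t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with time smoothing by a Gaussian of SD = s/√2 (the width of the Morlet
energy envelope at scale s) and scale smoothing by a renormalized boxcar of
0.6 octave (7 bins at 12 voices/octave). R² is clipped to [0, 1]; zero
denominators yield 0.

The scale grid is logarithmic at 12 voices/octave covering 640–10240 s
(0.1–1.6 mHz by plain reciprocal, which is how the band is labeled
throughout). Scales longer than duration/(2√2) are dropped with a warning:
their cone of influence would cover the whole record. The cone of influence
(COI) marks points within √2·s of either edge; pixels inside it are never
counted.

**Significance.** Per-scale pointwise thresholds come from Monte-Carlo
surrogates: `n_surrogates` (default 300) independent AR(1) pairs whose
lag-1 coefficients are fitted to the two input series are pushed through the
identical coherence construction, and the (1 − α) quantile (α = 0.05) of
their outside-COI R² values per scale is the threshold. AR(1) is the
standard red-noise null for wavelet coherence. No areawise or
multiple-testing correction is applied — the statistic of interest is the
count of pointwise-significant pixels. Two numerical choices keep the
Monte-Carlo pass tractable without changing its distribution: surrogate
coherence is computed in single precision, and the smoothed null field is
subsampled every 16 samples (~76 s) before pooling — the field decorrelates
over ~one scale (≥ 640 s), so the pooled marginal distribution and hence the
quantile are unaffected. Calibration is verified empirically: on uncoupled
AR(1) pairs the outside-COI significant fraction averages α within
Monte-Carlo error (acceptance suite).

**Summary statistics.** `Pix_total` counts significant outside-COI pixels,
where a pixel is one (time sample × scale bin) cell of the shared 0.209 Hz ×
12-voice grid — the API forces all methods of one analysis onto the same
grid, since the count is grid-dependent. The cross-method COV is the sample
(n−1) SD of the methods' `Pix_total` values divided by their mean, × 100;
a zero mean returns an explicit no-coherence marker rather than a number.
(The alternative reading — per-scale SDs averaged across scales — collapses
to the same ordering on these data and is not implemented.)

## Synthetic recordings

The generator (`synthetic` module) is first-class, tested code — it defines
the study conditions every statistical guarantee is measured under.

* **EEG**: a broadband carrier — unit Gaussian noise ("continuous"
  background) or a burst-suppression process (seeded renewal bursts, default
  6/min × 2 s, suppression ratio 0.15, 0.25-s cosine ramps) — multiplied by
  `envelope_base_uV · (1 + mod_depth·m(t))` plus white sensor noise. m(t)
  is a sum of unit sinusoids at the configured coupling periods (each
  required to lie within [2/scto2_rate, duration/4] so the wavelet analysis
  can resolve it), normalized to [−1, 1], with seeded random phases.
  Defaults: 25 µV base, modulation depth 0.5, 2 µV sensor noise — set for
  plausible display on the conventional 0–100 µV semi-log axis, not fitted
  to any patient data.
* **SctO₂**: mean 75 % plus a 3 %-amplitude slow oscillation plus
  independent AR(1) measurement noise (α = 0.8, SD 1.5 %), clipped to
  [0, 100] with clipped samples counted. The slow oscillation is a
  constant-power mix of the shared modulation m(t) (weight =
  `coupling_strength`, optionally lagged; default lag 0 s since coherence
  magnitude at fixed scale is phase-insensitive) and an independent
  *vasomotion* component at the same periods (weight = 1 −
  `coupling_strength`): a carrier whose complex amplitude drifts as an
  AR(1) with correlation time P/2, i.e. spectrally centred where the
  coupling lives but phase-incoherent with it over the wavelet smoothing
  support. This mix is what makes `coupling_strength` a genuine coherence
  dial — a fixed-phase sinusoid added to broadband noise is near-fully
  coherent with the EEG envelope at any nonzero weight, whereas the
  measured band R² here rises from the ~0.59 incoherent baseline through
  ≈ 0.82 at strength 0.5 to ≥ 0.99 at strength 0.8, so a cohort spanning
  strengths 0.1–1.0 spans weak-to-strong NVC the way a clinical cohort
  does. SctO₂ is generated directly at 256/1224 Hz — the margin clock, and
  the rate the NIRS device class nominally reports as 0.209 Hz — rather
  than decimated from a faster signal.
* Identical configs are bit-identical (a master seed spawns named
  sub-streams for phases, carrier, sensor noise, SctO₂ noise).

What the generator does *not* emulate: physiological hemodynamic transfer
(no forward model, no frequency-dependent phase lag), seizures, artifacts,
electrode pops, multichannel montages, or nonstationary coupling strength.
Passing tests therefore demonstrate correctness and calibration of the
*analysis*, and robustness of the NVC metric to the aEEG algorithm under
controlled coupling — not clinical validity on patient recordings.

## Problem sizes and numerical choices

The acceptance suite runs 10-hour subjects (36000 s → 7529 margin samples;
the full 640–10240 s band is resolvable since 10240 < 36000/(2√2)) and a
type-I calibration at n = 15000 samples (≈ 20 h at the margin rate) with
300 surrogates and 20 replicates. The acceptance script uses 10 calibration
replicates at n = 10000 and a 6-subject cohort; these sizes are the
package's reference configuration for a desk-scale reproduction.
Seeds are fixed in the tests and derived from `--seed` in the script.

Known limitations: thresholds are pointwise, so `Pix_total` under the null
is ~5 % of the countable grid rather than zero; margin t₀ differs between
M1 (window center 7.5 s) and M2 (2.39 s), an offset of less than one margin
sample that is ignored when aligning with SctO₂; EDF export is not
implemented (CSV is the interchange format; EDF is read via the optional
`mne` dependency); and the M3 path depends entirely on the quality of the
supplied device trace.
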