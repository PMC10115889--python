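# Methods

## The analysis

`specevents` implements a transient spectral-event analysis of resting-state
EEG together with the clinical-correlation statistics built on top of it.
The underlying model of brain rhythms is that band-limited activity —
delta/theta (1–6 Hz), alpha (7–14 Hz), beta (15–29 Hz) — is not a stationary
oscillation but a sequence of brief high-power *events* visible in the
unaveraged time–frequency plane.  The analysis therefore quantifies, per
patient, session, electrode and band of interest (BOI), four event features:
events per 2-s epoch (*number*), normalized power at the event maximum
(*power*), FWHM duration (*duration*), and FWHM frequency span (*span*), and
then asks whether pre- to post-treatment changes in those features (or their
pre-treatment levels) correlate with changes in depression (IDS-SR) and PTSD
(PCL-5) symptom scores across a treated cohort.

Pipeline, in execution order:

1. **Epoching.** Continuous recordings (8 electrodes, 500 Hz) are cut into
   non-overlapping 2-s epochs; trailing partial epochs are dropped.  Sample
   indexing is 0-based and half-open.
2. **Artifact screening.** An epoch is rejected when on any channel its peak
   absolute amplitude exceeds 8× the median across epochs of that channel's
   per-epoch RMS.  This amplitude-ratio rule is an automated, reproducible
   stand-in for manual artifact inspection; it is blind to clinical outcome
   by construction.  The factor 8 sits well above the ~5×RMS peaks that
   clean 1/f noise reaches in 2 s and well below movement/drift transients
   (20×RMS in the generator's artifact model); it is configurable.
3. **Inclusion.** A patient enters the analysis only if both sessions retain
   at least sixty clean 2-s epochs (>120 s of usable data) on all channels
   and the clinical record is complete.
4. **Epoch-count matching.** The larger session is subsampled uniformly
   without replacement down to the smaller session's count, with a seeded
   generator, so event *number* is compared on equal footing.
5. **Time–frequency responses.** Each epoch is convolved with 7-cycle
   complex Morlet wavelets on a 1–45 Hz grid (1 Hz spacing).  Kernels are
   unit-energy (Σ|w|²·dt = 1), truncated at ±4 temporal SDs; convolution is
   same-length with zero padding, so edge timepoints are retained.  Power is
   the squared magnitude.
6. **PSD and band power.** The PSD is the raw TFR averaged over time and
   over all epochs of both sessions; band power is the arithmetic mean over
   the band's grid rows (inclusive).  Band power feeds a two-way
   repeated-measures ANOVA (time × electrode) per band.
7. **FOM normalization.** Each frequency row of the TFR is divided by its
   median across all timepoints and epochs of that patient/session/
   electrode.  Power is then in factors of the median (FOM), making
   detection invariant to any per-frequency rescaling of the raw signal.
8. **Event detection.** Cells ≥ 6 FOM within the BOI rows are grouped into
   8-connected regions per epoch.  Each region yields exactly one event at
   its greatest local maximum; lesser maxima are discarded, so events never
   overlap within a region.  If several maxima tie for the greatest value,
   timing, frequency and FWHM boundaries are computed per maximum and
   averaged.
9. **Event measurement.** Duration is the FWHM of the time slice through
   the peak at the peak frequency; span is the FWHM of the frequency slice
   at the peak time.  Half-max crossings are linearly interpolated between
   grid cells.  A run cut by a grid edge takes twice the uncut half-width;
   if both sides are cut the full run extent is used.  Frequency spans may
   leave the BOI rows but not the 1–45 Hz grid.
10. **Statistics.** Pearson correlations between per-patient feature percent
    changes (or pre-treatment levels) and clinical change are computed for
    every (feature, electrode, band) cell — the 4 × 8 × 3 = 96 correction
    space — and BH-step-up adjusted at Q = 0.05 separately per clinical
    scale and per family (change vs baseline).  Adjusted p-values in
    (0.05, 0.08) are flagged "trending".  IDS-SR uses percent change,
    PCL-5 raw score change (both configurable).  Responders: PCL-5 raw
    reduction > 10 points (strict), IDS-SR percent reduction ≥ 50%
    (inclusive).

## Design choices where the method description is ambiguous

* **FWHM on 1-D slices.**  "Boundaries of the region containing power
  values greater than half the maximum" could mean 1-D slices through the
  peak or the 2-D half-max region's bounding box.  Slices are used: they
  are deterministic, cheap, and reduce to the correct closed forms on
  separable (Gaussian ridge) events.  Sub-cell interpolation is used
  because mean durations are plainly not multiples of the 2 ms sample step.
* **Threshold comparison** is ≥ (measure-zero difference on continuous
  data); **connectivity** is 8-connected (diagonal counts), configurable to
  4 — the brute-force oracle covers both.
* **Local maxima** are non-strict (≥ all 8 neighbours inside the
  band-restricted grid), so plateau cells fall under the tie rule.  The
  greatest local maximum of a region necessarily attains the region's
  maximum value, which is what the fast implementation exploits.
* **Tie averaging with different edge status** averages the per-maximum
  final widths (after any edge doubling).
* **Frequency spans are not clipped to the band**: a 15 Hz-wide beta band
  with ~10 Hz mean spans makes clipping implausible; spans are bounded only
  by the computed grid, with edge doubling at the grid boundary.
* **Normalization medians** are pooled per patient × session × electrode
  over all clean epochs and all timepoints, for every frequency row.
* **The >120 s usable-data floor** is applied per session (both sessions
  must pass), the stricter of the two possible readings.
* **BH family**: 96 tests per clinical scale per family; pooling the two
  scales into one 192-test family is available behind a config flag but off
  by default.
* **RM-ANOVA** uses the standard two-way within-subject decomposition
  (pingouin), with Greenhouse–Geisser-corrected p-values reported alongside
  the uncorrected ones.
* **Units.**  Power is carried in µV²-scaled units internally; detection
  and all event features operate on dimensionless FOM, so the absolute
  power scale cannot affect any event quantity (a property under test).
* **Precision.**  Wavelet convolution runs in single precision by default
  (`tfr_dtype`); kernels are always built in double precision.  Detection
  thresholds at 6 FOM and FWHM interpolation are insensitive to this at the
  tolerances used; `float64` is available via config.

## The synthetic-data generator

Real cohort data of this kind are not publicly distributable, so the test
surface is a generator with known ground truth.

**Background** is zero-mean Gaussian noise with an exactly shaped 1/f^α
spectrum (α = 1, RMS 10 µV by default; spectrum flattened below the 0.5 Hz
acquisition high-pass).  Band peaks in the PSD come from injected bursts,
not stationary oscillators.

**Bursts** are Gaussian-windowed sinusoids.  Per-band defaults are chosen
so the *detected* features sit at values typical of resting-state
spectral-event analyses: rates 0.69 / 1.28 / 2.35 events per 2-s epoch and
mean durations 884.6 / 295.4 / 136.9 ms for delta-theta / alpha / beta.
Envelope SDs are derived by inverting the duration relation at band-centre
frequency: a Gaussian burst convolved with the wavelet envelope has FWHM
duration 2√(ln 2)·√(σ_b² + σ_t²) with σ_t = 7/(2πf).  Burst centre
frequencies follow a truncated Gaussian at band centre (SD = band width/6):
band rhythms concentrate near a characteristic frequency, and centring
keeps a burst's spectral tail from crossing into the BOI above it (a
1.5 Hz upper-edge margin is kept for bands with a neighbour above); without
this, alpha bursts near 14 Hz are detected as spurious long-duration beta
events.  Each burst's amplitude is set analytically so that its peak
normalized power hits a target FOM (default 15, lognormal spread 0.30):
the peak wavelet response of a Gaussian burst has a closed form, and the
background median spectrum is estimated once per cohort from a seeded
reference recording.  Calibrating amplitude per burst (rather than per
band) keeps detectability independent of the envelope width, which matters
when envelope widths carry the experimental coupling.

**Artifacts** are Gaussian-windowed ~1 Hz transients at 20× channel RMS on
all channels of chosen epochs.  Cohort sessions record 4 spare epochs above
the usable-data floor because large genuine delta bursts occasionally trip
the amplitude screen.

**Clinical coupling.**  A per-patient latent amount z ~ N(0,1) multiplies
the coupled cell's generator parameter by m = 1 + γ·z (γ =
`coupling_strength`, default 0.30; m floored at 0.3).  For *duration* and
*span* the multiplier is applied to the feature value itself — the envelope
SD is re-solved per burst so the true detected duration (or span) scales by
exactly m — because the feature–parameter relation is compressive and the
coupling is defined on the feature scale.  For *number* the Poisson rate is
scaled; for *power* the target FOM.  IDS-SR percent change is
μ + σ·(ρ·z + √(1−ρ²)·w) with ρ = `target_r`, so corr(true feature change,
clinical change) = ρ exactly in expectation (and exactly ±1 when the noise
term vanishes); defaults μ = −39.3, σ = 18.  PCL-5 percent change is
generated correlated with IDS-SR change at 0.874.  In `baseline` mode the
multiplier applies to both sessions and the pre-treatment level carries the
coupling.

**The latent twin** (`gen_latent_cohort`) draws per-patient feature
summaries directly from the same coupling model without any EEG synthesis.
It exists to calibrate the statistical layer over hundreds of replicate
cohorts (null FDR control, recovery bias) at negligible cost; it shares the
clinical model with the full generator but none of the measurement physics.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: 1/f
background, transient band-limited events with realistic rates/durations,
artifact epochs, two-session cohorts with latent feature–clinical coupling.
It does **not** emulate volume conduction or electrode covariance (channels
are independent), realistic artifact taxonomies, non-Gaussian background,
eyes-open segments, or drift in burst properties within a session.  Passing
tests therefore demonstrate that the *pipeline* measures what it claims on
data obeying its assumptions — not that those assumptions hold in any
particular clinical recording.

### Measurement attenuation, and the conditions used for parameter recovery

Two properties of the method surfaced during generator design and are worth
knowing when interpreting real results:

* On a decaying background, FOM normalization divides a burst's ridge by
  per-row medians that fall with frequency, tilting the normalized maximum
  1–3 Hz *above* the injected centre frequency for short (spectrally wide)
  beta bursts.  Burst-recovery checks therefore match detected events
  against the realized normalized-power peak near the injection.
* The measured mean duration of a cell mixes injected events with
  background-born threshold exceedances (~0.5–0.8 per epoch in beta under
  Gaussian noise — an unavoidable consequence of a 6× median threshold),
  which shrinks the response slope of measured change to true change and
  adds session noise.  Correlation recovery is scale-invariant, so only the
  noise matters: with 100-epoch sessions the measured-vs-true correlation
  is ≈ 0.97, i.e. a true coupling of −0.66 is recovered at about −0.64 in
  expectation.  The false-event rate on pure background is reported by the
  test suite but not asserted against a fixed value.

The parameter-recovery validation accordingly runs 200 patients with
100 epochs (200-second resting recordings) per session, coupling strength
0.30 on frontal beta duration, target r = −0.66 — sizes chosen once, as the
package's study conditions, and used identically in the test suite and the
acceptance script.

## Tunable parameters (defaults)

| parameter | default | unit | why |
|---|---|---|---|
| `fs` | 500 | Hz | acquisition rate |
| `epoch_length` | 2.0 | s | epoching window |
| `freq_lo/hi/step` | 1–45, 1 | Hz | wavelet grid |
| `n_cycles` | 7 | — | Morlet width; σ_t = 7/(2πf) |
| `kernel_sd_truncation` | 4 | σ_t | kernel support |
| `threshold_fom` | 6 | FOM | event threshold |
| `connectivity` | 8 | — | region connectivity |
| `min_epochs` | 60 | epochs | usable-data floor (120 s) |
| `artifact_threshold_factor` | 8 | ×RMS | amplitude screen |
| `q_fdr` | 0.05 | — | BH level; trending < 0.08 |
| `tfr_dtype` | float32 | — | convolution precision |
| `CohortSpec.coupling_strength` | 0.30 | — | SD of latent multiplier |
| `CohortSpec.target_peak_fom` | 15 | FOM | burst detectability |
| `CohortSpec.background_rms` | 10 | µV | background scale |

## Known limitations

* The artifact screen is a single amplitude-ratio rule; it will not catch
  low-amplitude muscle artifact or stereotyped eye blinks below threshold.
* Channels are statistically independent in the generator, so cross-
  electrode event coordination cannot be studied on synthetic data.
* Mean beta durations sit close to the 7-cycle wavelet's resolution floor
  (2σ_t√(ln 2) ≈ 84–93 ms at 20–22 Hz), so large *decreases* in true burst
  duration compress in the measured feature.
* The RM-ANOVA degrees-of-freedom convention of the original analysis is
  ambiguous; the standard within-subject decomposition is used and the
  printed F-statistics of the source analysis are not a comparison target.
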