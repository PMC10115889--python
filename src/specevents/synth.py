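"""Synthetic EEG cohorts with known ground truth.

The study data this pipeline targets (resting-state 8-electrode EEG from a
23-patient pre/post-treatment cohort) are not publicly available, so every
downstream stage is exercised on synthetic recordings built here:

* 1/f^alpha background noise (resting EEG power spectra are broadband
  decaying; band peaks come from injected bursts, not stationary
  oscillators);
* transient oscillatory bursts — Gaussian-windowed sinusoids — injected at
  per-band rates; the default rates and envelope widths are calibrated so
  that, at band-center frequency, the expected detected event rate and
  FWHM duration match the values typical of resting-state spectral-event
  analyses (0.69 / 1.28 / 2.35 events per 2-s epoch and 884.6 / 295.4 /
  136.9 ms durations for delta-theta / alpha / beta);
* optional artifact epochs (low-frequency, high-amplitude transients);
* a two-session cohort whose true burst parameters change pre->post by a
  per-patient latent amount, with clinical percent change coupled linearly
  (plus Gaussian noise) to that latent amount so that the population
  Pearson correlation equals a configurable ``target_r`` exactly in
  expectation.

Every generator is a pure function of its seed: same seed, same output.

A latent-level twin, :func:`gen_latent_cohort`, draws per-patient feature
summaries directly (no EEG synthesis) with the same clinical coupling; it
exists to calibrate the statistical layer over many replicate cohorts at
negligible cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_BANDS, DEFAULT_ELECTRODES, FEATURES, BandDef
from .exceptions import InvalidArgumentError
from .preprocess import RawRecording
from .stats import ClinicalRecord
from .tfr import morlet_kernel, morlet_sigma_t

# Feature scales used to parameterize burst generation and the latent twin:
# events per 2-s epoch, FOM maxima power, FWHM duration (ms) and frequency
# span (Hz) per band.
BAND_FEATURE_MEANS: dict[str, dict[str, float]] = {
    "delta_theta": {"number": 0.69, "power": 8.0, "duration": 884.6, "span": 3.09},
    "alpha": {"number": 1.28, "power": 8.0, "duration": 295.4, "span": 5.49},
    "beta": {"number": 2.35, "power": 8.0, "duration": 136.9, "span": 9.82},
}

_TWO_SQRT_LN2 = 2.0 * math.sqrt(math.log(2.0))


@dataclass
class BurstSpec:
    """One transient oscillatory burst: a Gaussian-windowed sinusoid."""

    center_time: float   # s, within the recording
    center_freq: float   # Hz
    envelope_sd: float   # s, SD of the Gaussian amplitude envelope
    amplitude: float     # µV, envelope peak
    channel: str

    def validate(self, rec: RawRecording) -> None:
        if not (0.0 < self.center_freq < 45.0 + 1e-9):
            raise InvalidArgumentError("center_freq outside 0-45 Hz")
        if self.envelope_sd <= 0:
            raise InvalidArgumentError("envelope_sd must be positive")
        if self.amplitude <= 0:
            raise InvalidArgumentError("amplitude must be positive")
        if not (0.0 <= self.center_time <= rec.duration):
            raise InvalidArgumentError("burst lies outside the recording")
        rec.channel_index(self.channel)


@dataclass
class GroundTruth:
    """What was actually put into a synthetic recording or cohort."""

    bursts: list[BurstSpec] = field(default_factory=list)
    burst_epochs: list[int] = field(default_factory=list)  # parallel to bursts
    artifact_epochs: set[int] = field(default_factory=set)
    clinical_truth: pd.DataFrame | None = None
    epoch_length: float = 2.0


# ---------------------------------------------------------------------------
# background + injections
# ---------------------------------------------------------------------------

def gen_background(
    n_channels: int,
    duration: float,
    fs: float = 500.0,
    slope_alpha: float = 1.0,
    rms: float = 10.0,
    seed: int = 0,
    channel_labels: tuple[str, ...] | None = None,
) -> RawRecording:
    """Zero-mean Gaussian noise with a 1/f^alpha power spectrum.

    Spectral shaping is exact: white Gaussian Fourier coefficients are
    scaled by f^(-alpha/2) (flattened below 0.5 Hz so the DC region stays
    bounded) and inverse-transformed, then rescaled to the requested RMS.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    if n_channels < 1:
        raise InvalidArgumentError("need at least one channel")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    f_floor = 0.5  # Hz; matches the acquisition high-pass
    pos = freqs > 0
    shape[pos] = np.maximum(freqs[pos], f_floor) ** (-slope_alpha / 2.0)
    coef = (
        rng.normal(size=(n_channels, freqs.size))
        + 1j * rng.normal(size=(n_channels, freqs.size))
    ) * shape
    coef[:, 0] = 0.0
    data = np.fft.irfft(coef, n=n, axis=1)
    data -= data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, keepdims=True)
    data = data / std * rms
    labels = channel_labels or tuple(f"CH{i}" for i in range(n_channels))
    return RawRecording(data=data, fs=fs, channel_labels=labels)


def burst_waveform(
    burst: BurstSpec, fs: float, n_samples: int
) -> tuple[int, np.ndarray]:
    """Sampled burst, truncated at ±5 envelope SDs and clipped to the
    recording.  Returns (start_sample, samples)."""
    half = int(np.ceil(5.0 * burst.envelope_sd * fs))
    c = int(round(burst.center_time * fs))
    lo = max(0, c - half)
    hi = min(n_samples, c + half + 1)
    t = np.arange(lo, hi) / fs - burst.center_time
    w = (
        burst.amplitude
        * np.exp(-(t**2) / (2.0 * burst.envelope_sd**2))
        * np.cos(2.0 * np.pi * burst.center_freq * t)
    )
    return lo, w


def inject_bursts(
    rec: RawRecording,
    bursts: list[BurstSpec],
    epoch_length: float = 2.0,
) -> tuple[RawRecording, GroundTruth]:
    """Add Gaussian-windowed sinusoids to a recording.

    Returns the summed recording and a ground truth listing each burst with
    the epoch index its center falls in (0-based, 2-s tiling).
    """
    data = rec.data.copy()
    epochs = []
    for b in bursts:
        b.validate(rec)
        lo, w = burst_waveform(b, rec.fs, rec.n_samples)
        data[rec.channel_index(b.channel), lo : lo + w.size] += w
        epochs.append(int(b.center_time // epoch_length))
    out = RawRecording(
        data=data, fs=rec.fs, channel_labels=rec.channel_labels,
        session=rec.session, patient_id=rec.patient_id,
    )
    truth = GroundTruth(
        bursts=list(bursts), burst_epochs=epochs, epoch_length=epoch_length
    )
    return out, truth


def inject_artifacts(
    rec: RawRecording,
    epoch_indices: list[int],
    scale: float = 20.0,
    epoch_length: float = 2.0,
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Contaminate chosen epochs with low-frequency high-amplitude transients.

    Each marked epoch receives, on every channel, a Gaussian-windowed ~1 Hz
    transient whose peak is ``scale`` times the channel RMS — emulating eye
    movement / movement / drift artifacts that amplitude screening should
    remove.
    """
    if scale <= 1:
        raise InvalidArgumentError("scale must exceed 1")
    n_epochs = int(rec.duration // epoch_length)
    bad = sorted(set(int(i) for i in epoch_indices))
    if any(i < 0 or i >= n_epochs for i in bad):
        raise InvalidArgumentError("artifact epoch index out of range")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    samples_per_epoch = int(round(epoch_length * rec.fs))
    rms = rec.data.std(axis=1)
    for i in bad:
        center = (i + 0.3 + 0.4 * rng.random()) * epoch_length
        t = np.arange(i * samples_per_epoch, (i + 1) * samples_per_epoch) / rec.fs
        envelope = np.exp(-((t - center) ** 2) / (2.0 * 0.15**2))
        wave = envelope * np.cos(2.0 * np.pi * 1.0 * (t - center))
        data[:, i * samples_per_epoch : (i + 1) * samples_per_epoch] += (
            scale * rms[:, None] * wave[None, :]
        )
    out = RawRecording(
        data=data, fs=rec.fs, channel_labels=rec.channel_labels,
        session=rec.session, patient_id=rec.patient_id,
    )
    return out, GroundTruth(artifact_epochs=set(bad), epoch_length=epoch_length)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic two-session cohort.

    ``coupling_*`` choose the single correction-space cell whose true
    generator parameter varies across patients with the latent amount that
    also drives clinical change; ``target_r`` is the population Pearson
    correlation between the two.  ``coupling_mode`` selects whether the
    latent amount scales the pre->post *change* of the parameter or its
    *baseline* level.
    """

    n_patients: int = 23
    epochs_per_session: int = 60
    burst_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            b: BAND_FEATURE_MEANS[b]["number"] for b in BAND_FEATURE_MEANS
        }
    )
    coupling_feature: str = "duration"
    coupling_band: str = "beta"
    coupling_electrode: str = "FPz"
    coupling_mode: str = "change"          # "change" | "baseline"
    target_r: float = -0.66
    coupling_strength: float = 0.30        # SD of the latent multiplier
    baseline_jitter_sd: float = 0.05       # patient-level multiplicative SD
    target_peak_fom: float = 15.0          # calibrated burst peak, FOM units
    background_rms: float = 10.0           # µV
    background_alpha: float = 1.0
    fs: float = 500.0
    epoch_length: float = 2.0
    clinical_mean_ids_pct: float = -39.3   # mean IDS-SR percent change
    clinical_sd_ids_pct: float = 18.0
    clinical_mean_pcl_pct: float = -39.0
    clinical_sd_pcl_pct: float = 18.0
    pcl_ids_r: float = 0.874               # PCL-5 / IDS-SR change correlation
    artifact_epochs_per_session: int = 0
    artifact_scale: float = 20.0
    spare_epochs: int = 4                  # recorded beyond the usable floor
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise InvalidArgumentError("n_patients must be >= 3")
        if self.epochs_per_session < 60:
            raise InvalidArgumentError(
                "epochs_per_session must be >= 60 (the usable-data floor)"
            )
        if abs(self.target_r) > 1:
            raise InvalidArgumentError("|target_r| must be <= 1")
        if self.coupling_feature not in FEATURES:
            raise InvalidArgumentError(f"unknown feature {self.coupling_feature}")
        if self.coupling_mode not in ("change", "baseline"):
            raise InvalidArgumentError(f"unknown mode {self.coupling_mode}")

    def band(self, name: str) -> BandDef:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class PatientData:
    patient_id: str
    rec_pre: RawRecording
    rec_post: RawRecording
    clinical: ClinicalRecord
    truth_pre: GroundTruth
    truth_post: GroundTruth


def band_envelope_sd(band: BandDef, n_cycles: float = 7.0) -> float:
    """Default burst envelope SD for a band, in seconds.

    Chosen so that the FWHM duration of the detected event at band-center
    frequency — 2·sqrt(ln 2)·sqrt(σ_b² + σ_t²), the Gaussian burst envelope
    convolved with the wavelet envelope — matches the band's typical mean
    duration.
    """
    f_c = 0.5 * (band.lo + band.hi)
    target = BAND_FEATURE_MEANS[band.name]["duration"] / 1000.0
    total_sd = target / _TWO_SQRT_LN2
    sigma_t = morlet_sigma_t(f_c, n_cycles)
    return math.sqrt(max(total_sd**2 - sigma_t**2, 1e-4))


def _sample_center_freq(
    band: BandDef, rng: np.random.Generator, margin_hi: float = 0.25
) -> float:
    """Burst centre frequency: truncated Gaussian at band centre.

    Band rhythms concentrate near a characteristic frequency (alpha near
    10 Hz, etc.) rather than filling the band uniformly.  ``margin_hi``
    keeps centres away from the band's upper edge: a burst's spectral tail
    (wavelet σ_f = f/7 plus the burst's own bandwidth) would otherwise cross
    into the band of interest above and be detected there as a spurious
    long-duration event.
    """
    center = 0.5 * (band.lo + band.hi)
    sd = (band.hi - band.lo) / 6.0
    return float(
        np.clip(rng.normal(center, sd), band.lo + 0.25, band.hi - margin_hi)
    )


def _sd_for_duration_scale(
    sd0: float, freq: float, m: float, n_cycles: float = 7.0
) -> float:
    """Envelope SD making the burst's true detected duration m times the
    duration a burst with envelope ``sd0`` would have at ``freq``.

    The detected FWHM duration is 2·sqrt(ln 2)·sqrt(σ_b² + σ_t²) (burst
    envelope convolved with the wavelet envelope), so scaling the *feature*
    by m requires σ_b' = sqrt(m²(σ_b² + σ_t²) − σ_t²); the multiplier then
    acts linearly on the measured duration, not on σ_b.
    """
    st2 = morlet_sigma_t(freq, n_cycles) ** 2
    return math.sqrt(max(m**2 * (sd0**2 + st2) - st2, 1e-4))


def _sd_for_span_scale(
    sd0: float, freq: float, m: float, n_cycles: float = 7.0
) -> float:
    """Envelope SD making the burst's true frequency span m times the span
    of a burst with envelope ``sd0`` at ``freq``.

    Spectral width combines the wavelet filter SD σ_fw = f/n_cycles with the
    burst's own bandwidth σ_fb = 1/(2π σ_b); scaling the total by m gives
    σ_fb' = sqrt(m²(σ_fw² + σ_fb²) − σ_fw²), hence σ_b' = 1/(2π σ_fb').
    """
    sfw2 = (freq / n_cycles) ** 2
    sfb2 = (1.0 / (2.0 * math.pi * sd0)) ** 2
    sfb_new = math.sqrt(max(m**2 * (sfw2 + sfb2) - sfw2, 1e-6))
    return min(1.0 / (2.0 * math.pi * sfb_new), 2.0)


def _unit_burst_peak_power(
    freq: float, envelope_sd: float, fs: float, n_cycles: float = 7.0
) -> float:
    """Peak wavelet power of a unit-amplitude Gaussian burst at its own
    frequency (closed form: Gaussian-Gaussian convolution)."""
    st = morlet_sigma_t(freq, n_cycles)
    c = (st * math.sqrt(math.pi)) ** -0.5
    peak = (
        fs * (c / 2.0) * math.sqrt(2.0 * math.pi)
        * envelope_sd * st / math.sqrt(envelope_sd**2 + st**2)
    )
    return peak**2


class BurstCalibration:
    """Maps a desired peak FOM to a burst amplitude, per frequency.

    FOM normalization divides each row by its median power, so the amplitude
    reaching a target FOM is sqrt(target · median_background_power(f) /
    unit_burst_peak_power(f, σ_b)).  The background median spectrum is
    estimated once per cohort from a seeded reference recording and
    interpolated across 1–45 Hz; the unit-burst gain is analytic, so the
    calibration tracks each burst's own envelope width and frequency.
    """

    def __init__(self, spec: "CohortSpec") -> None:
        rec = gen_background(
            1, 32.0, spec.fs, spec.background_alpha, spec.background_rms,
            seed=spec.seed % (2**31 - 987_001) + 987_001,
        )
        self._fs = spec.fs
        self._grid = np.arange(1.0, 46.0, 3.0)
        meds = []
        for f in self._grid:
            kernel = morlet_kernel(f, spec.fs)
            conv = np.convolve(rec.data[0], kernel, mode="same")
            meds.append(np.median(np.abs(conv) ** 2))
        self._med = np.array(meds)

    def median_power(self, freq: float) -> float:
        return float(np.interp(freq, self._grid, self._med))

    def amplitude_for(self, freq: float, envelope_sd: float,
                      peak_fom: float) -> float:
        gain = _unit_burst_peak_power(freq, envelope_sd, self._fs)
        return math.sqrt(peak_fom * self.median_power(freq) / gain)


def _latent_and_clinical(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[ClinicalRecord], pd.DataFrame]:
    """Latent coupling amounts and the clinical records tied to them.

    z_i ~ N(0,1) drives both the coupled feature and, through
    Δc = μ + σ·(ρ·z + sqrt(1-ρ²)·w), the IDS-SR percent change, so
    corr(z, Δc) = ρ = target_r in expectation (exactly ρ = ±1 when the
    noise term vanishes).  PCL-5 percent change is generated correlated
    with IDS-SR change at the configured level.
    """
    n = spec.n_patients
    z = rng.normal(size=n)
    w = rng.normal(size=n)
    v = rng.normal(size=n)
    rho = spec.target_r
    ids_pct = spec.clinical_mean_ids_pct + spec.clinical_sd_ids_pct * (
        rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * w
    )
    rr = spec.pcl_ids_r
    ids_std = (ids_pct - spec.clinical_mean_ids_pct) / spec.clinical_sd_ids_pct
    pcl_pct = spec.clinical_mean_pcl_pct + spec.clinical_sd_pcl_pct * (
        rr * ids_std + math.sqrt(max(0.0, 1.0 - rr**2)) * v
    )
    ids_pre = np.clip(rng.normal(45.0, 6.0, size=n), 25.0, 70.0)
    pcl_pre = np.clip(rng.normal(50.0, 8.0, size=n), 25.0, 80.0)
    records = []
    for i in range(n):
        records.append(
            ClinicalRecord(
                patient_id=f"P{i:03d}",
                pcl5_pre=float(pcl_pre[i]),
                pcl5_post=float(max(0.0, pcl_pre[i] * (1 + pcl_pct[i] / 100))),
                ids_sr_pre=float(ids_pre[i]),
                ids_sr_post=float(max(0.0, ids_pre[i] * (1 + ids_pct[i] / 100))),
            )
        )
    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "z": z,
            "true_feature_pct_change": 100.0 * spec.coupling_strength * z,
            "ids_pct_change": ids_pct,
            "pcl_pct_change": pcl_pct,
        }
    )
    return z, records, truth


def _patient_multipliers(
    spec: CohortSpec, z_i: float
) -> tuple[float, float]:
    """(m_pre, m_post) multipliers of the coupled generator parameter."""
    m = max(0.3, 1.0 + spec.coupling_strength * z_i)
    if spec.coupling_mode == "change":
        return 1.0, m
    return m, m  # baseline mode: level varies, no pre->post change


def _gen_session(
    spec: CohortSpec,
    patient_id: str,
    session: str,
    m_coupled: float,
    base_jitter: float,
    cal: BurstCalibration,
    rng: np.random.Generator,
) -> tuple[RawRecording, GroundTruth]:
    # record a few spare epochs beyond the target so that occasional
    # amplitude-screen rejections (large genuine low-frequency bursts can
    # trip the artifact rule) do not push a session below the usable floor
    n_epochs = (
        spec.epochs_per_session
        + spec.spare_epochs
        + spec.artifact_epochs_per_session
    )
    duration = n_epochs * spec.epoch_length
    rec = gen_background(
        len(spec.electrodes),
        duration,
        spec.fs,
        spec.background_alpha,
        spec.background_rms,
        seed=int(rng.integers(2**31)),
        channel_labels=spec.electrodes,
    )
    rec.session = session
    rec.patient_id = patient_id

    artifact_epochs: list[int] = []
    if spec.artifact_epochs_per_session > 0:
        artifact_epochs = sorted(
            rng.choice(
                n_epochs, size=spec.artifact_epochs_per_session, replace=False
            ).tolist()
        )
    clean = [i for i in range(n_epochs) if i not in set(artifact_epochs)]

    bursts: list[BurstSpec] = []
    for ch in spec.electrodes:
        for band in spec.bands:
            coupled = (
                ch == spec.coupling_electrode and band.name == spec.coupling_band
            )
            m = m_coupled * base_jitter if coupled else 1.0
            rate = spec.burst_rates[band.name]
            sd0 = band_envelope_sd(band)
            if coupled and spec.coupling_feature == "number":
                rate = rate * m
            # bands with a neighbouring BOI above keep a spectral-leakage
            # margin below their upper edge; the top band needs none
            has_upper = any(b2.lo > band.hi for b2 in spec.bands)
            margin_hi = 1.5 if has_upper else 0.25
            for ep in clean:
                for _ in range(rng.poisson(rate)):
                    t0 = (ep + 0.05 + 0.90 * rng.random()) * spec.epoch_length
                    f0 = _sample_center_freq(band, rng, margin_hi)
                    sd = sd0
                    fom = spec.target_peak_fom
                    if coupled and spec.coupling_feature == "duration":
                        sd = _sd_for_duration_scale(sd0, f0, m)
                    elif coupled and spec.coupling_feature == "span":
                        sd = _sd_for_span_scale(sd0, f0, m)
                    elif coupled and spec.coupling_feature == "power":
                        fom = fom * m
                    sd *= float(np.exp(rng.normal(0.0, 0.10)))
                    fom *= float(np.exp(rng.normal(0.0, 0.30)))
                    # amplitude set per burst so its peak power in FOM units
                    # is controlled regardless of envelope width or frequency
                    amp = cal.amplitude_for(f0, sd, fom)
                    bursts.append(
                        BurstSpec(
                            center_time=float(t0),
                            center_freq=float(f0),
                            envelope_sd=float(sd),
                            amplitude=float(amp),
                            channel=ch,
                        )
                    )
    rec, truth = inject_bursts(rec, bursts, spec.epoch_length)
    if artifact_epochs:
        rec, art_truth = inject_artifacts(
            rec,
            artifact_epochs,
            spec.artifact_scale,
            spec.epoch_length,
            seed=int(rng.integers(2**31)),
        )
        truth.artifact_epochs = art_truth.artifact_epochs
    rec.session = session
    rec.patient_id = patient_id
    return rec, truth


def iter_cohort(spec: CohortSpec) -> Iterator[PatientData]:
    """Stream one patient at a time (recordings are large; avoid holding a
    whole large cohort in memory)."""
    master = np.random.SeedSequence(spec.seed)
    global_ss, *patient_ss = master.spawn(spec.n_patients + 1)
    g_rng = np.random.default_rng(global_ss)
    z, records, _ = _latent_and_clinical(spec, g_rng)
    cal = BurstCalibration(spec)
    for i in range(spec.n_patients):
        rng = np.random.default_rng(patient_ss[i])
        base_jitter = float(np.exp(rng.normal(0.0, spec.baseline_jitter_sd)))
        m_pre, m_post = _patient_multipliers(spec, float(z[i]))
        pid = records[i].patient_id
        rec_pre, tr_pre = _gen_session(
            spec, pid, "pre", m_pre, base_jitter, cal, rng
        )
        rec_post, tr_post = _gen_session(
            spec, pid, "post", m_post, base_jitter, cal, rng
        )
        yield PatientData(pid, rec_pre, rec_post, records[i], tr_pre, tr_post)


def cohort_truth(spec: CohortSpec) -> pd.DataFrame:
    """Per-patient latent ground truth (no EEG synthesis)."""
    master = np.random.SeedSequence(spec.seed)
    global_ss = master.spawn(1)[0]
    g_rng = np.random.default_rng(global_ss)
    _, _, truth = _latent_and_clinical(spec, g_rng)
    return truth


def gen_cohort(spec: CohortSpec) -> tuple[list[PatientData], GroundTruth]:
    """Materialize a full cohort.  Suitable for small n; for large cohorts
    use :func:`iter_cohort` and stream."""
    patients = list(iter_cohort(spec))
    truth = GroundTruth(
        clinical_truth=cohort_truth(spec), epoch_length=spec.epoch_length
    )
    return patients, truth


# ---------------------------------------------------------------------------
# latent-level twin (no EEG) for statistical calibration
# ---------------------------------------------------------------------------

def gen_latent_cohort(
    spec: CohortSpec,
    measurement_noise_pct: float = 2.0,
    uncoupled_change_sd_pct: float = 8.0,
) -> tuple[pd.DataFrame, list[ClinicalRecord], pd.DataFrame]:
    """Draw per-patient feature summaries directly, skipping EEG synthesis.

    Every correction-space cell gets a baseline level around its band's
    typical mean with patient-level jitter; the coupled cell's percent
    change (or baseline, per ``coupling_mode``) follows the latent amount
    while all other cells change by independent noise.  Returns
    (summaries, clinical records, truth) in the same shapes the full
    pipeline produces.
    """
    master = np.random.SeedSequence(spec.seed)
    global_ss, cells_ss = master.spawn(2)
    g_rng = np.random.default_rng(global_ss)
    z, records, truth = _latent_and_clinical(spec, g_rng)
    rng = np.random.default_rng(cells_ss)
    n = spec.n_patients
    rows = []
    for feature in FEATURES:
        for electrode in spec.electrodes:
            for band in spec.bands:
                mean = BAND_FEATURE_MEANS[band.name][feature]
                coupled = (
                    feature == spec.coupling_feature
                    and electrode == spec.coupling_electrode
                    and band.name == spec.coupling_band
                )
                base = mean * (
                    1.0 + spec.baseline_jitter_sd * rng.normal(size=n)
                )
                if coupled and spec.coupling_mode == "baseline":
                    base = base * (1.0 + spec.coupling_strength * z)
                if coupled and spec.coupling_mode == "change":
                    pct = 100.0 * spec.coupling_strength * z
                else:
                    pct = uncoupled_change_sd_pct * rng.normal(size=n)
                noise = measurement_noise_pct * rng.normal(size=(2, n))
                pre = base * (1.0 + noise[0] / 100.0)
                post = base * (1.0 + pct / 100.0) * (1.0 + noise[1] / 100.0)
                for i in range(n):
                    rows.append((f"P{i:03d}", "pre", electrode, band.name,
                                 feature, pre[i]))
                    rows.append((f"P{i:03d}", "post", electrode, band.name,
                                 feature, post[i]))
    long = pd.DataFrame(
        rows,
        columns=["patient_id", "session", "electrode", "band", "feature",
                 "value"],
    )
    summaries = (
        long.pivot_table(
            index=["patient_id", "session", "electrode", "band"],
            columns="feature",
            values="value",
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return summaries, records, truth
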