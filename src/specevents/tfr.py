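"""Morlet wavelet time–frequency responses, PSDs and FOM normalization.

Each 2-s epoch is convolved with a family of 7-cycle complex Morlet wavelets
(one per grid frequency, 1–45 Hz by default); squared magnitude gives the
per-epoch time–frequency response (TFR).  The session PSD is the TFR
averaged over time and epochs.  For event detection each frequency row of
the TFR is divided by its median across all timepoints and epochs of the
patient/session/electrode, yielding dimensionless power in factors of the
median (FOM).

Numerical conventions: kernels are truncated at ±4 temporal standard
deviations and unit-energy normalized (Σ|w|²·dt = 1); convolution is
same-length with zero padding, so edge timepoints are retained (downstream
event measurement has an explicit edge-doubling rule for exactly this
reason).  Convolutions run in single precision by default; kernels
themselves are always built in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.fft

from .config import BandDef
from .exceptions import DegenerateInputError, InvalidArgumentError
from .preprocess import EpochArray


@dataclass
class TFRStack:
    """Per-epoch power over a frequency x time grid for one electrode.

    ``power`` has shape (epochs, frequencies, timepoints); µV²-scaled for raw
    stacks, dimensionless FOM for normalized ones.
    """

    power: np.ndarray
    freqs: np.ndarray           # Hz, strictly increasing
    times: np.ndarray           # s within epoch
    fs: float
    electrode: str
    normalized: bool = False
    median_power: np.ndarray | None = None  # per-frequency medians used in FOM
    session: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidArgumentError("freqs must be strictly increasing")
        if self.power.ndim != 3 or self.power.shape[1] != self.freqs.size:
            raise InvalidArgumentError("power must be epochs x freqs x times")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def morlet_kernel(
    freq: float,
    fs: float,
    n_cycles: float = 7.0,
    sd_truncation: float = 4.0,
) -> np.ndarray:
    """Unit-energy complex Morlet kernel at ``freq``.

    Temporal standard deviation σ_t = n_cycles / (2π·freq); the sampled
    kernel spans ±``sd_truncation``·σ_t and satisfies Σ|w|²·dt = 1, so white
    noise of unit variance maps to unit expected output power.
    """
    if freq <= 0:
        raise InvalidArgumentError("frequency must be positive")
    if fs <= 2 * freq:
        raise InvalidArgumentError(
            f"frequency {freq} Hz at or above Nyquist for fs={fs}"
        )
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(sd_truncation * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)
    return w


def morlet_sigma_t(freq: float, n_cycles: float = 7.0) -> float:
    """Temporal SD of the Morlet envelope, in seconds."""
    return n_cycles / (2.0 * np.pi * freq)


def morlet_sigma_f(freq: float, n_cycles: float = 7.0) -> float:
    """Spectral SD of the Morlet filter, in Hz (σ_f = freq / n_cycles)."""
    return freq / n_cycles


def _tfr_power(
    x: np.ndarray,
    fs: float,
    freqs: Sequence[float],
    n_cycles: float,
    sd_truncation: float,
    dtype: str,
) -> np.ndarray:
    """Wavelet power of ``x`` (…, n_samples) at each frequency.

    Same-length zero-padded convolution, FFT-based, batched over the leading
    axes and grouped by padded length so short (high-frequency) kernels do
    not pay for the longest (1 Hz) kernel.
    """
    x = np.ascontiguousarray(x, dtype=dtype)
    lead = x.shape[:-1]
    n = x.shape[-1]
    xf = x.reshape(-1, n)
    cdtype = "complex64" if dtype == "float32" else "complex128"

    kernels = [morlet_kernel(f, fs, n_cycles, sd_truncation) for f in freqs]
    # Pad each linear convolution up to the nearest 2^k or 3*2^k length:
    # few distinct sizes (one forward FFT each) and fast FFT factorizations.
    nfft = [_bucket_length(n + k.size - 1) for k in kernels]

    out = np.empty((xf.shape[0], len(freqs), n), dtype=dtype)
    for nf in sorted(set(nfft)):
        rows = [i for i, m in enumerate(nfft) if m == nf]
        xhat = scipy.fft.fft(xf, nf, axis=-1).astype(cdtype, copy=False)
        for i in rows:
            k = kernels[i]
            khat = scipy.fft.fft(k, nf).astype(cdtype)
            y = scipy.fft.ifft(xhat * khat, axis=-1)
            half = (k.size - 1) // 2
            seg = y[:, half : half + n]
            out[:, i, :] = (seg.real**2 + seg.imag**2)
    return out.reshape(*lead, len(freqs), n)


def _bucket_length(required: int) -> int:
    """Smallest 2^k or 3*2^k that is >= required."""
    p = 1
    while p < required:
        p <<= 1
    three = 3 * (p >> 2)
    return three if three >= required else p


def compute_tfr(
    ep: EpochArray,
    electrode: str,
    freqs: Sequence[float],
    n_cycles: float = 7.0,
    sd_truncation: float = 4.0,
    dtype: str = "float32",
) -> TFRStack:
    """Per-epoch Morlet TFR for one electrode: power = |convolution|²."""
    ch = ep.channel_index(electrode)
    power = _tfr_power(
        ep.data[ch], ep.fs, freqs, n_cycles, sd_truncation, dtype
    )
    times = np.arange(ep.n_samples) / ep.fs
    return TFRStack(
        power=power,
        freqs=np.asarray(freqs, dtype=float),
        times=times,
        fs=ep.fs,
        electrode=electrode,
        normalized=False,
        session=ep.session,
        patient_id=ep.patient_id,
    )


def compute_tfr_all(
    ep: EpochArray,
    freqs: Sequence[float],
    n_cycles: float = 7.0,
    sd_truncation: float = 4.0,
    dtype: str = "float32",
) -> dict[str, TFRStack]:
    """TFRs for every channel at once (one batched FFT pass)."""
    power = _tfr_power(ep.data, ep.fs, freqs, n_cycles, sd_truncation, dtype)
    times = np.arange(ep.n_samples) / ep.fs
    return {
        label: TFRStack(
            power=power[ci],
            freqs=np.asarray(freqs, dtype=float),
            times=times,
            fs=ep.fs,
            electrode=label,
            normalized=False,
            session=ep.session,
            patient_id=ep.patient_id,
        )
        for ci, label in enumerate(ep.channel_labels)
    }


def compute_psd(tfrs: Sequence[TFRStack]) -> np.ndarray:
    """Session-pooled PSD: TFR averaged over time, then over all epochs.

    ``tfrs`` are the raw (non-normalized) stacks of one electrode across the
    sessions being pooled; with matched epoch counts this equals the grand
    mean over all epochs of both sessions.
    """
    if not tfrs:
        raise InvalidArgumentError("no TFR stacks given")
    if any(t.normalized for t in tfrs):
        raise InvalidArgumentError("compute_psd requires non-normalized TFRs")
    f0 = tfrs[0].freqs
    for t in tfrs[1:]:
        if not np.array_equal(t.freqs, f0):
            raise InvalidArgumentError("TFR stacks on different frequency grids")
    per_epoch = np.concatenate(
        [t.power.mean(axis=2) for t in tfrs], axis=0
    )  # (total epochs, freqs)
    return per_epoch.mean(axis=0).astype(float)


def band_power(psd: np.ndarray, freqs: Sequence[float], band: BandDef) -> float:
    """Arithmetic mean of the PSD over the band's grid rows (inclusive)."""
    rows = band.rows(freqs)
    return float(np.mean(np.asarray(psd, dtype=float)[rows]))


def normalize_fom(tfr: TFRStack) -> TFRStack:
    """Divide each frequency row by its median over all epochs and times.

    Output power is in factors of the median (FOM); by construction the
    pooled median of every row is exactly 1.
    """
    if tfr.normalized:
        raise InvalidArgumentError("TFR already normalized")
    if tfr.n_epochs < 1:
        raise InvalidArgumentError("need at least one epoch")
    pooled = np.moveaxis(tfr.power, 1, 0).reshape(tfr.freqs.size, -1)
    med = np.median(pooled, axis=1)
    if np.any(med <= 0):
        raise DegenerateInputError("zero median power on some frequency row")
    power = tfr.power / med[None, :, None]
    return replace(
        tfr,
        power=power,
        normalized=True,
        median_power=med.astype(float),
    )
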