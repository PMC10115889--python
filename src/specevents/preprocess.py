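"""Epoching, artifact rejection and session matching.

Continuous multichannel recordings are cut into non-overlapping 2-s epochs,
epochs with large-amplitude transients are removed by an automated
amplitude-ratio rule (a reproducible stand-in for manual artifact
inspection, masked from clinical outcome), sessions below the usable-data
floor are excluded, and pre/post sessions are equalized in epoch count by
seeded uniform subsampling so that event counts are comparable.

Sample indexing is 0-based and half-open throughout: epoch ``i`` covers
samples ``[i*L, (i+1)*L)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .exceptions import EmptyInputError, InvalidArgumentError

if TYPE_CHECKING:  # pragma: no cover
    from .stats import ClinicalRecord


@dataclass
class RawRecording:
    """Continuous multichannel EEG: ``data`` is channels x samples, in µV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    session: str | None = None      # "pre" | "post"
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidArgumentError("duplicate channel labels")
        if self.data.shape[0] != len(self.channel_labels):
            raise InvalidArgumentError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"unknown electrode {label!r}") from None


@dataclass
class EpochArray:
    """Segmented data: ``data`` is channels x epochs x samples."""

    data: np.ndarray
    fs: float
    epoch_length: float
    channel_labels: tuple[str, ...]
    kept_epoch_indices: tuple[int, ...]
    session: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.kept_epoch_indices = tuple(int(i) for i in self.kept_epoch_indices)
        expected = int(round(self.epoch_length * self.fs))
        if self.data.ndim != 3 or self.data.shape[2] != expected:
            raise InvalidArgumentError(
                f"epoch data must be channels x epochs x {expected} samples"
            )
        if self.data.shape[1] != len(self.kept_epoch_indices):
            raise InvalidArgumentError("kept_epoch_indices length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"unknown electrode {label!r}") from None

    def select(self, epoch_positions: Sequence[int]) -> "EpochArray":
        """New EpochArray keeping the given positions (into the current axis)."""
        pos = np.asarray(sorted(epoch_positions), dtype=int)
        return EpochArray(
            data=self.data[:, pos, :],
            fs=self.fs,
            epoch_length=self.epoch_length,
            channel_labels=self.channel_labels,
            kept_epoch_indices=tuple(self.kept_epoch_indices[p] for p in pos),
            session=self.session,
            patient_id=self.patient_id,
        )


def segment_epochs(rec: RawRecording, epoch_length: float = 2.0) -> EpochArray:
    """Cut a recording into non-overlapping epochs; drop the trailing partial.

    Epoch ``i`` covers samples ``[i*L, (i+1)*L)`` with ``L = epoch_length*fs``.
    """
    if epoch_length <= 0:
        raise InvalidArgumentError("epoch_length must be positive")
    samples_per_epoch = int(round(epoch_length * rec.fs))
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise EmptyInputError(
            f"recording of {rec.duration:.3f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * samples_per_epoch]
    data = trimmed.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    return EpochArray(
        data=data.copy(),
        fs=rec.fs,
        epoch_length=epoch_length,
        channel_labels=rec.channel_labels,
        kept_epoch_indices=tuple(range(n_epochs)),
        session=rec.session,
        patient_id=rec.patient_id,
    )


def reject_artifacts(
    ep: EpochArray, amp_threshold_factor: float = 8.0
) -> EpochArray:
    """Remove epochs whose peak amplitude is an outlier on any channel.

    An epoch is rejected when, on any channel, its peak absolute amplitude
    exceeds ``amp_threshold_factor`` times the median across epochs of that
    channel's per-epoch RMS.  The rule targets eye-movement, muscle and
    drift transients, which are large relative to the ongoing background.
    """
    if ep.n_epochs == 0:
        raise EmptyInputError("no epochs to screen")
    if amp_threshold_factor <= 0:
        raise InvalidArgumentError("amp_threshold_factor must be positive")
    rms = np.sqrt(np.mean(ep.data**2, axis=2))        # channels x epochs
    med_rms = np.median(rms, axis=1, keepdims=True)   # channels x 1
    peak = np.max(np.abs(ep.data), axis=2)            # channels x epochs
    bad = np.any(peak > amp_threshold_factor * med_rms, axis=0)
    keep = np.flatnonzero(~bad)
    if keep.size == 0:
        warnings.warn("all epochs rejected as artifactual", stacklevel=2)
    return ep.select(keep)


def usable_data_filter(
    ep_pre: EpochArray,
    ep_post: EpochArray,
    clinical: "ClinicalRecord | None",
    min_epochs: int = 60,
) -> bool:
    """Inclusion rule: both sessions at or above the clean-epoch floor on all
    channels, and a complete clinical record."""
    if ep_pre.n_epochs < min_epochs or ep_post.n_epochs < min_epochs:
        return False
    if clinical is None:
        return False
    return clinical.is_complete()


def match_epoch_counts(
    ep_pre: EpochArray, ep_post: EpochArray, seed: int
) -> tuple[EpochArray, EpochArray]:
    """Equalize epoch counts by subsampling the larger session.

    The larger session is subsampled uniformly without replacement down to
    ``min(n_pre, n_post)``; selection is seeded and reproducible, and the
    retained epochs keep their original order.
    """
    if ep_pre.n_epochs == 0 or ep_post.n_epochs == 0:
        raise EmptyInputError("cannot match epoch counts with an empty session")
    n = min(ep_pre.n_epochs, ep_post.n_epochs)
    rng = np.random.default_rng(seed)

    def subsample(ep: EpochArray) -> EpochArray:
        if ep.n_epochs == n:
            return ep
        pos = rng.choice(ep.n_epochs, size=n, replace=False)
        return ep.select(np.sort(pos))

    return subsample(ep_pre), subsample(ep_post)
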