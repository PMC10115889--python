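"""File I/O: recordings (CSV, EDF), clinical tables, results tables.

CSV recordings are rows = samples, columns = channels, with a leading
comment line carrying the sampling rate.  EDF reading goes through MNE;
EDF writing uses a small built-in 16-bit EDF writer (header + int16 data
records per the EDF interchange format).  Result tables are TSV with a
leading ``# config_hash:`` comment so every output can be traced to the
exact configuration that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidArgumentError
from .preprocess import RawRecording
from .stats import ClinicalRecord

REQUIRED_CLINICAL_COLUMNS = (
    "patient_id", "pcl5_pre", "pcl5_post", "ids_sr_pre", "ids_sr_post",
)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    """Samples x channels CSV with ``# fs=<Hz>`` header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.8g")


def read_recording_csv(path: str | Path) -> RawRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise FormatError(f"{path}: line 1: expected '# fs=<Hz>' header")
        try:
            fs = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line 1: unparseable fs") from exc
        labels = tuple(s.strip() for s in fh.readline().strip().split(","))
        if not labels or labels == ("",):
            raise FormatError(f"{path}: line 2: missing channel labels")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return RawRecording(data=data.T, fs=fs, channel_labels=labels)


def write_recording_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a 16-bit EDF file (whole-second recordings; µV physical units)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_records = rec.n_samples // fs_i
    if n_records * fs_i != rec.n_samples:
        raise InvalidArgumentError(
            "EDF writer requires a whole number of 1-s records"
        )
    n_sig = rec.n_channels
    phys_min = np.floor(rec.data.min(axis=1)) - 1.0
    phys_max = np.ceil(rec.data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise InvalidArgumentError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            fixed("0", 8),
            fixed("X X X X", 80),
            fixed("Startdate X X X X", 80),
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 * (1 + n_sig)), 8),
            fixed("", 44),
            fixed(str(n_records), 8),
            fixed("1", 8),
            fixed(str(n_sig), 4),
        ]
    )
    sig = b"".join(fixed(lab, 16) for lab in rec.channel_labels)
    sig += b"".join(fixed("", 80) for _ in range(n_sig))
    sig += b"".join(fixed("uV", 8) for _ in range(n_sig))
    sig += b"".join(fixed(f"{phys_min[i]:g}", 8) for i in range(n_sig))
    sig += b"".join(fixed(f"{phys_max[i]:g}", 8) for i in range(n_sig))
    sig += b"".join(fixed(str(dig_min), 8) for _ in range(n_sig))
    sig += b"".join(fixed(str(dig_max), 8) for _ in range(n_sig))
    sig += b"".join(fixed("", 80) for _ in range(n_sig))
    sig += b"".join(fixed(str(fs_i), 8) for _ in range(n_sig))
    sig += b"".join(fixed("", 32) for _ in range(n_sig))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round(
        (rec.data - phys_min[:, None]) / gain[:, None] + dig_min
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for ch in range(n_sig):
                fh.write(digital[ch, r * fs_i : (r + 1) * fs_i].tobytes())


def read_recording_edf(path: str | Path) -> RawRecording:
    """Read an EDF recording via MNE; data returned in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    return RawRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Load a recording, inferring the format from the suffix if not given."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "edf":
        return read_recording_edf(path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")


def check_channels(
    rec: RawRecording, required: tuple[str, ...]
) -> None:
    """Raise with the missing labels if the montage is incomplete."""
    missing = [c for c in required if c not in rec.channel_labels]
    if missing:
        raise FormatError(
            f"recording is missing required electrode(s): {', '.join(missing)}"
        )


# ---------------------------------------------------------------------------
# clinical + tables
# ---------------------------------------------------------------------------

def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                pcl5_pre=_maybe(row["pcl5_pre"]),
                pcl5_post=_maybe(row["pcl5_post"]),
                ids_sr_pre=_maybe(row["ids_sr_pre"]),
                ids_sr_post=_maybe(row["ids_sr_post"]),
            )
        )
    return out


def _maybe(v) -> float | None:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) else None


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "pcl5_pre": r.pcl5_pre,
            "pcl5_post": r.pcl5_post,
            "ids_sr_pre": r.ids_sr_pre,
            "ids_sr_post": r.ids_sr_post,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_table(
    df: pd.DataFrame, path: str | Path, config_hash: str | None = None
) -> None:
    """TSV with an optional leading config-hash comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_bursts_tsv(truth, path: str | Path) -> None:
    """Ground-truth burst table: one injected burst per row."""
    rows = [
        {
            "channel": b.channel,
            "epoch_index": e,
            "center_time": b.center_time,
            "center_freq": b.center_freq,
            "envelope_sd": b.envelope_sd,
            "amplitude": b.amplitude,
        }
        for b, e in zip(truth.bursts, truth.burst_epochs)
    ]
    pd.DataFrame(
        rows,
        columns=["channel", "epoch_index", "center_time", "center_freq",
                 "envelope_sd", "amplitude"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def save_tfr_npz(tfr, path: str | Path) -> None:
    """Binary TFR container with the frequency/time axes in metadata."""
    np.savez_compressed(
        path,
        power=tfr.power,
        freqs=tfr.freqs,
        times=tfr.times,
        meta=json.dumps(
            {
                "fs": tfr.fs,
                "electrode": tfr.electrode,
                "normalized": bool(tfr.normalized),
                "session": tfr.session,
                "patient_id": tfr.patient_id,
            }
        ),
    )


def load_tfr_npz(path: str | Path):
    from .tfr import TFRStack

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return TFRStack(
            power=z["power"], freqs=z["freqs"], times=z["times"],
            fs=meta["fs"], electrode=meta["electrode"],
            normalized=meta["normalized"], session=meta["session"],
            patient_id=meta["patient_id"],
        )
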