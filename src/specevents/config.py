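"""Pipeline configuration.

All analysis constants live here: acquisition parameters (500 Hz sampling,
0.5–50 Hz acquisition band), the 2-s epoching, the 1–45 Hz wavelet grid with
7-cycle Morlet kernels, the three bands of interest (delta/theta 1–6 Hz,
alpha 7–14 Hz, beta 15–29 Hz), the 6x factor-of-median detection threshold,
the 60-epoch usable-data floor, and the Q = 0.05 FDR level.  A config
round-trips losslessly through JSON or YAML so a run can be reproduced from
its serialized config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

#: Standard 8-electrode montage used throughout (frontal-polar, frontal,
#: central, parietal, occipital midline coverage).
DEFAULT_ELECTRODES: tuple[str, ...] = (
    "FP1", "FP2", "FPz", "F3", "Fz", "Cz", "Pz", "Oz",
)


@dataclass(frozen=True)
class BandDef:
    """A band of interest (BOI) on the integer frequency grid, inclusive."""

    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, inclusive

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def rows(self, freqs: Sequence[float]) -> list[int]:
        """Indices of grid frequencies inside the band (inclusive ends)."""
        idx = [i for i, f in enumerate(freqs) if self.lo <= f <= self.hi]
        if not idx:
            raise ValueError(f"band {self.name} outside frequency grid")
        return idx


DEFAULT_BANDS: tuple[BandDef, ...] = (
    BandDef("delta_theta", 1.0, 6.0),
    BandDef("alpha", 7.0, 14.0),
    BandDef("beta", 15.0, 29.0),
)

FEATURES: tuple[str, ...] = ("number", "power", "duration", "span")


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with its default."""

    fs: float = 500.0                 # Hz, sampling rate
    epoch_length: float = 2.0         # s, non-overlapping epochs
    hp_hz: float = 0.5                # Hz, acquisition high-pass (metadata)
    lp_hz: float = 50.0               # Hz, acquisition low-pass (metadata)
    freq_lo: float = 1.0              # Hz, wavelet grid start
    freq_hi: float = 45.0             # Hz, wavelet grid end
    freq_step: float = 1.0            # Hz, wavelet grid spacing
    n_cycles: float = 7.0             # Morlet cycles
    kernel_sd_truncation: float = 4.0  # kernel support = +/- this many sigma_t
    threshold_fom: float = 6.0        # detection threshold, factors of median
    connectivity: int = 8             # suprathreshold-region connectivity
    min_epochs: int = 60              # usable-data floor per session
    artifact_threshold_factor: float = 8.0  # peak amp / median epoch RMS
    q_fdr: float = 0.05               # BH false-discovery level
    trend_hi: float = 0.08            # trending band: q_fdr < p_c < trend_hi
    pcl5_change_mode: str = "raw"     # PCL-5 association uses raw score change
    ids_change_mode: str = "percent"  # IDS-SR association uses percent change
    pool_scales_in_bh: bool = False   # BH family per clinical scale (96 tests)
    tfr_dtype: str = "float32"        # compute dtype for wavelet transforms
    seed_cohort: int = 0
    seed_subsample: int = 0
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    bands: tuple[BandDef, ...] = DEFAULT_BANDS

    # -- derived ----------------------------------------------------------
    @property
    def freqs(self) -> tuple[float, ...]:
        n = int(round((self.freq_hi - self.freq_lo) / self.freq_step)) + 1
        return tuple(self.freq_lo + i * self.freq_step for i in range(n))

    def band(self, name: str) -> BandDef:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        d["electrodes"] = list(self.electrodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["bands"] = tuple(BandDef(**b) for b in d.get("bands", []))
        d["electrodes"] = tuple(d.get("electrodes", DEFAULT_ELECTRODES))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
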