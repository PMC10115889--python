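"""End-to-end orchestration.

For each patient: segment both sessions into 2-s epochs, reject artifact
epochs, apply the usable-data filter (>= 60 clean epochs per session on all
channels plus a complete clinical record), match epoch counts between
sessions, compute Morlet TFRs per electrode, pool both sessions into the
PSD and band powers, FOM-normalize per session, detect spectral events per
band, and summarize the four event features.  Cohort-level statistics
(RM-ANOVA on band power, paired t-tests, change and baseline correlation
tables with BH correction) run on the pooled summaries.

Any per-patient failure is recorded and the pipeline continues with the
remaining patients.  Given fixed seeds the whole run is deterministic.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import events as ev
from . import io as sio
from . import preprocess as pp
from . import stats as st
from . import tfr as tf
from .config import FEATURES, PipelineConfig
from .exceptions import SpecEventsError

logger = logging.getLogger(__name__)


@dataclass
class PatientInput:
    patient_id: str
    rec_pre: pp.RawRecording
    rec_post: pp.RawRecording
    clinical: st.ClinicalRecord


@dataclass
class PatientResult:
    patient_id: str
    included: bool
    reason: str | None
    n_epochs: int
    summaries: pd.DataFrame | None = None       # electrode x band features
    psd: pd.DataFrame | None = None             # electrode x frequency
    band_power: pd.DataFrame | None = None      # session x electrode x band
    events: pd.DataFrame | None = None
    manifest: pd.DataFrame | None = None        # per-epoch kept/rejected


@dataclass
class CohortResult:
    config: PipelineConfig
    summaries: pd.DataFrame
    clinical: pd.DataFrame
    psd: pd.DataFrame
    band_power: pd.DataFrame
    events: pd.DataFrame | None
    manifest: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)


def _subsample_seed(config: PipelineConfig, patient_id: str) -> int:
    """Stable per-patient seed for epoch-count matching."""
    return (config.seed_subsample * 2654435761 + zlib.crc32(patient_id.encode())) % (
        2**31
    )


def events_to_frame(event_list: list[ev.SpectralEvent]) -> pd.DataFrame:
    cols = [
        "patient_id", "session", "electrode", "band", "epoch_index",
        "peak_time", "peak_freq", "maxima_power_fom", "duration_ms",
        "freq_span_hz", "onset", "offset", "f_lo", "f_hi", "time_edge",
        "freq_edge", "n_tied_maxima",
    ]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in event_list], columns=cols
    )


def analyze_patient(
    patient: PatientInput,
    config: PipelineConfig,
    store_events: bool = True,
) -> PatientResult:
    """Run the single-patient portion of the pipeline."""
    pid = patient.patient_id
    manifest_rows = []
    eps = {}
    for session, rec in (("pre", patient.rec_pre), ("post", patient.rec_post)):
        sio.check_channels(rec, config.electrodes)
        segmented = pp.segment_epochs(rec, config.epoch_length)
        clean = pp.reject_artifacts(segmented, config.artifact_threshold_factor)
        kept = set(clean.kept_epoch_indices)
        for i in segmented.kept_epoch_indices:
            manifest_rows.append(
                {
                    "patient_id": pid,
                    "session": session,
                    "epoch_index": i,
                    "kept": i in kept,
                    "reason": "" if i in kept else "amplitude_artifact",
                }
            )
        eps[session] = clean
    manifest = pd.DataFrame(manifest_rows)

    if not pp.usable_data_filter(
        eps["pre"], eps["post"], patient.clinical, config.min_epochs
    ):
        reason = (
            "incomplete_clinical"
            if not (patient.clinical and patient.clinical.is_complete())
            else "below_min_epochs"
        )
        return PatientResult(pid, False, reason, 0, manifest=manifest)

    ep_pre, ep_post = pp.match_epoch_counts(
        eps["pre"], eps["post"], _subsample_seed(config, pid)
    )
    n_epochs = ep_pre.n_epochs

    freqs = config.freqs
    summary_rows, psd_rows, bp_rows, all_events = [], [], [], []
    tfr_pre = tf.compute_tfr_all(
        ep_pre, freqs, config.n_cycles, config.kernel_sd_truncation,
        config.tfr_dtype,
    )
    tfr_post = tf.compute_tfr_all(
        ep_post, freqs, config.n_cycles, config.kernel_sd_truncation,
        config.tfr_dtype,
    )
    for electrode in config.electrodes:
        pair = (tfr_pre[electrode], tfr_post[electrode])
        psd = tf.compute_psd(pair)
        psd_rows.extend(
            {"patient_id": pid, "electrode": electrode, "freq": f, "power": p}
            for f, p in zip(freqs, psd)
        )
        for session, stack in zip(("pre", "post"), pair):
            session_psd = tf.compute_psd([stack])
            for band in config.bands:
                bp_rows.append(
                    {
                        "patient_id": pid,
                        "session": session,
                        "electrode": electrode,
                        "band": band.name,
                        "band_power": tf.band_power(session_psd, freqs, band),
                    }
                )
            norm = tf.normalize_fom(stack)
            for band in config.bands:
                det = ev.detect_events_band(
                    norm, band, config.threshold_fom, config.connectivity
                )
                summ = ev.summarize_features(
                    det, n_epochs, band.name, pid, session, electrode
                )
                summary_rows.append(
                    {
                        "patient_id": pid,
                        "session": session,
                        "electrode": electrode,
                        "band": band.name,
                        "n_epochs": n_epochs,
                        "n_events": summ.n_events,
                        "number": summ.number,
                        "power": summ.power,
                        "duration": summ.duration,
                        "span": summ.span,
                    }
                )
                if store_events:
                    all_events.extend(det)
    return PatientResult(
        patient_id=pid,
        included=True,
        reason=None,
        n_epochs=n_epochs,
        summaries=pd.DataFrame(summary_rows),
        psd=pd.DataFrame(psd_rows),
        band_power=pd.DataFrame(bp_rows),
        events=events_to_frame(all_events) if store_events else None,
        manifest=manifest,
    )


def analyze_cohort(
    patients: Iterable[PatientInput],
    config: PipelineConfig,
    store_events: bool = True,
) -> CohortResult:
    """Run every patient (streaming) and pool summaries."""
    summaries, psds, bps, evts, manifests, clin_rows = [], [], [], [], [], []
    excluded = []
    for patient in patients:
        pid = patient.patient_id
        try:
            res = analyze_patient(patient, config, store_events)
        except SpecEventsError as exc:
            logger.warning("patient %s failed: %s", pid, exc)
            excluded.append((pid, f"error: {exc}"))
            continue
        if res.manifest is not None:
            manifests.append(res.manifest)
        if not res.included:
            logger.info("patient %s excluded: %s", pid, res.reason)
            excluded.append((pid, res.reason or "excluded"))
            continue
        summaries.append(res.summaries)
        psds.append(res.psd)
        bps.append(res.band_power)
        if store_events and res.events is not None:
            evts.append(res.events)
        c = patient.clinical
        clin_rows.append(
            {
                "patient_id": pid,
                "pcl5_pre": c.pcl5_pre,
                "pcl5_post": c.pcl5_post,
                "ids_sr_pre": c.ids_sr_pre,
                "ids_sr_post": c.ids_sr_post,
            }
        )
    empty = pd.DataFrame()
    return CohortResult(
        config=config,
        summaries=pd.concat(summaries, ignore_index=True) if summaries else empty,
        clinical=pd.DataFrame(clin_rows),
        psd=pd.concat(psds, ignore_index=True) if psds else empty,
        band_power=pd.concat(bps, ignore_index=True) if bps else empty,
        events=pd.concat(evts, ignore_index=True) if evts else None,
        manifest=pd.concat(manifests, ignore_index=True) if manifests else empty,
        excluded=excluded,
    )


def paired_t_table(result: CohortResult) -> pd.DataFrame:
    """Pre vs post paired t-tests for every correction-space cell, with BH
    correction across the 96-cell space."""
    config = result.config
    rows = []
    for feature in FEATURES:
        for electrode in config.electrodes:
            for band in [b.name for b in config.bands]:
                cell = result.summaries[
                    (result.summaries["electrode"] == electrode)
                    & (result.summaries["band"] == band)
                ]
                wide = cell.pivot(
                    index="patient_id", columns="session", values=feature
                ).dropna()
                if len(wide) >= 3 and {"pre", "post"} <= set(wide.columns):
                    res = st.paired_t(
                        wide["pre"].to_numpy(), wide["post"].to_numpy()
                    )
                    t_val, p_val, n = res.statistic, res.p, len(wide)
                else:
                    t_val, p_val, n = np.nan, np.nan, len(wide)
                rows.append(
                    {
                        "family": "paired_t",
                        "feature": feature,
                        "electrode": electrode,
                        "band": band,
                        "n": n,
                        "t": t_val,
                        "p": p_val,
                    }
                )
    table = pd.DataFrame(rows)
    valid = table["p"].notna().to_numpy()
    p_c = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    trend = np.zeros(len(table), dtype=bool)
    if valid.any():
        p_c[valid], sig[valid], trend[valid] = st.bh_adjust(
            table.loc[valid, "p"].to_numpy(), config.q_fdr, config.trend_hi
        )
    table["p_c"], table["significant"], table["trending"] = p_c, sig, trend
    return table


def anova_tables(result: CohortResult) -> pd.DataFrame:
    """Two-way RM-ANOVA (time x electrode) on band power, one per band."""
    config = result.config
    out = []
    bp = result.band_power
    for band in config.bands:
        sub = bp[bp["band"] == band.name]
        wide = sub.pivot_table(
            index="patient_id", columns=["session", "electrode"],
            values="band_power",
        )
        pats = wide.dropna().index
        arr = np.empty((len(pats), 2, len(config.electrodes)))
        for ti, session in enumerate(("pre", "post")):
            for eij, e in enumerate(config.electrodes):
                arr[:, ti, eij] = wide.loc[pats, (session, e)].to_numpy()
        table = st.rm_anova_band_power(arr)
        table.insert(0, "band", band.name)
        out.append(table)
    return pd.concat(out, ignore_index=True)


def run_stats(result: CohortResult) -> dict[str, pd.DataFrame]:
    """All cohort statistics from pooled summaries + clinical records."""
    config = result.config
    change = pd.concat(
        [
            st.correlate_feature_changes(
                result.summaries, result.clinical, scale, config
            )
            for scale in st.SCALES
        ],
        ignore_index=True,
    )
    baseline = pd.concat(
        [
            st.correlate_baseline(
                result.summaries, result.clinical, scale, config
            )
            for scale in st.SCALES
        ],
        ignore_index=True,
    )
    responders = []
    for _, row in result.clinical.iterrows():
        rec = st.ClinicalRecord(
            row.patient_id, row.pcl5_pre, row.pcl5_post,
            row.ids_sr_pre, row.ids_sr_post,
        )
        pcl, ids = st.classify_response(rec)
        responders.append(
            {
                "patient_id": row.patient_id,
                "pcl5_responder": pcl,
                "ids_responder": ids,
                "pcl5_change": row.pcl5_post - row.pcl5_pre,
                "ids_pct_change": st.percent_change(
                    row.ids_sr_pre, row.ids_sr_post
                ),
            }
        )
    return {
        "stats_change": change,
        "stats_baseline": baseline,
        "paired_t": paired_t_table(result),
        "anova": anova_tables(result),
        "responders": pd.DataFrame(responders),
    }


def write_results(
    result: CohortResult,
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.config.hash()
    sio.write_table(result.summaries, out / "features.tsv", h)
    sio.write_table(result.psd, out / "psd.tsv", h)
    sio.write_table(result.band_power, out / "band_power.tsv", h)
    sio.write_table(result.manifest, out / "epoch_manifest.tsv", h)
    if result.events is not None:
        sio.write_table(result.events, out / "events.tsv", h)
    for name, df in tables.items():
        sio.write_table(df, out / f"{name}.tsv", h)
    sio.write_json(
        {
            "config": result.config.to_dict(),
            "config_hash": h,
            "n_included": int(result.clinical.shape[0]),
            "excluded": [list(x) for x in result.excluded],
        },
        out / "run.json",
    )


def load_manifest(manifest_path: str | Path) -> Iterator[PatientInput]:
    """Manifest CSV: patient_id, pre_path, post_path + clinical columns."""
    df = pd.read_csv(manifest_path, comment="#")
    base = Path(manifest_path).parent
    for _, row in df.iterrows():
        def _resolve(p: str) -> Path:
            path = Path(p)
            return path if path.is_absolute() else base / path

        yield PatientInput(
            patient_id=str(row["patient_id"]),
            rec_pre=sio.read_recording(_resolve(row["pre_path"])),
            rec_post=sio.read_recording(_resolve(row["post_path"])),
            clinical=st.ClinicalRecord(
                patient_id=str(row["patient_id"]),
                pcl5_pre=sio._maybe(row.get("pcl5_pre")),
                pcl5_post=sio._maybe(row.get("pcl5_post")),
                ids_sr_pre=sio._maybe(row.get("ids_sr_pre")),
                ids_sr_post=sio._maybe(row.get("ids_sr_post")),
            ),
        )


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
    store_events: bool = True,
) -> CohortResult:
    """File-based end-to-end run: manifest in, result tables out."""
    result = analyze_cohort(load_manifest(manifest_path), config, store_events)
    tables = run_stats(result)
    write_results(result, tables, out_dir)
    return result
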