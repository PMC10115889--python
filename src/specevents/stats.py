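"""Cohort-level statistics.

Implements the inference layer of the analysis: pre/post percent changes,
responder classification (PCL-5 raw reduction > 10 points; IDS-SR percent
reduction >= 50%), two-way repeated-measures ANOVA on band power (time x
electrode), paired t-tests on event features, Pearson correlations between
event-feature changes (or baselines) and clinical-score changes, and
Benjamini–Hochberg step-up FDR correction over the full correction space of
4 features x 8 electrodes x 3 bands = 96 tests per clinical scale.

Library use: paired t and Pearson via scipy.stats, BH adjustment via
statsmodels, repeated-measures ANOVA via pingouin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import FEATURES, PipelineConfig
from .exceptions import DegenerateInputError, InvalidArgumentError

logger = logging.getLogger(__name__)

SCALES = ("PCL5", "IDSSR")


@dataclass
class ClinicalRecord:
    """Pre/post symptom scores for one patient.

    PCL-5 is the PTSD symptom checklist, IDS-SR the self-reported depression
    inventory; lower is better on both.
    """

    patient_id: str
    pcl5_pre: float | None
    pcl5_post: float | None
    ids_sr_pre: float | None
    ids_sr_post: float | None

    def is_complete(self) -> bool:
        vals = (self.pcl5_pre, self.pcl5_post, self.ids_sr_pre, self.ids_sr_post)
        return all(v is not None and np.isfinite(v) for v in vals)


@dataclass
class StatResult:
    """One test of the statistical layer (correlation or paired t)."""

    family: str                  # anova | paired_t | corr_change | corr_baseline
    feature: str | None
    electrode: str | None
    band: str | None
    scale: str | None            # PCL5 | IDSSR | None
    statistic: float
    r: float | None
    p: float
    p_c: float | None = None
    significant: bool | None = None
    trending: bool | None = None
    n: int | None = None


def percent_change(pre, post):
    """100 x (post - pre) / pre; negative means a decrease.

    Works elementwise on arrays.  A zero ``pre`` is degenerate and raises.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if np.any(pre_arr == 0):
        raise DegenerateInputError("percent change undefined for pre = 0")
    out = 100.0 * (post_arr - pre_arr) / pre_arr
    return float(out) if out.ndim == 0 else out


def _pct_change_or_nan(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Vectorized percent change mapping pre==0 or missing data to NaN."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (post - pre) / pre
    out[~np.isfinite(out)] = np.nan
    return out


def classify_response(rec: ClinicalRecord) -> tuple[bool, bool]:
    """(PCL-5 responder, IDS-SR responder).

    PCL-5 response is a raw reduction strictly greater than 10 points;
    IDS-SR response is a percent reduction of at least 50%.
    """
    if not rec.is_complete():
        raise InvalidArgumentError(f"incomplete clinical record {rec.patient_id}")
    pcl = (rec.pcl5_pre - rec.pcl5_post) > 10.0
    ids = percent_change(rec.ids_sr_pre, rec.ids_sr_post) <= -50.0
    return bool(pcl), bool(ids)


def paired_t(pre: np.ndarray, post: np.ndarray) -> StatResult:
    """Two-sided paired t-test of post vs pre.

    With a constant nonzero difference the statistic is unbounded; the
    result reports p = 0 (and t = ±inf).  With identical vectors t = 0 and
    p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise InvalidArgumentError("pre/post length mismatch")
    if pre.size < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    d = post - pre
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return StatResult("paired_t", None, None, None, None, 0.0, None, 1.0)
        t = math.inf if d[0] > 0 else -math.inf
        return StatResult("paired_t", None, None, None, None, t, None, 0.0)
    t, p = sps.ttest_rel(post, pre)
    return StatResult(
        "paired_t", None, None, None, None, float(t), None, float(p),
        n=pre.size,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("length mismatch")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(
    pvals, q: float = 0.05, trend_hi: float = 0.08
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values over one family.

    Returns (p_c, significant, trending): p_c(i) = min_{j: p_j >= p_i ranked}
    (m/rank_j)·p_j capped at 1; significant iff p_c < q; trending iff
    q < p_c < trend_hi.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, bool), np.zeros(0, bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    _, p_c, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    significant = p_c < q
    trending = (p_c > q) & (p_c < trend_hi)
    return p_c, significant, trending


def rm_anova_band_power(band_power: np.ndarray) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on band power.

    ``band_power`` is patients x time(2: pre, post) x electrodes.  Returns
    the pingouin ANOVA table with main effects of time and electrode and
    their interaction; sphericity is handled by the Greenhouse–Geisser
    correction columns pingouin reports.
    """
    bp = np.asarray(band_power, dtype=float)
    if bp.ndim != 3 or bp.shape[1] != 2:
        raise InvalidArgumentError("expected patients x 2 x electrodes array")
    if not np.all(np.isfinite(bp)):
        raise InvalidArgumentError("missing cells in within-subject design")
    import pingouin as pg

    n_pat, _, n_el = bp.shape
    rows = [
        {
            "subject": i,
            "time": t,
            "electrode": e,
            "power": bp[i, ti, e],
        }
        for i in range(n_pat)
        for ti, t in enumerate(("pre", "post"))
        for e in range(n_el)
    ]
    df = pd.DataFrame(rows)
    return pg.rm_anova(
        dv="power", within=["time", "electrode"], subject="subject",
        data=df, detailed=True,
    )


# ---------------------------------------------------------------------------
# Correlation pipeline over the 4 x 8 x 3 correction space
# ---------------------------------------------------------------------------

def _clinical_change(
    clinical: pd.DataFrame, scale: str, config: PipelineConfig
) -> pd.Series:
    """Per-patient clinical change on the requested scale.

    IDS-SR uses percent change by default; PCL-5 uses raw score change
    (post - pre) by default.  Negative values are improvement on both.
    """
    if scale == "IDSSR":
        mode = config.ids_change_mode
        pre, post = clinical["ids_sr_pre"], clinical["ids_sr_post"]
    elif scale == "PCL5":
        mode = config.pcl5_change_mode
        pre, post = clinical["pcl5_pre"], clinical["pcl5_post"]
    else:
        raise InvalidArgumentError(f"unknown scale {scale!r}")
    if mode == "percent":
        vals = _pct_change_or_nan(pre.to_numpy(), post.to_numpy())
    elif mode == "raw":
        vals = post.to_numpy(dtype=float) - pre.to_numpy(dtype=float)
    else:
        raise InvalidArgumentError(f"unknown change mode {mode!r}")
    return pd.Series(vals, index=clinical["patient_id"].to_numpy())


def _correlation_table(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    scale: str,
    config: PipelineConfig,
    baseline: bool,
) -> pd.DataFrame:
    family = "corr_baseline" if baseline else "corr_change"
    y = _clinical_change(clinical, scale, config)
    bands = [b.name for b in config.bands]
    # one pivot for the whole correction space: columns are
    # (feature, session, electrode, band), rows are patients
    piv = summaries.pivot_table(
        index="patient_id",
        columns=["session", "electrode", "band"],
        values=list(FEATURES),
    )
    pats = piv.index
    yv = y.reindex(pats).to_numpy(dtype=float)
    n_y = int(np.isfinite(yv).sum())
    nan_col = np.full(len(pats), np.nan)

    def col(feature, session, electrode, band):
        key = (feature, session, electrode, band)
        if key in piv.columns:
            return piv[key].to_numpy(dtype=float)
        return nan_col

    rows = []
    for feature in FEATURES:
        for electrode in config.electrodes:
            for band in bands:
                pre = col(feature, "pre", electrode, band)
                if baseline:
                    x = pre
                else:
                    post = col(feature, "post", electrode, band)
                    x = _pct_change_or_nan(pre, post)
                ok = np.isfinite(x) & np.isfinite(yv)
                n = int(ok.sum())
                if n_y - n > 0:
                    logger.warning(
                        "%s %s/%s/%s/%s: %d patient(s) excluded pairwise",
                        family, scale, feature, electrode, band, n_y - n,
                    )
                if n >= 3 and np.std(x[ok]) > 0 and np.std(yv[ok]) > 0:
                    r, p = pearson(x[ok], yv[ok])
                else:
                    r, p = np.nan, np.nan
                rows.append(
                    {
                        "family": family,
                        "scale": scale,
                        "feature": feature,
                        "electrode": electrode,
                        "band": band,
                        "n": n,
                        "r": r,
                        "r2": r * r if np.isfinite(r) else np.nan,
                        "p": p,
                    }
                )
    table = pd.DataFrame(rows)
    valid = table["p"].notna().to_numpy()
    p_c = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    trend = np.zeros(len(table), dtype=bool)
    if valid.any():
        p_c[valid], sig[valid], trend[valid] = bh_adjust(
            table.loc[valid, "p"].to_numpy(), config.q_fdr, config.trend_hi
        )
    table["p_c"] = p_c
    table["significant"] = sig
    table["trending"] = trend
    return table.sort_values(
        ["p_c", "p"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def correlate_feature_changes(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    scale: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Pearson tests of feature percent change vs clinical change.

    One test per (feature, electrode, band) — the full 96-cell correction
    space — BH-corrected across the space, sorted by adjusted p.
    """
    config = config or PipelineConfig()
    return _correlation_table(summaries, clinical, scale, config, baseline=False)


def correlate_baseline(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    scale: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """As correlate_feature_changes but with pre-treatment feature levels."""
    config = config or PipelineConfig()
    return _correlation_table(summaries, clinical, scale, config, baseline=True)


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabulate ClinicalRecords (one row per patient)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "pcl5_pre": r.pcl5_pre,
                "pcl5_post": r.pcl5_post,
                "ids_sr_pre": r.ids_sr_pre,
                "ids_sr_post": r.ids_sr_post,
            }
            for r in records
        ]
    )
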