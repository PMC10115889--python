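"""Inference layer: percent change, responders, t/r/ANOVA, BH, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import specevents as se
from specevents.stats import SCALES, ClinicalRecord, clinical_to_frame
from specevents.synth import CohortSpec, gen_latent_cohort

from oracles import bh_stepup, paired_t_formula


def _record(pcl=(50, 30), ids=(40, 18), pid="P0"):
    return ClinicalRecord(pid, pcl[0], pcl[1], ids[0], ids[1])


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected", [(10, 5, -50.0), (10, 10, 0.0), (20, 25, 25.0)]
    )
    def test_values(self, pre, post, expected):
        assert se.percent_change(pre, post) == expected

    def test_zero_pre_degenerate(self):
        with pytest.raises(se.DegenerateInputError):
            se.percent_change(0, 5)

    def test_cohort_mean_matches_generator(self):
        spec = CohortSpec(n_patients=400, target_r=0.0, seed=17)
        _, records, _ = gen_latent_cohort(spec)
        changes = [
            se.percent_change(r.ids_sr_pre, r.ids_sr_post) for r in records
        ]
        assert np.mean(changes) == pytest.approx(
            spec.clinical_mean_ids_pct, abs=3 * spec.clinical_sd_ids_pct / 20
        )


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "pcl,expected", [((50, 39), True), ((50, 40), False)]
    )
    def test_pcl5_strict_ten_point_rule(self, pcl, expected):
        assert se.classify_response(_record(pcl=pcl))[0] is expected

    @pytest.mark.parametrize(
        "ids,expected", [((40, 20), True), ((40, 21), False)]
    )
    def test_ids_inclusive_fifty_percent_rule(self, ids, expected):
        assert se.classify_response(_record(ids=ids))[1] is expected

    def test_incomplete_record_rejected(self):
        rec = ClinicalRecord("P0", 50, None, 40, 20)
        with pytest.raises(se.InvalidArgumentError):
            se.classify_response(rec)


class TestPairedT:
    def test_identical_vectors(self):
        res = se.paired_t(np.arange(5.0), np.arange(5.0))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_shift_degenerate(self):
        pre = np.array([1.0, 5.0, 2.0, 7.0])
        res = se.paired_t(pre, pre + 3.0)
        assert res.p == 0.0

    def test_matches_explicit_formula(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(10, 2, size=12)
        post = pre + rng.normal(0.5, 1, size=12)
        res = se.paired_t(pre, post)
        assert res.statistic == pytest.approx(
            paired_t_formula(pre.tolist(), post.tolist()), rel=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(se.InvalidArgumentError):
            se.paired_t(np.arange(4.0), np.arange(5.0))


class TestPearson:
    def test_perfect_linear(self):
        r, p = se.pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(0)
        r, _ = se.pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_zero_variance_degenerate(self):
        with pytest.raises(se.DegenerateInputError):
            se.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBHAdjust:
    def test_hand_enumerated_example(self):
        # ranks 1..4, m=4: adjusted = min_{j>=i} (4/j) p_(j) = 0.04 for all
        p_c, sig, _ = se.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(p_c, 0.04)
        assert sig.all()

    def test_single_p_unchanged(self):
        p_c, _, _ = se.bh_adjust([0.2])
        assert p_c[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        p_c, _, _ = se.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_c[order]) >= -1e-15)

    def test_trending_band(self):
        # adjusted p for the middle test is (3/2)*0.04 = 0.06: trending
        p_c, sig, trend = se.bh_adjust([0.001, 0.04, 0.9])
        assert sig[0] and not sig[1]
        assert trend[1] and not trend[2]

    def test_invalid_p_rejected(self):
        with pytest.raises(se.InvalidArgumentError):
            se.bh_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_brute_force_stepup(self, pvals):
        p_c, _, _ = se.bh_adjust(pvals)
        assert np.allclose(p_c, bh_stepup(pvals), rtol=1e-12, atol=1e-12)


class TestRMAnova:
    def _simulate(self, rng, time_shift=0.0, n_pat=12, n_el=4):
        offsets = rng.normal(0, 2.0, size=n_el)  # large electrode effects
        subj = rng.normal(0, 1.0, size=(n_pat, 1, 1))
        noise = rng.normal(0, 0.5, size=(n_pat, 2, n_el))
        data = subj + offsets[None, None, :] + noise
        data[:, 1, :] += time_shift
        return data

    def test_identical_sessions_zero_time_f(self):
        rng = np.random.default_rng(0)
        data = self._simulate(rng)
        data[:, 1, :] = data[:, 0, :]
        table = se.rm_anova_band_power(data)
        f_time = table.loc[table.Source == "time", "F"].iloc[0]
        assert f_time == pytest.approx(0.0, abs=1e-9)

    def test_large_time_shift_detected(self):
        rng = np.random.default_rng(1)
        table = se.rm_anova_band_power(self._simulate(rng, time_shift=5.0))
        p_time = table.loc[table.Source == "time", "p_unc"].iloc[0]
        assert p_time < 0.001

    def test_null_time_p_uniform(self):
        # KS calibration: with no true time effect the time-effect p-value
        # should be uniform over repeated simulated cohorts
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            table = se.rm_anova_band_power(self._simulate(rng))
            pvals.append(table.loc[table.Source == "time", "p_unc"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_cells_rejected(self):
        data = np.ones((5, 2, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(se.InvalidArgumentError):
            se.rm_anova_band_power(data)


class TestCorrelationPipeline:
    def test_row_count_is_full_correction_space(self, config):
        spec = CohortSpec(n_patients=8, seed=3)
        summaries, records, _ = gen_latent_cohort(spec)
        for scale in SCALES:
            table = se.correlate_feature_changes(
                summaries, clinical_to_frame(records), scale, config
            )
            assert len(table) == 96
            assert table["p_c"].notna().all()
            base = se.correlate_baseline(
                summaries, clinical_to_frame(records), scale, config
            )
            assert len(base) == 96

    def test_change_coupling_recovered(self, config):
        spec = CohortSpec(
            n_patients=200, target_r=-0.66, coupling_strength=0.25, seed=10
        )
        summaries, records, _ = gen_latent_cohort(spec)
        table = se.correlate_feature_changes(
            summaries, clinical_to_frame(records), "IDSSR", config
        )
        cell = table[
            (table.feature == "duration")
            & (table.electrode == "FPz")
            & (table.band == "beta")
        ].iloc[0]
        # Fisher 95% CI around r = -0.66 at n = 200
        assert -0.727 < cell.r < -0.580
        assert cell.significant

    def test_baseline_coupling_recovered(self, config):
        spec = CohortSpec(
            n_patients=200, target_r=0.68, coupling_mode="baseline",
            coupling_strength=0.25, seed=11,
        )
        summaries, records, _ = gen_latent_cohort(spec)
        table = se.correlate_baseline(
            summaries, clinical_to_frame(records), "IDSSR", config
        )
        cell = table[
            (table.feature == "duration")
            & (table.electrode == "FPz")
            & (table.band == "beta")
        ].iloc[0]
        assert 0.60 < cell.r < 0.76
        assert cell.significant

    def test_uncoupled_cells_rarely_significant(self, config):
        spec = CohortSpec(
            n_patients=200, target_r=-0.66, coupling_strength=0.25, seed=10
        )
        summaries, records, _ = gen_latent_cohort(spec)
        table = se.correlate_feature_changes(
            summaries, clinical_to_frame(records), "IDSSR", config
        )
        others = table[
            ~(
                (table.feature == "duration")
                & (table.electrode == "FPz")
                & (table.band == "beta")
            )
        ]
        assert others.significant.mean() <= 0.05 + 2 * np.sqrt(
            0.05 * 0.95 / len(others)
        )

    def test_missing_cell_excluded_pairwise(self, config):
        spec = CohortSpec(n_patients=10, seed=5)
        summaries, records, _ = gen_latent_cohort(spec)
        # patient P000 has no beta duration measurement at FPz
        mask = (
            (summaries.patient_id == "P000")
            & (summaries.electrode == "FPz")
            & (summaries.band == "beta")
        )
        summaries.loc[mask, "duration"] = np.nan
        table = se.correlate_feature_changes(
            summaries, clinical_to_frame(records), "IDSSR", config
        )
        cell = table[
            (table.feature == "duration")
            & (table.electrode == "FPz")
            & (table.band == "beta")
        ].iloc[0]
        assert cell.n == 9
        full = table[(table.feature == "number") & (table.electrode == "FPz")
                     & (table.band == "beta")].iloc[0]
        assert full.n == 10
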