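"""Event detection: regions, maxima pruning, ties, FWHM, summaries.

The vectorized detector is checked cell-for-cell against a literal
brute-force implementation (flood fill + exhaustive local-maximum scan +
tie averaging) on random TFR-like grids, under both 4- and 8-connectivity.
"""

import numpy as np
import pytest

import specevents as se
from specevents.events import detect_events, detect_events_band, find_regions
from specevents.synth import BurstSpec
from specevents.tfr import morlet_sigma_f, morlet_sigma_t

from oracles import detect as oracle_detect

BAND = se.BandDef("mid", 5.0, 16.0)  # rows 4..15 on the 1..20 Hz grid


def _stack(grid, dt=0.02, f0=1.0, df=1.0):
    grid = np.asarray(grid, dtype=float)
    return se.TFRStack(
        power=grid[None],
        freqs=f0 + df * np.arange(grid.shape[0]),
        times=dt * np.arange(grid.shape[1]),
        fs=1.0 / dt,
        electrode="Cz",
        normalized=True,
    )


def _compare_with_oracle(stack, band, connectivity=8):
    got = detect_events_band(stack, band, 6.0, connectivity)
    via_regions = detect_events(
        find_regions(stack, band, 6.0, connectivity), stack, band
    )
    rows = band.rows(stack.freqs)
    expected = oracle_detect(
        stack.power[0].tolist(),
        rows,
        stack.freqs.tolist(),
        stack.times.tolist(),
        6.0,
        connectivity,
    )
    for events in (got, via_regions):
        assert len(events) == len(expected)
        key = lambda e: (round(e["peak_time"], 9), e["peak_freq"])
        ekey = lambda e: (round(e.peak_time, 9), e.peak_freq)
        for e, o in zip(sorted(events, key=ekey), sorted(expected, key=key)):
            assert e.peak_time == pytest.approx(o["peak_time"], abs=1e-9)
            assert e.peak_freq == pytest.approx(o["peak_freq"], abs=1e-9)
            assert e.maxima_power_fom == pytest.approx(o["power"], rel=1e-12)
            assert e.duration_ms == pytest.approx(o["duration_ms"], rel=1e-9)
            assert e.freq_span_hz == pytest.approx(o["span_hz"], rel=1e-9)
            assert e.n_tied_maxima == o["n_tied"]


class TestFindRegions:
    def test_constant_tfr_no_regions(self):
        stack = _stack(np.ones((20, 50)))
        assert find_regions(stack, BAND, 6.0) == []

    def test_single_burst_single_region(self):
        grid = np.ones((20, 50))
        grid[8, 20] = 30.0  # one isolated suprathreshold cell
        stack = _stack(grid)
        regions = find_regions(stack, BAND, 6.0)
        assert len(regions) == 1
        assert regions[0].cells == [(8, 20)]

    def test_separated_bumps_two_regions(self):
        grid = np.ones((20, 50))
        grid[8, 10] = grid[9, 40] = 50.0
        regions = find_regions(_stack(grid), BAND, 6.0)
        assert len(regions) == 2

    def test_out_of_band_cells_ignored(self):
        grid = np.ones((20, 50))
        grid[0, 25] = 100.0  # below the band rows
        assert find_regions(_stack(grid), BAND, 6.0) == []

    def test_requires_normalized(self):
        stack = _stack(np.ones((20, 50)))
        stack.normalized = False
        with pytest.raises(se.InvalidArgumentError):
            find_regions(stack, BAND, 6.0)

    def test_diagonal_connectivity_difference(self):
        grid = np.ones((20, 50))
        grid[8, 10] = grid[9, 11] = 50.0  # diagonal neighbors
        assert len(find_regions(_stack(grid), BAND, 6.0, connectivity=8)) == 1
        assert len(find_regions(_stack(grid), BAND, 6.0, connectivity=4)) == 2


class TestDetectEvents:
    def test_single_maximum(self):
        grid = np.ones((20, 50))
        grid[8, 20] = 6.5
        grid[8, 21] = 7.2
        events = detect_events_band(_stack(grid), BAND)
        assert len(events) == 1
        e = events[0]
        assert e.peak_freq == 9.0
        assert e.peak_time == pytest.approx(0.42)
        assert e.maxima_power_fom == pytest.approx(7.2)

    def test_greatest_maximum_survives(self):
        grid = np.ones((20, 50))
        grid[8, 20] = 8.0
        grid[8, 22] = 7.5
        grid[8, 21] = 7.0  # saddle keeps both in one region
        events = detect_events_band(_stack(grid), BAND)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(0.40)
        assert events[0].maxima_power_fom == pytest.approx(8.0)

    def test_tied_maxima_averaged(self):
        # equal maxima at t=0.5 s and t=0.7 s, same frequency -> 0.6 s
        grid = np.ones((20, 50))
        grid[8, 25] = grid[8, 35] = 9.0
        grid[8, 26:35] = 6.5  # bridge keeps one region
        events = detect_events_band(_stack(grid), BAND)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(0.6)
        assert events[0].n_tied_maxima == 2

    def test_empty_region_list_gives_no_events(self):
        stack = _stack(np.ones((20, 50)))
        assert detect_events([], stack, BAND) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, grid_factory, seed, connectivity):
        rng = np.random.default_rng(seed)
        stack = grid_factory(rng, n_bumps=int(rng.integers(1, 5)))
        _compare_with_oracle(stack, BAND, connectivity)

    def test_tie_with_plateau_matches_oracle(self):
        grid = np.ones((20, 50))
        grid[8, 20] = grid[8, 21] = 9.0  # adjacent plateau at the maximum
        grid[9, 30] = 9.0
        grid[8, 22:31] = 6.5
        _compare_with_oracle(_stack(grid), BAND)

    def test_threshold_monotonicity(self, grid_factory):
        stack = grid_factory(np.random.default_rng(3), n_bumps=6)
        counts = [
            len(detect_events_band(stack, BAND, thr))
            for thr in (4.0, 6.0, 9.0, 14.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestEventFWHM:
    def test_impulse_duration_matches_wavelet_envelope(self):
        x = np.zeros((1, 1, 1000))
        x[0, 0, 500] = 1.0
        ep = se.EpochArray(x, 500.0, 2.0, ("Cz",), (0,))
        tfr = se.compute_tfr(ep, "Cz", range(1, 46), dtype="float64")
        tfr.normalized = True  # impulse row shape is what matters here
        row = 19  # 20 Hz
        col = int(np.argmax(tfr.power[0, row]))
        dur, span, *_ = se.event_fwhm(tfr, 0, row, col)
        expected = 2e3 * morlet_sigma_t(20.0) * np.sqrt(np.log(2))
        assert dur == pytest.approx(expected, rel=0.10)

    def test_sustained_tone_span_matches_wavelet_bandwidth(self):
        t = np.arange(1000) / 500.0
        x = np.cos(2 * np.pi * 20 * t)[None, None, :]
        ep = se.EpochArray(x, 500.0, 2.0, ("Cz",), (0,))
        tfr = se.compute_tfr(ep, "Cz", range(1, 46), dtype="float64")
        tfr.normalized = True
        dur, span, *_ = se.event_fwhm(tfr, 0, 19, 500)
        expected = 2 * morlet_sigma_f(20.0) * np.sqrt(np.log(2))
        assert span == pytest.approx(expected, rel=0.10)

    def test_edge_doubling_left_cut(self):
        # run cut by the left epoch edge; right half-width doubles
        grid = np.ones((20, 50))
        peak_col = 10
        grid[8, : peak_col + 1] = 9.0          # above half-max back to t=0
        grid[8, peak_col + 1 : peak_col + 21] = np.linspace(8.8, 1.0, 20)
        stack = _stack(grid)
        dur_ms, _, onset, offset, *_ , tedge, fedge = se.event_fwhm(
            stack, 0, 8, peak_col
        )
        # locate the exact right half-max crossing by interpolation
        row = grid[8]
        half = 4.5
        k = peak_col
        while row[k + 1] > half:
            k += 1
        frac = (row[k] - half) / (row[k] - row[k + 1])
        right = (k + frac) * 0.02
        assert tedge and not fedge
        assert dur_ms == pytest.approx(2e3 * (right - peak_col * 0.02))

    def test_symmetric_peak_onset_offset(self):
        grid = np.ones((20, 50))
        prof = np.array([1.0, 3.0, 6.0, 10.0, 6.0, 3.0, 1.0])
        grid[8, 17:24] = prof
        stack = _stack(grid)
        dur_ms, _, onset, offset, *_ = se.event_fwhm(stack, 0, 8, 20)
        assert onset == pytest.approx(0.4 - dur_ms / 2000)
        assert offset == pytest.approx(0.4 + dur_ms / 2000)
        # half-max = 5 crosses between cells 18 (3.0) and 19 (6.0) at
        # 1/3 cell above 18, i.e. 4/3 cells from the peak on each side
        assert dur_ms == pytest.approx(2 * (4 / 3) * 20.0)


class TestScaleInvariance:
    def test_events_invariant_to_signal_scaling(self, background_1f):
        rec, _ = se.inject_bursts(
            background_1f,
            [BurstSpec(10.2, 20.0, 0.06, 120.0, "Cz")],
        )
        scaled = se.RawRecording(
            rec.data * 37.5, rec.fs, rec.channel_labels
        )
        events = []
        for r in (rec, scaled):
            ep = se.segment_epochs(r, 2.0).select(range(10))
            tfr = se.compute_tfr(ep, "Cz", range(1, 46), dtype="float64")
            norm = se.normalize_fom(tfr)
            events.append(detect_events_band(norm, se.DEFAULT_BANDS[2]))
        a, b = events
        assert len(a) == len(b) >= 1
        for ea, eb in zip(a, b):
            assert ea.peak_time == eb.peak_time
            assert ea.peak_freq == eb.peak_freq
            assert ea.duration_ms == pytest.approx(eb.duration_ms, rel=1e-6)
            assert ea.maxima_power_fom == pytest.approx(
                eb.maxima_power_fom, rel=1e-9
            )


class TestSummarizeFeatures:
    def _event(self, dur, power=7.0, span=3.0):
        return se.SpectralEvent(
            band="beta", epoch_index=0, peak_time=1.0, peak_freq=20.0,
            maxima_power_fom=power, duration_ms=dur, freq_span_hz=span,
            onset=0.9, offset=1.1, f_lo=18.0, f_hi=22.0,
        )

    def test_number_per_epoch(self):
        s = se.summarize_features([self._event(100)] * 3, 2, "beta")
        assert s.number == 1.5

    def test_mean_duration(self):
        s = se.summarize_features(
            [self._event(100), self._event(200)], 2, "beta"
        )
        assert s.duration == 150.0

    def test_empty_events_flag_missing(self):
        s = se.summarize_features([], 5, "beta")
        assert s.number == 0
        assert np.isnan(s.power) and np.isnan(s.duration) and np.isnan(s.span)

    def test_zero_epochs_rejected(self):
        with pytest.raises(se.InvalidArgumentError):
            se.summarize_features([], 0, "beta")
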