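"""Independent brute-force reference implementations used only by tests.

These apply the detection and correction rules literally — explicit flood
fill, exhaustive local-maximum scans, direct step-up enumeration — with no
code shared with the package, so they can serve as oracles for the
vectorized implementations.
"""

from __future__ import annotations

import math


def bh_stepup(pvals: list[float]) -> list[float]:
    """Literal Benjamini–Hochberg step-up adjusted p-values.

    adjusted(i) = min over j with rank >= rank(i) of (m / rank_j) * p_j,
    capped at 1, where ranks follow ascending p.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * pvals[i] / (pos + 1))
        adjusted[i] = min(1.0, running_min)
    return adjusted


def _neighbors(f: int, t: int, n_f: int, n_t: int, connectivity: int):
    for df in (-1, 0, 1):
        for dtc in (-1, 0, 1):
            if df == 0 and dtc == 0:
                continue
            if connectivity == 4 and df != 0 and dtc != 0:
                continue
            ff, tt = f + df, t + dtc
            if 0 <= ff < n_f and 0 <= tt < n_t:
                yield ff, tt


def flood_regions(grid, band_rows, threshold, connectivity=8):
    """Connected components of suprathreshold cells within band rows.

    ``grid`` is a full freqs x times array (one epoch); returns a list of
    sorted cell lists in full-grid (freq_row, time_col) coordinates.
    """
    rows = set(band_rows)
    n_f = len(grid)
    n_t = len(grid[0])
    above = {
        (f, t)
        for f in rows
        for t in range(n_t)
        if grid[f][t] >= threshold
    }
    seen = set()
    regions = []
    for cell in sorted(above):
        if cell in seen:
            continue
        stack = [cell]
        comp = []
        seen.add(cell)
        while stack:
            f, t = stack.pop()
            comp.append((f, t))
            for ff, tt in _neighbors(f, t, n_f, n_t, connectivity):
                if (ff, tt) in above and (ff, tt) not in seen:
                    seen.add((ff, tt))
                    stack.append((ff, tt))
        regions.append(sorted(comp))
    return regions


def local_maxima(grid, band_rows, cells, connectivity=8):
    """Cells of ``cells`` that are >= every neighbor in the band-restricted
    grid (non-strict, so plateau cells count and fall under the tie rule)."""
    rows = sorted(band_rows)
    lo, hi = rows[0], rows[-1]
    n_t = len(grid[0])
    out = []
    for f, t in cells:
        is_max = True
        for ff, tt in _neighbors(f, t, hi - lo + 1 + lo, n_t, connectivity):
            if ff < lo or ff > hi:
                continue
            if grid[ff][tt] > grid[f][t]:
                is_max = False
                break
        if is_max:
            out.append((f, t))
    return out


def fwhm_1d(values, peak_idx, step, origin):
    """Literal half-max scan with linear interpolation and edge doubling."""
    peak = values[peak_idx]
    half = peak / 2.0
    n = len(values)
    j = peak_idx
    while j > 0 and values[j - 1] > half:
        j -= 1
    left = None
    if j > 0:
        frac = (values[j] - half) / (values[j] - values[j - 1])
        left = (j - frac) * step + origin
    k = peak_idx
    while k < n - 1 and values[k + 1] > half:
        k += 1
    right = None
    if k < n - 1:
        frac = (values[k] - half) / (values[k] - values[k + 1])
        right = (k + frac) * step + origin
    center = peak_idx * step + origin
    if left is not None and right is not None:
        return right - left, False
    if left is None and right is not None:
        return 2.0 * (right - center), True
    if right is None and left is not None:
        return 2.0 * (center - left), True
    return (k - j) * step, True


def detect(grid, band_rows, freqs, times, threshold=6.0, connectivity=8):
    """Full literal detection on one epoch grid.

    Returns one dict per suprathreshold region with tie-averaged peak time,
    peak frequency, maxima power, FWHM duration (ms) and frequency span.
    """
    dt = times[1] - times[0]
    df = freqs[1] - freqs[0]
    events = []
    for region in flood_regions(grid, band_rows, threshold, connectivity):
        maxima = local_maxima(grid, band_rows, region, connectivity)
        greatest = max(grid[f][t] for f, t in maxima)
        tied = [(f, t) for f, t in maxima if grid[f][t] == greatest]
        durs, spans, ptimes, pfreqs = [], [], [], []
        for f, t in tied:
            tslice = [grid[f][tt] for tt in range(len(times))]
            fslice = [grid[ff][t] for ff in range(len(freqs))]
            d, _ = fwhm_1d(tslice, t, dt, times[0])
            s, _ = fwhm_1d(fslice, f, df, freqs[0])
            durs.append(d * 1000.0)
            spans.append(s)
            ptimes.append(times[t])
            pfreqs.append(freqs[f])
        k = len(tied)
        events.append(
            {
                "cells": region,
                "peak_time": sum(ptimes) / k,
                "peak_freq": sum(pfreqs) / k,
                "power": greatest,
                "duration_ms": sum(durs) / k,
                "span_hz": sum(spans) / k,
                "n_tied": k,
            }
        )
    return events


def paired_t_formula(pre, post):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), d = post - pre."""
    n = len(pre)
    d = [b - a for a, b in zip(pre, post)]
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)
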