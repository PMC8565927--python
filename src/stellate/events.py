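"""Detection and kinetic measurement of synaptic current events.

Conventions follow standard whole-cell electrophysiology analysis:

* baseline = mean over the 1 ms window preceding the event onset;
* amplitude = |mean over a 100 µs window centered on the peak - baseline|
  (the windowed mean suppresses single-sample noise excursions);
* 10-90 % rise time and half-width are measured with linear interpolation
  between samples, with the crossing levels anchored on the instantaneous
  baseline-subtracted extremum (not the windowed amplitude, whose small
  negative bias would otherwise widen the half-width);
* the weighted decay constant tau_decay is the integral of the
  baseline-subtracted current from its peak to the return to baseline,
  divided by the peak amplitude.

All measurements are invariant to adding a constant offset to the trace, and
treat inward (negative) and outward events symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cable import Trace

__all__ = [
    "EventStats",
    "detect_events",
    "measure_event",
    "waveform_stats",
    "tau_decay_weighted",
    "average_events",
    "summarize_population",
]


@dataclass(frozen=True)
class EventStats:
    """Kinetic summary of a single event (pA / ms)."""

    amplitude: float
    rise_10_90: float
    half_width: float
    tau_decay: float
    peak_time: float


def _robust_sd(x: np.ndarray) -> float:
    """Noise SD estimate from the median absolute deviation."""
    return float(sstats.median_abs_deviation(x, scale="normal"))


def detect_events(
    trace: Trace,
    threshold_sd: float = 4.0,
    min_interval: float = 2.0,
    baseline_window: float = 1.0,
    smooth_ms: float = 0.2,
) -> np.ndarray:
    """Threshold-crossing event detection.

    The trace is median-subtracted and boxcar-smoothed over ``smooth_ms``
    (roughly the synaptic rise time) before thresholding; the threshold is
    ``threshold_sd`` times the robust noise SD of the *raw* trace, the
    convention used when setting amplitude thresholds from measured baseline
    noise.  Smoothing suppresses single-sample noise excursions that would
    otherwise cross an amplitude threshold at high sampling rates, while
    barely attenuating synaptic events, which last much longer than the
    smoothing window.  A dead time of ``min_interval`` ms follows each
    detected onset.  Returns onset times in ms.
    """
    x = trace.samples
    if x.size * trace.dt <= baseline_window:
        raise ValueError("trace shorter than the baseline window")
    centered = x - np.median(x)
    sd = _robust_sd(x)
    if sd == 0:
        return np.asarray([])
    k = max(1, int(round(smooth_ms / trace.dt)))
    if k > 1:
        stat = np.convolve(centered, np.full(k, 1.0 / k), mode="same")
    else:
        stat = centered
    above = np.abs(stat) > threshold_sd * sd
    dead = max(1, int(round(min_interval / trace.dt)))
    onsets = []
    i = 0
    n = x.size
    while i < n:
        if above[i]:
            onsets.append(trace.t0 + i * trace.dt)
            i += dead
        else:
            i += 1
    return np.asarray(onsets)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool) -> float:
    """First time y crosses level, linearly interpolated.

    ``rising=True`` scans forward for the first crossing from below;
    ``rising=False`` likewise but y is scanned as given (callers pass
    reversed arrays for backward scans).
    """
    below = y < level
    for i in range(1, y.size):
        if below[i - 1] and not below[i]:
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise ValueError("no crossing found")


def _parabolic_peak(window: np.ndarray) -> float:
    """Peak value from a quadratic least-squares fit to a window of samples
    centred on the maximum; falls back to the window mean when the fit is
    not concave (e.g. a flat-topped pulse)."""
    n = window.size
    if n < 3:
        return float(np.max(window))
    x = np.arange(n, dtype=float) - (n - 1) / 2.0
    a, b, c = np.polyfit(x, window, 2)
    if a >= 0:
        return float(np.mean(window))
    vertex = c - b * b / (4.0 * a)
    return float(vertex)


def _first_crossing_from_peak(t: np.ndarray, y: np.ndarray,
                              level: float) -> float:
    """Crossing time of ``level`` on a rising limb, scanning backward from
    the peak (the last element) toward the onset."""
    for i in range(y.size - 1, 0, -1):
        if y[i - 1] < level <= y[i]:
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise ValueError("no crossing found on the rise limb")


def measure_event(
    trace: Trace,
    onset: float,
    baseline_window: float = 1.0,
    peak_window: float = 0.1,
    search_window: float = 10.0,
    integration_window: float = 10.0,
    localize_smooth_ms: float = 0.1,
) -> EventStats:
    """Measure one event starting near ``onset`` (ms).

    The peak is the extremum of the baseline-subtracted signal within
    ``search_window`` ms after onset; it is localized on a copy smoothed
    over ``localize_smooth_ms`` so that a noise excursion on a slow event
    does not displace it, while all levels and crossings are measured on
    the raw samples.  See the module docstring for the amplitude /
    kinetics conventions.
    """
    dt = trace.dt
    i_on = int(round((onset - trace.t0) / dt))
    if i_on < 0 or i_on >= trace.samples.size:
        raise ValueError("onset outside trace")
    nb = int(round(baseline_window / dt))
    b0 = max(0, i_on - nb)
    if i_on == 0:
        baseline = float(trace.samples[0])
    else:
        baseline = float(np.mean(trace.samples[b0:i_on]))

    # include one pre-onset sample so level crossings at a step onset exist
    i_seg = max(0, i_on - 1)
    i_end = min(trace.samples.size, i_on + int(round(search_window / dt)) + 1)
    seg = trace.samples[i_seg:i_end] - baseline
    if seg.size < 3:
        raise ValueError("event not fully contained in trace")
    sign = 1.0 if np.max(seg) >= -np.min(seg) else -1.0
    seg = sign * seg
    # localize the peak on a smoothed copy; plateau-safe (middle of the
    # maximal run)
    k = max(1, int(round(localize_smooth_ms / dt)))
    seg_s = np.convolve(seg, np.full(k, 1.0 / k), mode="same") if k > 1 else seg
    smax = float(np.max(seg_s))
    at_max = np.flatnonzero(seg_s >= smax - 1e-12 * max(1.0, abs(smax)))
    i_pk = int(at_max[at_max.size // 2])
    # refine on the raw samples within the smoothing neighbourhood
    lo = max(0, i_pk - k)
    hi = min(seg.size, i_pk + k + 1)
    i_pk = lo + int(np.argmax(seg[lo:hi]))
    if i_pk == 0 or i_pk == seg.size - 1:
        raise ValueError("event peak at trace boundary")
    peak_time = trace.t0 + (i_seg + i_pk) * dt

    # windowed-mean amplitude, 100 µs centred on the peak
    half_w = max(0, int(round(peak_window / dt / 2)))
    w0 = max(0, i_pk - half_w)
    w1 = min(seg.size, i_pk + half_w + 1)
    amplitude = float(np.mean(seg[w0:w1]))

    # crossing levels anchor on a local parabolic peak estimate over the
    # same window: exact for smooth waveforms, unbiased under noise (the
    # raw sample maximum overestimates a noisy peak and would bias the
    # widths)
    peak_level = _parabolic_peak(seg[w0:w1])

    tseg = trace.t0 + dt * np.arange(i_seg, i_end)
    rise_t = tseg[: i_pk + 1]
    rise_y = seg[: i_pk + 1]
    # scan outward from the peak: reversed rise limb, forward decay limb
    t90 = _first_crossing_from_peak(rise_t, rise_y, 0.9 * peak_level)
    t10 = _first_crossing_from_peak(rise_t, rise_y, 0.1 * peak_level)
    rise = t90 - t10
    t_half_rise = _first_crossing_from_peak(rise_t, rise_y, 0.5 * peak_level)
    dec_t = tseg[i_pk:]
    dec_y = -seg[i_pk:]  # decay crossing of the half level from above
    t_half_decay = _interp_crossing(dec_t, dec_y, -0.5 * peak_level, True)
    half_width = t_half_decay - t_half_rise

    tau = tau_decay_weighted(
        trace,
        onset=onset,
        baseline=baseline,
        peak_index=i_seg + i_pk,
        sign=sign,
        integration_window=integration_window,
    )
    return EventStats(
        amplitude=amplitude,
        rise_10_90=rise,
        half_width=half_width,
        tau_decay=tau,
        peak_time=peak_time,
    )


def waveform_stats(trace: Trace, baseline: float | None = None) -> EventStats:
    """Kinetics of a clean (noiseless) waveform such as a simulated EPSC.

    Baseline defaults to the first sample; the amplitude is the
    instantaneous extremum (no peak window).
    """
    if baseline is None:
        baseline = float(trace.samples[0])
    y = trace.samples - baseline
    sign = 1.0 if np.max(y) >= -np.min(y) else -1.0
    y = sign * y
    t = trace.times
    i_pk = int(np.argmax(y))
    if i_pk == 0 or i_pk == y.size - 1:
        raise ValueError("waveform peak at trace boundary")
    peak = float(y[i_pk])
    t10 = _interp_crossing(t[: i_pk + 1], y[: i_pk + 1], 0.1 * peak, True)
    t90 = _interp_crossing(t[: i_pk + 1], y[: i_pk + 1], 0.9 * peak, True)
    t_half_rise = _interp_crossing(t[: i_pk + 1], y[: i_pk + 1], 0.5 * peak, True)
    t_half_decay = _interp_crossing(t[i_pk:], -y[i_pk:], -0.5 * peak, True)
    # weighted decay: integral from the peak to baseline return (or the end)
    dec = y[i_pk:]
    below = np.where(dec <= 0)[0]
    stop = int(below[0]) if below.size else dec.size
    tau = float(np.trapezoid(dec[:stop], dx=trace.dt) / peak)
    return EventStats(
        amplitude=peak,
        rise_10_90=t90 - t10,
        half_width=t_half_decay - t_half_rise,
        tau_decay=tau,
        peak_time=float(t[i_pk]),
    )


def tau_decay_weighted(
    trace: Trace,
    onset: float = 0.0,
    baseline: float | None = None,
    peak_index: int | None = None,
    sign: float | None = None,
    integration_window: float = 10.0,
) -> float:
    """Weighted decay time constant (ms).

    tau_decay = integral of the baseline-subtracted current from the peak to
    the first return to baseline (or the end of ``integration_window``),
    divided by the peak amplitude.  For a single exponential this equals its
    time constant.
    """
    dt = trace.dt
    i_on = int(round((onset - trace.t0) / dt))
    if baseline is None:
        nb = int(round(1.0 / dt))
        baseline = (
            float(np.mean(trace.samples[max(0, i_on - nb): i_on]))
            if i_on > 0
            else float(trace.samples[0])
        )
    if sign is None or peak_index is None:
        y_on = trace.samples[i_on:] - baseline
        if sign is None:
            sign = 1.0 if np.max(y_on) >= -np.min(y_on) else -1.0
        if peak_index is None:
            peak_index = i_on + int(np.argmax(sign * y_on))
    stop = min(trace.samples.size,
               peak_index + int(round(integration_window / dt)) + 1)
    dec = sign * (trace.samples[peak_index:stop] - baseline)
    peak = float(dec[0])
    if peak <= 0:
        raise ValueError("nonpositive peak amplitude")
    below = np.where(dec <= 0)[0]
    if below.size:
        dec = dec[: int(below[0])]
    return float(np.trapezoid(dec, dx=dt) / peak)


def average_events(
    trace: Trace,
    onsets,
    pre_window: float = 2.0,
    post_window: float = 10.0,
) -> Trace:
    """Aligned mean event waveform.

    Segments of ``pre_window`` + ``post_window`` ms around each onset are
    baseline-subtracted (mean of the 1 ms before onset) and averaged.
    Kinetics of small events are conventionally measured on this average,
    where the noise is suppressed by sqrt(n).  The returned trace starts
    ``pre_window`` ms before the aligned onset (t0 = -pre_window).
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if onsets.size == 0:
        raise ValueError("no onsets to average")
    dt = trace.dt
    n_pre = int(round(pre_window / dt))
    n_post = int(round(post_window / dt))
    nb = int(round(1.0 / dt))
    acc = np.zeros(n_pre + n_post)
    used = 0
    for onset in onsets:
        i_on = int(round((onset - trace.t0) / dt))
        if i_on - n_pre < 0 or i_on + n_post > trace.samples.size:
            continue
        seg = trace.samples[i_on - n_pre: i_on + n_post]
        baseline = float(np.mean(trace.samples[max(0, i_on - nb): i_on]))
        acc += seg - baseline
        used += 1
    if used == 0:
        raise ValueError("no event fits inside the trace")
    return Trace(dt=dt, samples=acc / used, t0=-pre_window, unit=trace.unit)


def summarize_population(
    events: pd.DataFrame,
    group_of_cell: dict | None = None,
    compare_groups: tuple[str, str] | None = None,
) -> dict:
    """Per-cell means and group summaries of event statistics.

    ``events`` needs a ``cell_id`` column plus numeric statistic columns
    (e.g. amplitude, rise_10_90, half_width, tau_decay).  Cells are averaged
    first, then groups summarized as mean ± SEM; an optional two-sample
    Mann-Whitney rank comparison is run per statistic.
    """
    if "cell_id" not in events.columns:
        raise ValueError("events table needs a cell_id column")
    value_cols = [
        c for c in events.columns
        if c != "cell_id" and pd.api.types.is_numeric_dtype(events[c])
    ]
    per_cell = events.groupby("cell_id", sort=True)[value_cols].mean()
    out: dict = {"per_cell": per_cell}
    if group_of_cell is not None:
        pc = per_cell.copy()
        pc["group"] = [group_of_cell[c] for c in pc.index]
        grp = pc.groupby("group")[value_cols]
        out["group_table"] = grp.agg(["mean", "sem", "count"])
        if compare_groups is not None:
            a, b = compare_groups
            tests = {}
            for col in value_cols:
                xa = pc.loc[pc["group"] == a, col]
                xb = pc.loc[pc["group"] == b, col]
                stat, p = sstats.mannwhitneyu(xa, xb, alternative="two-sided")
                tests[col] = {"U": float(stat), "p": float(p)}
            out["tests"] = tests
    return out
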