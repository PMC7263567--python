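"""Actomyosin oscillation analysis.

The pipeline mirrors the standard treatment of pulsatile basal myosin
signals: subtract a cell-free background, smooth with a Gaussian kernel
(σ = 3 samples), detect alternating peaks and troughs, report the
period both as the mean interval between adjacent peaks and as the
dominant period of the power spectral density, where the PSD is the
one-dimensional Fourier transform of the signal's autocorrelation.
Cycle amplitudes are measured on the unsmoothed background-subtracted
signal within cycle windows found on the smoothed one, because a σ = 3
kernel attenuates the oscillation amplitude itself at typical
period-to-frame ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

SMOOTH_SIGMA = 3.0          # samples
SMOOTH_TRUNCATE = 3.0       # kernel truncated at 3 sigma
PROMINENCE_FRAC = 0.2       # of the signal range
MIN_SAMPLES = 8


@dataclass
class IntensityTrace:
    """Uniformly sampled scalar signal (fluorescence a.u., μm², or %)."""

    values: np.ndarray
    dt_s: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < MIN_SAMPLES:
            raise ValueError(f"trace needs >= {MIN_SAMPLES} samples")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_s

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt_s


@dataclass
class CycleSet:
    """Alternating peaks/troughs of one trace, with per-cycle amplitudes."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    amplitudes: np.ndarray          # per cycle, on the measurement signal
    flagged: bool = False           # True when < 2 peaks (period undefined)

    @property
    def n_peaks(self) -> int:
        return int(len(self.peak_indices))


@dataclass
class PeriodSummary:
    intervals_s: np.ndarray
    mean_s: float


@dataclass
class PSDResult:
    frequencies: np.ndarray         # 1/s, nonnegative half-spectrum
    power: np.ndarray
    dominant_period_s: float
    flagged: bool = False           # True for constant input


@dataclass
class CouplingStats:
    r_myosin_protrusion: float
    r_myosin_area: float
    lag_myosin_protrusion_s: float
    lag_myosin_area_s: float
    period_cv: dict
    flagged: bool = False


def preprocess(trace: IntensityTrace, background_value: float) -> IntensityTrace:
    """Background-subtract, clip at zero, and Gaussian-smooth (σ = 3 samples)."""
    if background_value < 0:
        raise ValueError("background must be non-negative")
    support = 2 * int(SMOOTH_TRUNCATE * SMOOTH_SIGMA) + 1
    if trace.values.size < support:
        raise ValueError(
            f"trace shorter than the smoothing kernel support ({support} samples)")
    x = np.clip(trace.values - background_value, 0.0, None)
    smoothed = gaussian_filter1d(x, SMOOTH_SIGMA, mode="reflect",
                                 truncate=SMOOTH_TRUNCATE)
    return IntensityTrace(values=smoothed, dt_s=trace.dt_s, label=trace.label)


def detect_cycles(trace: IntensityTrace,
                  measure_on: Optional[np.ndarray] = None,
                  prominence_frac: float = PROMINENCE_FRAC) -> CycleSet:
    """Detect alternating peaks and troughs.

    Extrema need a prominence of ``prominence_frac`` times the signal
    range.  ``measure_on`` optionally supplies the signal on which the
    per-cycle (max − min) amplitudes are evaluated (typically the
    unsmoothed trace); it defaults to the detection signal itself.
    """
    x = trace.values
    rng_ = float(x.max() - x.min())
    raw = x if measure_on is None else np.asarray(measure_on, dtype=float)
    if raw.shape != x.shape:
        raise ValueError("measure_on must match the trace length")
    if rng_ == 0:
        return CycleSet(np.array([], int), np.array([], int),
                        np.array([]), flagged=True)
    prom = prominence_frac * rng_
    peaks, _ = sps.find_peaks(x, prominence=prom)
    troughs, _ = sps.find_peaks(-x, prominence=prom)
    peaks, troughs = _enforce_alternation(x, peaks, troughs)

    amplitudes = []
    if troughs.size >= 2:
        for t0, t1 in zip(troughs[:-1], troughs[1:]):
            window = raw[t0:t1 + 1]
            amplitudes.append(float(window.max() - window.min()))
    elif peaks.size >= 1 and troughs.size == 1:
        amplitudes.append(float(raw.max() - raw.min()))
    return CycleSet(peak_indices=peaks, trough_indices=troughs,
                    amplitudes=np.asarray(amplitudes),
                    flagged=peaks.size < 2)


def _enforce_alternation(x, peaks, troughs):
    """Merge runs of same-type extrema, keeping the most extreme one."""
    events = sorted([(int(i), "p") for i in peaks] + [(int(i), "t") for i in troughs])
    out_p: List[int] = []
    out_t: List[int] = []
    i = 0
    while i < len(events):
        j = i
        while j + 1 < len(events) and events[j + 1][1] == events[i][1]:
            j += 1
        run = [e[0] for e in events[i:j + 1]]
        if events[i][1] == "p":
            out_p.append(max(run, key=lambda k: x[k]))
        else:
            out_t.append(min(run, key=lambda k: x[k]))
        i = j + 1
    return np.asarray(out_p, int), np.asarray(out_t, int)


def period_from_intervals(cycles: CycleSet, dt_s: float) -> PeriodSummary:
    """Oscillation period as intervals between adjacent detected peaks."""
    if cycles.n_peaks < 2:
        raise ValueError("need >= 2 peaks to measure intervals")
    intervals = np.diff(cycles.peak_indices) * dt_s
    return PeriodSummary(intervals_s=intervals, mean_s=float(intervals.mean()))


def cycle_amplitude(cycles: CycleSet) -> float:
    """Mean per-cycle (max − min) amplitude."""
    if cycles.amplitudes.size == 0:
        raise ValueError("no complete cycle detected")
    return float(cycles.amplitudes.mean())


def psd_dominant_period(trace: IntensityTrace) -> PSDResult:
    """Dominant oscillation period from the PSD of the autocorrelation.

    The signal is mean-subtracted; the normalized biased autocorrelation
    (lag 0 = 1) is Fourier-transformed without windowing, and the
    dominant period is the reciprocal of the frequency of maximum power,
    searching only above 1/(total duration) to avoid trend leakage.
    """
    x = trace.values
    n = x.size
    if n < 32:
        raise ValueError("need >= 32 samples for a spectral estimate")
    x = x - x.mean()
    c0 = float(np.dot(x, x))
    if c0 == 0:
        freqs = np.fft.rfftfreq(n, trace.dt_s)
        return PSDResult(freqs, np.zeros_like(freqs), float("nan"), flagged=True)
    # biased autocorrelation, normalized so lag 0 equals 1
    ac = np.correlate(x, x, mode="full")[n - 1:] / c0
    spectrum = np.abs(np.fft.rfft(ac))
    freqs = np.fft.rfftfreq(n, trace.dt_s)
    fmin = 1.0 / (n * trace.dt_s)
    searchable = freqs >= fmin * (1.0 - 1e-9)
    searchable[0] = False
    idx = int(np.argmax(np.where(searchable, spectrum, -np.inf)))
    return PSDResult(frequencies=freqs, power=spectrum,
                     dominant_period_s=float(1.0 / freqs[idx]))


def autocorrelation(trace: IntensityTrace) -> np.ndarray:
    """Normalized biased autocorrelation (lag 0 = 1) of the centred signal."""
    x = trace.values - trace.values.mean()
    c0 = float(np.dot(x, x))
    if c0 == 0:
        raise ValueError("autocorrelation undefined for a constant trace")
    return np.correlate(x, x, mode="full")[x.size - 1:] / c0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _xcorr_lag(a: np.ndarray, b: np.ndarray, dt_s: float) -> float:
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        return float("nan")
    cc = np.correlate(a, b, mode="full")
    lag = int(np.argmax(cc)) - (a.size - 1)
    return lag * dt_s


def _period_cv(trace: IntensityTrace) -> float:
    cycles = detect_cycles(trace)
    if cycles.n_peaks < 3:
        return float("nan")
    intervals = np.diff(cycles.peak_indices) * trace.dt_s
    return float(intervals.std(ddof=1) / intervals.mean())


def coupling_stats(bundle) -> CouplingStats:
    """Myosin/geometry coupling of one trace bundle.

    Reports zero-lag Pearson correlations of myosin with protrusion area
    and basal area, the lag of maximum cross-correlation, and each
    trace's period coefficient of variation as a stochasticity summary.
    Any object with ``myosin``, ``protrusion_pct`` and ``basal_area``
    IntensityTrace attributes is accepted.
    """
    m = bundle.myosin
    p = bundle.protrusion_pct
    a = bundle.basal_area
    if not (m.values.size == p.values.size == a.values.size):
        raise ValueError("bundle traces are not aligned")
    r_mp = _pearson(m.values, p.values)
    r_ma = _pearson(m.values, a.values)
    return CouplingStats(
        r_myosin_protrusion=r_mp,
        r_myosin_area=r_ma,
        lag_myosin_protrusion_s=_xcorr_lag(m.values, p.values, m.dt_s),
        lag_myosin_area_s=_xcorr_lag(m.values, a.values, m.dt_s),
        period_cv={t.label or name: _period_cv(t)
                   for name, t in (("myosin", m), ("protrusion_pct", p),
                                   ("basal_area", a))},
        flagged=math.isnan(r_mp) or math.isnan(r_ma),
    )


def analyze_trace(trace: IntensityTrace, background_value: float = 0.0) -> dict:
    """Convenience pipeline: preprocess, cycle stats, both period estimates."""
    smoothed = preprocess(trace, background_value)
    raw = np.clip(trace.values - background_value, 0.0, None)
    cycles = detect_cycles(smoothed, measure_on=raw)
    out = {"label": trace.label, "n_peaks": cycles.n_peaks,
           "flagged": cycles.flagged}
    if not cycles.flagged:
        summary = period_from_intervals(cycles, trace.dt_s)
        out["period_intervals_mean_s"] = summary.mean_s
        intervals = summary.intervals_s
        out["period_cv"] = (float(intervals.std(ddof=1) / intervals.mean())
                            if intervals.size > 1 else float("nan"))
    if cycles.amplitudes.size:
        out["amplitude"] = cycle_amplitude(cycles)
    if trace.values.size >= 32:
        psd = psd_dominant_period(smoothed)
        out["period_psd_s"] = psd.dominant_period_s
    return out
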