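"""Summary metrics over simulated time series.

All metrics operate on stored, uniformly sampled traces (so any analysis
can be re-run offline from a written CSV) and report a missing quantity
as ``None`` rather than zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar trace with units metadata."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size == 0:
            raise ValueError("time series must be nonempty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        sel = (self.times >= t_start) & (self.times <= t_end)
        if not sel.any():
            raise ValueError(f"window [{t_start}, {t_end}] outside the trace")
        return TimeSeries(self.times[sel], self.values[sel], self.label, self.units)


@dataclass
class SummaryMetrics:
    """Bundle of optional summary quantities; absent metrics stay ``None``."""

    decay_time: float | None = None
    steady_state_time: float | None = None
    oscillation_amplitude: float | None = None
    peak_current_ratio_log10: float | None = None
    extrema: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"decay_time": self.decay_time,
                "steady_state_time": self.steady_state_time,
                "oscillation_amplitude": self.oscillation_amplitude,
                "peak_current_ratio_log10": self.peak_current_ratio_log10,
                "extrema": dict(self.extrema)}


def decay_time(ts: TimeSeries, stim_end: float, baseline: float,
               frac: float = 0.05) -> float | None:
    """Time after ``stim_end`` for the deviation from ``baseline`` to fall
    below ``frac`` of its post-stimulus peak and stay there.

    For a pure exponential relaxation with time constant ``tau`` and the
    default 5% criterion this is ~3 tau.  Returns 0.0 for a trace already
    at baseline and ``None`` (with a warning) if the trace never
    recovers.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    tail = ts.window(stim_end, float(ts.times[-1]))
    dev = np.abs(tail.values - baseline)
    peak = dev.max()
    if peak == 0.0:
        return 0.0
    below = dev < frac * peak
    if not below[-1]:
        logger.warning("decay_time: trace never recovers to %.0f%% of its peak "
                       "deviation within the window", 100 * frac)
        return None
    # last index still at/above threshold
    above_idx = np.flatnonzero(~below)
    if above_idx.size == 0:
        return 0.0
    first_settled = above_idx[-1] + 1
    return float(tail.times[first_settled] - stim_end)


def steady_state_time(ts: TimeSeries, window: float = 1.0,
                      tol: float = 0.05) -> float | None:
    """Earliest time (relative to the trace start) after which the signal
    stays within ``tol`` of its final excursion.

    The trace is smoothed with a moving mean of length ``window`` seconds
    to suppress spike-locked oscillations; the settling band is
    ``tol * |final - initial|`` around the final (smoothed) value.
    Returns ``None`` if the band is never entered for good.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must lie in (0, 1)")
    v = ts.values.astype(float)
    if ts.dt > 0 and window > ts.dt and v.size > 3:
        n = max(1, int(round(window / ts.dt)))
        kernel = np.ones(n) / n
        # 'same' convolution with edge correction
        smooth = np.convolve(v, kernel, mode="same")
        norm = np.convolve(np.ones_like(v), kernel, mode="same")
        v = smooth / norm
    final = v[-1]
    initial = v[0]
    excursion = abs(final - initial)
    if excursion == 0.0:
        return 0.0
    outside = np.abs(v - final) > tol * excursion
    idx = np.flatnonzero(outside)
    if idx.size == 0:
        return 0.0
    if idx[-1] == v.size - 1:
        return None
    return float(ts.times[idx[-1] + 1] - ts.times[0])


def oscillation_amplitude(ts: TimeSeries, t_start: float,
                          t_end: float, min_cycles: int = 5) -> float | None:
    """Mean peak-to-peak excursion over detected oscillation cycles.

    Peaks and troughs are located with a prominence floor of 1% of the
    window's total range; ``None`` is returned when fewer than
    ``min_cycles`` cycles are present (e.g. a constant trace).
    """
    w = ts.window(t_start, t_end)
    v = w.values
    vrange = v.max() - v.min()
    if vrange == 0.0:
        return None
    prom = 0.01 * vrange
    peaks, _ = find_peaks(v, prominence=prom)
    troughs, _ = find_peaks(-v, prominence=prom)
    if peaks.size < min_cycles or troughs.size < min_cycles:
        return None
    # pair each peak with the nearest following trough
    p2p = []
    j = 0
    for i in peaks:
        while j < troughs.size and troughs[j] <= i:
            j += 1
        if j >= troughs.size:
            break
        p2p.append(v[i] - v[troughs[j]])
    if len(p2p) < min_cycles:
        return None
    return float(np.mean(p2p))


def peak_current_ratio(membrane: TimeSeries, process: TimeSeries,
                       t_start: float, t_end: float) -> float | None:
    """``log10(max|membrane| / max|process|)`` over a common window."""
    m = membrane.window(t_start, t_end)
    p = process.window(t_start, t_end)
    peak_m = np.abs(m.values).max()
    peak_p = np.abs(p.values).max()
    if peak_p == 0.0:
        logger.warning("peak_current_ratio: process current identically zero")
        return None
    return float(np.log10(peak_m / peak_p))


def summarize(result, stim_start: float | None = None,
              stim_end: float | None = None) -> SummaryMetrics:
    """Standard summary of a :class:`pscsim.model.SimulationResult`."""
    proto = result.metadata["protocol"]
    stim_start = proto["stim_start"] if stim_start is None else stim_start
    stim_end = proto["stim_end"] if stim_end is None else stim_end
    st = result.states
    metrics = SummaryMetrics()
    metrics.extrema = {
        "peak_K_PsC": float(st["K_PsC"].max()),
        "trough_K_PsC": float(st["K_PsC"].min()),
        "peak_Na_PsC": float(st["Na_PsC"].max()),
        "trough_Na_PsC": float(st["Na_PsC"].min()),
        "peak_K_PsECS": float(st["K_PsECS"].max()),
        "V_A_min": float(st["V_A"].min()),
        "V_A_max": float(st["V_A"].max()),
    }
    t = result.times
    if stim_end < t[-1]:
        mem = TimeSeries(t, result.currents["I_K_membrane"].to_numpy(),
                         "I_K_membrane", "A")
        pf = TimeSeries(t, result.currents["I_KPF"].to_numpy(), "I_KPF", "A")
        metrics.peak_current_ratio_log10 = peak_current_ratio(
            mem, pf, stim_start, stim_end)
        va = TimeSeries(t, st["V_A"].to_numpy(), "V_A", "V")
        metrics.oscillation_amplitude = oscillation_amplitude(
            va, stim_start, stim_end)
    return metrics
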