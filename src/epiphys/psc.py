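"""Postsynaptic-current metrics: spontaneous events, paired-pulse ratio, E/I.

Covers the three whole-cell voltage-clamp measurements of the pipeline:

* spontaneous PSC detection (frequency in Hz and mean baseline-to-peak
  amplitude in pA), via an amplitude threshold on the lightly smoothed,
  polarity-rectified trace — threshold defaults to 3x a robust
  (median-absolute-deviation) noise SD;
* paired-pulse ratio, PPR = A2/A1 at a fixed inter-stimulus interval
  (100 ms by convention), with optional subtraction of the extrapolated
  single-exponential decay of the first response before measuring the
  second — an inverse index of presynaptic release probability;
* excitation/inhibition balance from compound PSCs recorded at -40 mV:
  the early inward lobe is the excitatory component, the delayed outward
  lobe the inhibitory one; peak amplitudes and total lobe areas (pA*ms,
  trapezoidal) give the peak and area E/I ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .recordings import SweepRecording

__all__ = [
    "PscEvent",
    "EIResult",
    "detect_spontaneous",
    "paired_pulse_ratio",
    "compound_ei",
    "robust_noise_sd",
]


@dataclass
class PscEvent:
    time_ms: float
    amplitude_pa: float  # baseline-to-peak magnitude, polarity-rectified
    polarity: str


@dataclass
class EIResult:
    exc_peak_pa: float
    inh_peak_pa: float
    exc_area_pams: float
    inh_area_pams: float
    ei_peak_ratio: float  # NaN when the inhibitory component is absent
    ei_area_ratio: float


def robust_noise_sd(x: np.ndarray) -> float:
    """MAD-based noise SD, insensitive to sparse large events."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_spontaneous(
    sweep: SweepRecording,
    polarity: str = "inward",
    threshold_pa: float | None = None,
    min_interval_ms: float = 5.0,
    smooth_ms: float = 1.25,
    threshold_sd: float = 3.0,
) -> tuple[list[PscEvent], float, float]:
    """Detect spontaneous PSCs; return (events, frequency_hz, mean_amp_pa).

    Events are local maxima of the polarity-rectified, baseline-subtracted
    sweep (smoothed over ``smooth_ms``) that exceed ``threshold_pa``
    (default ``threshold_sd`` x robust noise SD) and are separated by at
    least ``min_interval_ms``. Amplitude is re-measured on the raw trace
    as the mean over a short window centred on the detected peak, which
    keeps it unbiased by the peak-picking noise.
    """
    if sweep.n_samples == 0:
        raise ValueError("empty sweep")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    if threshold_pa is not None and threshold_pa <= 0:
        raise ValueError("threshold_pa must be positive")
    sign = -1.0 if polarity == "inward" else 1.0
    x = sign * (sweep.values - np.median(sweep.values))
    if threshold_pa is None:
        threshold_pa = threshold_sd * robust_noise_sd(x)
        if threshold_pa == 0:
            threshold_pa = np.finfo(float).tiny
    width = max(1, int(round(smooth_ms * sweep.sample_rate_hz / 1000.0)))
    xs = _smooth(x, width)
    dist = max(1, int(round(min_interval_ms * sweep.sample_rate_hz / 1000.0)))
    # the prominence requirement stops noise maxima riding on the decay of
    # a detected event from double-counting it
    peaks, _ = find_peaks(
        xs, height=threshold_pa, prominence=threshold_pa, distance=dist
    )
    # amplitude is peak minus a local pre-event baseline (median over a
    # window just before the rise), which discounts the residual decay of
    # any preceding event
    pre_lo = int(round(20.0 * sweep.sample_rate_hz / 1000.0))
    pre_hi = int(round(5.0 * sweep.sample_rate_hz / 1000.0))
    events = []
    for p in peaks:
        pre = x[max(0, p - pre_lo) : max(0, p - pre_hi)]
        local_base = float(np.median(pre)) if len(pre) else 0.0
        events.append(
            PscEvent(
                time_ms=p * 1000.0 / sweep.sample_rate_hz,
                amplitude_pa=float(xs[p] - local_base),
                polarity=polarity,
            )
        )
    freq = len(events) / sweep.duration_s
    mean_amp = float(np.mean([e.amplitude_pa for e in events])) if events else float("nan")
    return events, freq, mean_amp


def _fit_exp_tail(t_ms: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Log-linear single-exponential fit ``y = A exp(-t/tau)``; None if ill-posed."""
    good = y > 0
    if good.sum() < max(4, len(y) // 2):
        return None
    coef = np.polyfit(t_ms[good], np.log(y[good]), 1)
    if coef[0] >= 0:  # not decaying
        return None
    tau = -1.0 / coef[0]
    return math.exp(coef[1]), tau


def paired_pulse_ratio(
    sweep: SweepRecording,
    stim_times_ms: tuple[float, float] | None = None,
    decay_correction: bool = True,
    polarity: str = "inward",
    baseline_ms: float = 10.0,
    peak_window_ms: tuple[float, float] = (2.0, 50.0),
) -> float:
    """PPR = A2 / A1, amplitudes baseline-to-peak after the two stimuli.

    With ``decay_correction`` (on by default at the conventional 100 ms
    interval) the residual decay of response 1 is estimated from a
    single-exponential fit on the last 40% of the inter-stimulus segment
    and subtracted before measuring A2.
    """
    stims = list(stim_times_ms) if stim_times_ms is not None else list(sweep.stim_times_ms)
    if len(stims) != 2:
        raise ValueError(f"need exactly two stimulus times, got {len(stims)}")
    t1, t2 = sorted(stims)
    sign = -1.0 if polarity == "inward" else 1.0
    fs = sweep.sample_rate_hz

    i_base0 = max(0, sweep.index_at_ms(t1 - baseline_ms))
    i_base1 = sweep.index_at_ms(t1)
    base_seg = sweep.values[i_base0:i_base1]
    baseline = float(base_seg.mean()) if len(base_seg) else 0.0
    noise = float(base_seg.std()) if len(base_seg) > 1 else 0.0
    x = sign * (sweep.values - baseline)
    t_ms = sweep.times_ms

    def window(t_stim: float, t_limit: float) -> slice:
        lo = sweep.index_at_ms(t_stim + peak_window_ms[0])
        hi = min(sweep.index_at_ms(min(t_stim + peak_window_ms[1], t_limit)),
                 sweep.n_samples)
        if hi <= lo:
            raise ValueError("peak window collapses; check stimulus times")
        return slice(lo, hi)

    w1 = window(t1, t2)
    a1 = float(x[w1].max())
    if a1 <= max(3.0 * noise, 1e-12):
        raise ValueError(
            f"first response ({a1:.3g} pA) is below the noise floor; PPR undefined"
        )

    w2 = window(t2, sweep.duration_ms)
    residual = np.zeros(sweep.n_samples)
    if decay_correction:
        tail_lo = sweep.index_at_ms(t2 - 0.4 * (t2 - t1))
        tail_hi = sweep.index_at_ms(t2)
        tail = x[tail_lo:tail_hi]
        if len(tail) >= 4 and tail.mean() > 0.5 * noise:
            fit = _fit_exp_tail(t_ms[tail_lo:tail_hi] - t1, tail)
            if fit is not None:
                amp, tau = fit
                residual = amp * np.exp(-(t_ms - t1) / tau)
                residual[t_ms < t1] = 0.0
    a2 = float((x - residual)[w2].max())
    return a2 / a1


def compound_ei(
    sweep: SweepRecording,
    stim_time_ms: float | None = None,
    blank_ms: float = 2.0,
    baseline_ms: float = 10.0,
    noise_floor_sd: float = 3.0,
) -> EIResult:
    """Decompose a compound PSC at -40 mV into excitatory and inhibitory lobes.

    After baseline subtraction and a stimulus-artifact blanking window,
    the negative (inward) portion of the post-stimulus trace is the
    excitatory component and the positive (outward) portion the
    inhibitory one; lobe peak = extremum magnitude, lobe area =
    trapezoidal integral of the rectified portion in pA*ms. A missing
    outward phase yields zero inhibitory magnitudes and NaN ratios.
    """
    if stim_time_ms is None:
        if len(sweep.stim_times_ms) != 1:
            raise ValueError("sweep must carry exactly one stimulus time")
        stim_time_ms = sweep.stim_times_ms[0]
    i_base0 = max(0, sweep.index_at_ms(stim_time_ms - baseline_ms))
    i_base1 = sweep.index_at_ms(stim_time_ms)
    base_seg = sweep.values[i_base0:i_base1]
    baseline = float(base_seg.mean()) if len(base_seg) else 0.0
    noise = float(base_seg.std()) if len(base_seg) > 1 else 0.0

    i0 = sweep.index_at_ms(stim_time_ms + blank_ms)
    y = sweep.values[i0:] - baseline
    dt_ms = 1000.0 / sweep.sample_rate_hz
    neg = np.clip(y, None, 0.0)
    pos = np.clip(y, 0.0, None)
    exc_peak = float(-neg.min()) if len(y) else 0.0
    inh_peak = float(pos.max()) if len(y) else 0.0
    exc_area = float(np.trapezoid(-neg, dx=dt_ms))
    inh_area = float(np.trapezoid(pos, dx=dt_ms))

    if inh_peak <= max(noise_floor_sd * noise, 0.0) or inh_peak == 0.0:
        return EIResult(exc_peak, 0.0, exc_area, 0.0, float("nan"), float("nan"))
    return EIResult(
        exc_peak, inh_peak, exc_area, inh_area,
        exc_peak / inh_peak, exc_area / inh_area,
    )
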