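"""Field-EPSP measurement, input-output curves, population-spike threshold.

An extracellular field sweep after a stimulus contains, in order: the
stimulus artifact (blanked), the fiber volley (fast presynaptic
deflection, amplitude roughly linear in stimulus intensity), and the
fEPSP proper — a slower negative-going field whose baseline-to-peak
amplitude and rising-phase slope index synaptic drive. At sufficient
intensity a positive-going population spike (Ps) rides on the fEPSP
trough, signalling postsynaptic firing; the lowest intensity at which it
appears is the Ps threshold, a standard readout of neuronal excitability.

Slope is a least-squares line over the 20-80% span of the rising
(descending-voltage) phase, the field's usual convention; the Ps
criterion is a notch prominence of 10% of the fEPSP amplitude, with an
absolute-mV alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .recordings import SweepRecording
from .stats import ComparisonResult, compare_two

__all__ = [
    "FepspMeasure",
    "IOCurve",
    "measure_fepsp",
    "build_io",
    "compare_io",
    "ps_threshold",
    "fc_ppr_effect",
    "PairedEffect",
]


@dataclass
class FepspMeasure:
    intensity_ua: float
    fv_amp_mv: float
    fepsp_amp_mv: float
    fepsp_slope_mv_per_ms: float  # magnitude of the rising-phase slope
    ps_present: bool
    ps_amp_mv: float
    ok: bool = True  # False when no deflection rose above the noise floor


@dataclass
class IOCurve:
    measures: list[FepspMeasure]

    def __post_init__(self) -> None:
        ints = [m.intensity_ua for m in self.measures]
        if any(b <= a for a, b in zip(ints, ints[1:])):
            raise ValueError("intensities must be strictly increasing")

    @property
    def intensities(self) -> np.ndarray:
        return np.array([m.intensity_ua for m in self.measures])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([m.fepsp_amp_mv for m in self.measures])

    @property
    def ps_threshold_ua(self) -> float:
        """Lowest intensity with a population spike; NaN if none."""
        for m in self.measures:
            if m.ps_present:
                return m.intensity_ua
        return float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.measures])


def measure_fepsp(
    sweep: SweepRecording,
    stim_time_ms: float | None = None,
    intensity_ua: float = float("nan"),
    blank_ms: float = 2.0,
    baseline_ms: float = 10.0,
    fv_window_ms: tuple[float, float] = (2.0, 4.5),
    fepsp_window_ms: tuple[float, float] = (4.5, 50.0),
    slope_span: tuple[float, float] = (0.2, 0.8),
    ps_prominence_frac: float = 0.10,
    ps_abs_mv: float | None = None,
) -> FepspMeasure:
    """Measure one field sweep: fiber volley, fEPSP amplitude/slope, Ps flag.

    All windows are in ms relative to the stimulus; the artifact is
    ignored inside ``blank_ms``. A sweep with no post-stimulus deflection
    above the noise floor returns a zeroed measure flagged ``ok=False``.
    """
    if stim_time_ms is None:
        if len(sweep.stim_times_ms) != 1:
            raise ValueError("sweep must carry exactly one stimulus time")
        stim_time_ms = sweep.stim_times_ms[0]
    t_ms = sweep.times_ms
    i_base0 = max(0, sweep.index_at_ms(stim_time_ms - baseline_ms))
    i_base1 = sweep.index_at_ms(stim_time_ms)
    base_seg = sweep.values[i_base0:i_base1]
    baseline = float(base_seg.mean()) if len(base_seg) else 0.0
    noise = float(base_seg.std()) if len(base_seg) > 1 else 0.0
    y = sweep.values - baseline

    def win(lo_ms: float, hi_ms: float) -> slice:
        lo = sweep.index_at_ms(stim_time_ms + max(lo_ms, blank_ms))
        hi = min(sweep.index_at_ms(stim_time_ms + hi_ms), sweep.n_samples)
        return slice(lo, hi)

    w_fv = win(*fv_window_ms)
    fv_amp = max(0.0, float(-y[w_fv].min())) if w_fv.stop > w_fv.start else 0.0

    w_f = win(*fepsp_window_ms)
    seg = y[w_f]
    if len(seg) == 0 or -seg.min() <= max(3.0 * noise, 0.0):
        return FepspMeasure(intensity_ua, fv_amp, 0.0, 0.0, False, 0.0, ok=False)
    trough_rel = int(np.argmin(seg))
    amp = float(-seg[trough_rel])

    # slope: fit over the 20-80% amplitude span of the falling limb
    rising = seg[: trough_rel + 1]
    depth = -rising
    sel = (depth >= slope_span[0] * amp) & (depth <= slope_span[1] * amp)
    slope = 0.0
    if sel.sum() >= 2:
        tt = t_ms[w_f][: trough_rel + 1][sel]
        slope = abs(float(np.polyfit(tt, rising[sel], 1)[0]))

    # population spike: positive-going notch inside the fEPSP trough
    crit = ps_abs_mv if ps_abs_mv is not None else ps_prominence_frac * amp
    crit = max(crit, 7.0 * noise)  # never let baseline noise pass as a notch
    peaks, props = find_peaks(seg, prominence=crit)
    # the notch rides inside the trough, below the pre-stimulus baseline
    in_trough = [i for i, p in enumerate(peaks) if seg[p] < 0]
    ps_present = len(in_trough) > 0
    ps_amp = (
        float(max(props["prominences"][i] for i in in_trough)) if ps_present else 0.0
    )
    return FepspMeasure(intensity_ua, fv_amp, amp, slope, ps_present, ps_amp)


def build_io(measures: list[FepspMeasure]) -> IOCurve:
    """Order measures by intensity into an input-output curve."""
    return IOCurve(sorted(measures, key=lambda m: m.intensity_ua))


def ps_threshold(curve: IOCurve) -> float:
    """Lowest stimulus intensity that evokes a population spike (NaN if none)."""
    return curve.ps_threshold_ua


def compare_io(curve_a: IOCurve, curve_b: IOCurve) -> tuple[pd.DataFrame, float]:
    """Per-intensity fEPSP amplitude ratios b/a and their mean.

    Only intensities present in both curves are compared; raises when the
    curves share none.
    """
    a = {m.intensity_ua: m.fepsp_amp_mv for m in curve_a.measures}
    b = {m.intensity_ua: m.fepsp_amp_mv for m in curve_b.measures}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("curves share no stimulus intensities")
    rows = [
        dict(intensity_ua=i, amp_a_mv=a[i], amp_b_mv=b[i],
             ratio=b[i] / a[i] if a[i] != 0 else float("nan"))
        for i in shared
    ]
    table = pd.DataFrame(rows)
    return table, float(table["ratio"].mean())


@dataclass
class PairedEffect:
    """Before/after paired comparison of a per-slice metric (e.g. PPR)."""

    diffs: np.ndarray
    mean_before: float
    mean_after: float
    mean_change: float
    comparison: ComparisonResult = field(repr=False, default=None)


def fc_ppr_effect(ppr_before, ppr_after) -> PairedEffect:
    """Paired before/after effect on PPR (e.g. fluorocitrate perfusion)."""
    before = np.asarray(list(ppr_before), dtype=float)
    after = np.asarray(list(ppr_after), dtype=float)
    if len(before) != len(after):
        raise ValueError("paired samples must have equal length")
    diffs = after - before
    comparison = compare_two(before, after, paired=True) if len(before) >= 3 else None
    return PairedEffect(
        diffs=diffs,
        mean_before=float(before.mean()),
        mean_after=float(after.mean()),
        mean_change=float(diffs.mean()),
        comparison=comparison,
    )
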