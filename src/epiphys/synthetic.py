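"""Ground-truth synthetic signal generators for all four modalities.

These generators emulate the recordings the analysis stages were designed
for — 1 Hz / 5 min astrocyte soma fluorescence, 4 kHz whole-cell current
sweeps, field-potential input-output families, and 1 kHz LFP — with every
injected event recorded in a :class:`GroundTruth` table so that detection,
classification and effect-recovery can be verified end to end.

Design notes
------------
* Calcium transients use a rise-plateau-decay profile whose
  supra-threshold span equals the drawn duration exactly, which makes
  duration recovery well-posed; the supra-threshold criterion is
  2 x ``noise_sd`` in raw fluorescence units.
* Spontaneous synaptic events are a Poisson process convolved with a
  biexponential kernel; amplitudes are lognormal (hence positive).
* Fiber volley grows linearly with stimulus intensity while the fEPSP
  follows a saturating (Hill) curve, so a condition effect on synaptic
  gain is a pure amplitude-scale multiplier at every intensity.
* LFP background is 1/f ("pink") by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .recordings import FluorTrace, LfpRecording, SweepRecording

__all__ = [
    "CaSimConfig",
    "PscSimConfig",
    "LfpSimConfig",
    "GroundTruth",
    "gen_calcium_traces",
    "gen_psc_sweep",
    "gen_paired_pulse",
    "gen_compound_psc",
    "gen_fepsp_family",
    "gen_lfp",
    "biexp_kernel",
]


@dataclass
class GroundTruth:
    """Injected-event bookkeeping: one row per event, plus free-form params."""

    events: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# calcium imaging
# ---------------------------------------------------------------------------

@dataclass
class CaSimConfig:
    """Fluorescence-trace simulation: 1 Hz frames, 5 min recordings.

    ``event_amp_dist`` is in multiples of ``noise_sd``; transient durations
    are lognormal per class, parameterised by (mean of log-seconds, SD of
    log-seconds). Defaults put ~99% of fast-transient (FT) durations below
    and ~99% of slow-transient (ST) durations above the 23.1 s class
    boundary.
    """

    n_cells: int = 10
    n_frames: int = 300
    frame_period_s: float = 1.0
    baseline_level: float = 3000.0
    background: float = 200.0
    noise_sd: float = 30.0
    event_rate_per_min: float = 1.2
    st_fraction: float = 0.25
    ft_duration_dist: tuple[float, float] = (math.log(9.0), 0.30)
    st_duration_dist: tuple[float, float] = (math.log(40.0), 0.20)
    event_amp_dist: tuple[float, float] = (10.0, 2.0)
    drift_slope: float = 0.0
    merged_fraction: float = 0.0  # fraction of events built as 2-peak complexes
    amp_unit_au: float | None = None  # amplitude/threshold unit; noise_sd if None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.st_fraction <= 1.0:
            raise ValueError("st_fraction must lie in [0, 1]")
        if self.n_frames < 30:
            raise ValueError("n_frames must be >= 30 to admit a baseline window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.unit_au <= 0:
            raise ValueError(
                "event amplitudes are expressed in multiples of noise_sd; "
                "a noiseless run must set amp_unit_au > 0 explicitly"
            )
        if self.event_rate_per_min < 0 or self.n_cells < 1:
            raise ValueError("rates and counts must be non-negative")
        if self.baseline_level <= self.background:
            raise ValueError("baseline_level must exceed background")

    @property
    def unit_au(self) -> float:
        """AU unit for event amplitudes and the supra-threshold criterion."""
        return self.noise_sd if self.amp_unit_au is None else self.amp_unit_au


def _transient_profile(n_d: int, amp: float, thr: float) -> np.ndarray:
    """Rise-plateau-decay profile: exactly ``n_d`` frames at/above ``thr``."""
    if n_d == 1:
        return np.array([amp])
    rise = max(1, round(0.1 * n_d))
    # keep the decay short so only the last frame or two sit near threshold
    decay = min(max(1, round(0.15 * n_d)), n_d - rise)
    plateau = n_d - rise - decay
    parts = [np.linspace(1.3 * thr, amp, rise)]
    if plateau:
        parts.append(np.full(plateau, amp))
    # geometric fall from amp to just above threshold at the last frame
    parts.append(amp * (1.2 * thr / amp) ** (np.arange(1, decay + 1) / decay))
    return np.concatenate(parts)


def _merged_profile(
    d1: int, d2: int, a1: float, a2: float, thr: float
) -> np.ndarray:
    """Two-peak complex with a trough at 40% of the smaller peak (frame d1-1)."""
    trough = 0.4 * min(a1, a2)
    r1 = max(1, round(0.1 * d1))
    r2 = max(1, round(0.1 * d2))
    segs = [
        np.linspace(1.3 * thr, a1, r1),
        np.linspace(a1, trough, d1 - r1 + 1)[1:],
        np.linspace(trough, a2, r2 + 1)[1:],
        np.linspace(a2, 1.2 * thr, d2 - r2 + 1)[1:],
    ]
    return np.concatenate(segs)


_TAIL = np.array([0.3, 0.1, 0.03])  # sub-threshold decay tail, x thr


def gen_calcium_traces(cfg: CaSimConfig) -> tuple[list[FluorTrace], GroundTruth]:
    """Simulate per-soma fluorescence traces with known transients.

    Each trace is baseline + linear drift + Gaussian noise + injected
    transients; frames 0-29 are kept event-free so a quiet baseline window
    always exists. Raises when the requested events cannot be placed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    thr = 2.0 * cfg.unit_au
    minutes = cfg.n_frames * cfg.frame_period_s / 60.0
    traces: list[FluorTrace] = []
    rows: list[dict] = []

    for ci in range(cfg.n_cells):
        cell_id = f"cell_{ci:03d}"
        values = np.full(cfg.n_frames, cfg.baseline_level, dtype=float)
        values += cfg.drift_slope * np.arange(cfg.n_frames)
        n_ev = rng.poisson(cfg.event_rate_per_min * minutes)
        occupied = np.zeros(cfg.n_frames, dtype=bool)
        occupied[:34] = True  # reserved quiet window + margin

        specs = []
        for _ in range(n_ev):
            merged = rng.random() < cfg.merged_fraction
            if merged:
                durs = np.exp(
                    rng.normal(*cfg.ft_duration_dist, size=2)
                )
                nds = np.maximum(
                    5, np.round(durs / cfg.frame_period_s).astype(int)
                )
                amps = (
                    np.clip(rng.normal(*cfg.event_amp_dist, size=2), 6.0, None)
                    * cfg.unit_au
                )
                profile = _merged_profile(nds[0], nds[1], amps[0], amps[1], thr)
                specs.append(("merged", profile, nds, amps, ("FT", "FT")))
            else:
                is_st = rng.random() < cfg.st_fraction
                dist = cfg.st_duration_dist if is_st else cfg.ft_duration_dist
                dur = float(np.exp(rng.normal(*dist)))
                # clamp at the 5-frame detectability floor: shorter
                # excursions are not events under the detection criterion
                n_d = max(5, round(dur / cfg.frame_period_s))
                amp = (
                    max(3.0, rng.normal(*cfg.event_amp_dist)) * cfg.unit_au
                )
                profile = _transient_profile(n_d, amp, thr)
                specs.append(
                    ("single", profile, (n_d,), (amp,), ("ST" if is_st else "FT",))
                )

        tail = len(_TAIL)
        # place longest events first so a long transient is never starved
        # of a gap by earlier short placements
        for kind, profile, nds, amps, labels in sorted(
            specs, key=lambda s: len(s[1]), reverse=True
        ):
            span = len(profile)
            hi = cfg.n_frames - span - tail - 2
            # a valid onset needs span+tail plus a 2-frame margin both sides
            # free; enumerate all of them and draw one uniformly
            need = span + tail + 4
            if 34 + need > cfg.n_frames:
                raise ValueError(
                    f"n_frames={cfg.n_frames} too small to host a "
                    f"{span}-frame event plus the 30-frame quiescent "
                    "window; raise n_frames or shorten durations"
                )
            free_run = np.lib.stride_tricks.sliding_window_view(
                ~occupied, need
            ).all(axis=1)
            valid = [v for v in (np.flatnonzero(free_run) + 2) if 34 <= v <= hi]
            if not valid:
                if 34 + need > cfg.n_frames:
                    # the event cannot fit even in an empty trace
                    raise ValueError(
                        f"n_frames={cfg.n_frames} too small to host a "
                        f"{span}-frame event plus the 30-frame quiescent "
                        "window; raise n_frames or shorten durations"
                    )
                # feasible config, crowded draw: censor this event (the trace
                # is full); it is injected nowhere and recorded nowhere
                continue
            onset = int(rng.choice(valid))
            values[onset : onset + span] += profile
            values[onset + span : onset + span + tail] += thr * _TAIL
            occupied[onset - 2 : onset + span + tail + 2] = True

            sub_onset = onset
            for nd, a, lab in zip(nds, amps, labels):
                rows.append(dict(
                    signal_id=cell_id, onset_frame=int(sub_onset),
                    n_frames=int(nd), duration_s=nd * cfg.frame_period_s,
                    amp_au=float(a), label=lab, merged=(kind == "merged"),
                ))
                sub_onset += int(nd)

        if cfg.noise_sd > 0:
            values += rng.normal(0.0, cfg.noise_sd, size=cfg.n_frames)
        traces.append(
            FluorTrace(cell_id, cfg.frame_period_s, values, cfg.background)
        )

    columns = ["signal_id", "onset_frame", "n_frames", "duration_s",
               "amp_au", "label", "merged"]
    truth = GroundTruth(
        events=pd.DataFrame(rows, columns=columns),
        params={"config": cfg, "threshold_au": thr},
    )
    return traces, truth


# ---------------------------------------------------------------------------
# synaptic currents
# ---------------------------------------------------------------------------

@dataclass
class PscSimConfig:
    """Spontaneous postsynaptic-current sweep simulation (4 kHz default)."""

    sweep_duration_s: float = 60.0
    sample_rate_hz: float = 4000.0
    event_rate_hz: float = 1.0
    amp_dist: tuple[float, float] = (20.0, 5.0)  # pA (mean, sd)
    rise_tau_ms: float = 1.5
    decay_tau_ms: float = 12.0
    polarity: str = "inward"
    noise_sd_pa: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.rise_tau_ms >= self.decay_tau_ms:
            raise ValueError("rise_tau must be shorter than decay_tau")
        if self.event_rate_hz < 0 or self.noise_sd_pa < 0 or self.amp_dist[1] < 0:
            raise ValueError("rates and SDs must be non-negative")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")

    @property
    def time_to_peak_ms(self) -> float:
        tr, td = self.rise_tau_ms, self.decay_tau_ms
        return tr * td / (td - tr) * math.log(td / tr)


def biexp_kernel(cfg: PscSimConfig, n_samples: int | None = None) -> np.ndarray:
    """Unit-peak biexponential kernel ``exp(-t/tau_d) - exp(-t/tau_r)``."""
    dt_ms = 1000.0 / cfg.sample_rate_hz
    if n_samples is None:
        n_samples = int(8 * cfg.decay_tau_ms / dt_ms)
    t = np.arange(n_samples) * dt_ms
    k = np.exp(-t / cfg.decay_tau_ms) - np.exp(-t / cfg.rise_tau_ms)
    return k / k.max()


def _lognormal_amps(rng, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def gen_psc_sweep(cfg: PscSimConfig) -> tuple[SweepRecording, GroundTruth]:
    """Poisson train of biexponential PSCs plus Gaussian noise."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.sweep_duration_s * cfg.sample_rate_hz))
    values = np.zeros(n)
    n_ev = rng.poisson(cfg.event_rate_hz * cfg.sweep_duration_s)
    times_ms = np.sort(rng.uniform(0.0, cfg.sweep_duration_s * 1000.0, n_ev))
    amps = _lognormal_amps(rng, *cfg.amp_dist, n_ev)
    kernel = biexp_kernel(cfg)
    sign = -1.0 if cfg.polarity == "inward" else 1.0
    for t_ms, a in zip(times_ms, amps):
        i0 = int(round(t_ms * cfg.sample_rate_hz / 1000.0))
        seg = kernel[: n - i0]
        values[i0 : i0 + len(seg)] += sign * a * seg
    if cfg.noise_sd_pa > 0:
        values += rng.normal(0.0, cfg.noise_sd_pa, n)
    sweep = SweepRecording(cfg.sample_rate_hz, values, modality="voltage_clamp")
    truth = GroundTruth(
        events=pd.DataFrame(
            {"time_ms": times_ms, "amplitude_pa": amps}
        ),
        params={"config": cfg},
    )
    return sweep, truth


def gen_paired_pulse(
    a1_pa: float,
    ppr_true: float,
    isi_ms: float = 100.0,
    kernel: PscSimConfig | None = None,
    pre_ms: float = 50.0,
) -> SweepRecording:
    """Two evoked responses with true peak amplitudes ``a1`` and ``a1*ppr_true``.

    Responses are additive, so the true ratio is recoverable once the
    residual decay of the first response is subtracted before measuring
    the second peak. The default inter-stimulus interval is 100 ms.
    """
    if a1_pa <= 0 or ppr_true <= 0:
        raise ValueError("a1_pa and ppr_true must be positive")
    cfg = kernel if kernel is not None else PscSimConfig(noise_sd_pa=0.0)
    cfg.validate()
    if isi_ms < cfg.time_to_peak_ms:
        raise ValueError(
            f"isi_ms={isi_ms} shorter than the kernel rise "
            f"(time to peak {cfg.time_to_peak_ms:.2f} ms)"
        )
    rng = np.random.default_rng(cfg.seed)
    dur_ms = pre_ms + isi_ms + 10 * cfg.decay_tau_ms
    n = int(round(dur_ms * cfg.sample_rate_hz / 1000.0))
    values = np.zeros(n)
    k = biexp_kernel(cfg)
    stims = [pre_ms, pre_ms + isi_ms]
    for t_ms, amp in zip(stims, (a1_pa, a1_pa * ppr_true)):
        i0 = int(round(t_ms * cfg.sample_rate_hz / 1000.0))
        seg = k[: n - i0]
        values[i0 : i0 + len(seg)] += -amp * seg  # EPSCs inward
    if cfg.noise_sd_pa > 0:
        values += rng.normal(0.0, cfg.noise_sd_pa, n)
    return SweepRecording(cfg.sample_rate_hz, values, stim_times_ms=stims)


def gen_compound_psc(
    exc_peak_pa: float,
    exc_area_pams: float,
    inh_peak_pa: float,
    inh_area_pams: float,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 4000.0,
    stim_ms: float = 50.0,
    exc_latency_ms: float = 3.0,
    gap_ms: float = 1.0,
) -> SweepRecording:
    """Compound PSC at -40 mV: early inward lobe then delayed outward lobe.

    Each lobe is a half-sine with independently specified peak and area
    (width follows as ``pi * area / (2 * peak)``); the lobes are disjoint
    in time so zero-crossing decomposition recovers the configured values
    exactly on noiseless sweeps.
    """
    for v in (exc_peak_pa, exc_area_pams, inh_peak_pa, inh_area_pams):
        if v < 0:
            raise ValueError("peaks and areas must be non-negative")
    dt_ms = 1000.0 / sample_rate_hz

    def half_sine(peak: float, area: float) -> np.ndarray:
        if peak == 0 or area == 0:
            return np.zeros(0)
        w_ms = math.pi * area / (2.0 * peak)
        m = max(2, int(round(w_ms / dt_ms)))
        return peak * np.sin(np.pi * np.arange(m) * dt_ms / w_ms)

    exc = half_sine(exc_peak_pa, exc_area_pams)
    inh = half_sine(inh_peak_pa, inh_area_pams)
    exc_start_ms = stim_ms + exc_latency_ms
    inh_start_ms = exc_start_ms + len(exc) * dt_ms + gap_ms
    dur_ms = inh_start_ms + len(inh) * dt_ms + 20.0
    n = int(round(dur_ms / dt_ms))
    values = np.zeros(n)
    i0 = int(round(exc_start_ms / dt_ms))
    values[i0 : i0 + len(exc)] -= exc
    i1 = int(round(inh_start_ms / dt_ms))
    values[i1 : i1 + len(inh)] += inh
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd_pa, n)
    return SweepRecording(
        sample_rate_hz, values, stim_times_ms=[stim_ms], holding_mv=-40.0
    )


# ---------------------------------------------------------------------------
# field potentials
# ---------------------------------------------------------------------------

def _hill(i: np.ndarray | float, i50: float, h: float) -> np.ndarray | float:
    return i**h / (i**h + i50**h)


def gen_fepsp_family(
    intensities_ua: Sequence[float],
    amp_scale_mv: float,
    ps_threshold_ua: float,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 10000.0,
    fv_scale_mv_per_ua: float = 0.004,
    i50_ua: float = 60.0,
    hill_coef: float = 2.0,
    ps_frac: float = 0.25,
) -> list[tuple[float, SweepRecording]]:
    """One field sweep per stimulus intensity.

    Each sweep carries a stimulus artifact, a fiber volley growing
    linearly with intensity, a negative-going fEPSP whose amplitude is
    ``amp_scale_mv`` times a saturating Hill function of intensity, and —
    at intensities at or above ``ps_threshold_ua`` — a positive-going
    population-spike notch riding on the fEPSP trough. Everything
    postsynaptic scales with ``amp_scale_mv``, so a condition that
    multiplies synaptic gain shows up as the same fold-change at every
    intensity.
    """
    intensities = list(intensities_ua)
    if sorted(intensities) != intensities:
        raise ValueError("intensities must be sorted ascending")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sample_rate_hz
    dur_ms, stim_ms = 80.0, 10.0
    n = int(round(dur_ms / dt_ms))
    t_ms = np.arange(n) * dt_ms
    family = []
    for inten in intensities:
        v = np.zeros(n)
        # stimulus artifact: sharp biphasic pulse within the blanking window
        art = (t_ms >= stim_ms) & (t_ms < stim_ms + 0.4)
        v[art] += 2.0
        art2 = (t_ms >= stim_ms + 0.4) & (t_ms < stim_ms + 0.8)
        v[art2] -= 2.0
        # fiber volley: fast negative Gaussian, linear in intensity
        v -= (fv_scale_mv_per_ua * inten) * np.exp(
            -0.5 * ((t_ms - (stim_ms + 3.0)) / 0.25) ** 2
        )
        # fEPSP: negative half-sine, onset 5 ms post-stimulus, 25 ms wide
        amp = amp_scale_mv * _hill(inten, i50_ua, hill_coef)
        on, w = stim_ms + 5.0, 25.0
        mask = (t_ms >= on) & (t_ms < on + w)
        v[mask] -= amp * np.sin(np.pi * (t_ms[mask] - on) / w)
        # population spike: positive notch at the trough
        if inten >= ps_threshold_ua:
            v += (ps_frac * amp) * np.exp(
                -0.5 * ((t_ms - (on + w / 2.0)) / 0.6) ** 2
            )
        if noise_sd_mv > 0:
            v += rng.normal(0.0, noise_sd_mv, n)
        family.append(
            (float(inten),
             SweepRecording(sample_rate_hz, v, stim_times_ms=[stim_ms],
                            modality="field"))
        )
    return family


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

@dataclass
class LfpSimConfig:
    """LFP simulation: pink/white background plus scheduled ADs and spikes.

    ``ad_schedule`` rows are (start_s, duration_s, dominant_freq_hz,
    amplitude_mv); ``spike_schedule`` rows are (time_s, width_ms,
    amplitude_mv) with widths restricted to the 20-70 ms interictal range.
    """

    duration_s: float = 120.0
    sample_rate_hz: float = 1000.0
    background_psd: str = "pink"
    background_sd_mv: float = 0.05
    ad_schedule: list[tuple[float, float, float, float]] = field(default_factory=list)
    spike_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    injection_time_s: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.background_psd not in ("pink", "white"):
            raise ValueError("background_psd must be 'pink' or 'white'")
        ads = sorted(self.ad_schedule)
        for (s, d, f, a) in ads:
            if not (0 <= s and s + d <= self.duration_s):
                raise ValueError(f"AD at {s}s/{d}s falls outside the recording")
            if f <= 0 or a < 0 or d <= 0:
                raise ValueError("AD frequency/duration must be positive")
        for (p, n) in zip(ads, ads[1:]):
            if n[0] < p[0] + p[1]:
                raise ValueError(
                    f"overlapping ADs: one starting {n[0]} s begins before "
                    f"the AD at {p[0]} s (duration {p[1]} s) ends"
                )
        for (t, w, a) in self.spike_schedule:
            if not 0 <= t <= self.duration_s:
                raise ValueError(f"spike at {t} s outside the recording")
            if not 20.0 <= w <= 70.0:
                raise ValueError(
                    f"interictal spike width {w} ms outside the 20-70 ms range"
                )


def _pink_noise(rng, n: int, sd: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return sd * x / x.std()


def gen_lfp(cfg: LfpSimConfig) -> tuple[LfpRecording, GroundTruth]:
    """Background noise plus scheduled after-discharges and interictal spikes.

    ADs are amplitude-modulated (Tukey envelope) oscillations at their
    dominant frequency; spikes are Gaussian deflections whose FWHM equals
    the scheduled width.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz
    if cfg.background_psd == "pink":
        values = _pink_noise(rng, n, cfg.background_sd_mv)
    else:
        values = rng.normal(0.0, cfg.background_sd_mv, n)

    rows = []
    for (start, dur, f, amp) in cfg.ad_schedule:
        i0, i1 = int(start * cfg.sample_rate_hz), int((start + dur) * cfg.sample_rate_hz)
        m = i1 - i0
        env = tukey(m, alpha=0.2)
        values[i0:i1] += amp * env * np.sin(2 * np.pi * f * (t[i0:i1] - start))
        rows.append(dict(kind="ad", time_s=start, duration_s=dur,
                         freq_hz=f, amplitude_mv=amp, width_ms=np.nan))
    for (ts, w_ms, amp) in cfg.spike_schedule:
        sigma_s = (w_ms / 1000.0) / 2.3548  # FWHM -> sigma
        lo = max(0.0, ts - 5 * sigma_s)
        hi = min(cfg.duration_s, ts + 5 * sigma_s)
        i0, i1 = int(lo * cfg.sample_rate_hz), int(hi * cfg.sample_rate_hz)
        values[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - ts) / sigma_s) ** 2)
        rows.append(dict(kind="spike", time_s=ts, duration_s=np.nan,
                         freq_hz=np.nan, amplitude_mv=amp, width_ms=w_ms))

    rec = LfpRecording(cfg.sample_rate_hz, values,
                       injection_time_s=cfg.injection_time_s)
    columns = ["kind", "time_s", "duration_s", "freq_hz", "amplitude_mv",
               "width_ms"]
    truth = GroundTruth(events=pd.DataFrame(rows, columns=columns),
                        params={"config": cfg})
    return rec, truth
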