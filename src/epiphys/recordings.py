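"""In-memory containers for the raw signals the pipeline consumes.

Three modalities are handled: per-soma fluorescence time series from
calcium imaging (arbitrary units, ~1 Hz frame rate), voltage-clamp
current sweeps (pA, kHz sampling) and field / LFP voltage traces (mV).
All containers hold uniformly sampled data as 1-D float arrays plus the
minimal acquisition metadata the analysis stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorTrace", "SweepRecording", "LfpRecording"]


@dataclass
class FluorTrace:
    """One astrocyte soma's fluorescence time series.

    Parameters
    ----------
    cell_id : str
        Identifier of the soma ROI.
    frame_period_s : float
        Time between frames in seconds (1.0 s at the nominal 1 Hz rate).
    values : ndarray
        Raw fluorescence per frame, arbitrary units, background NOT yet
        subtracted.
    background : float
        Scalar background fluorescence to subtract before normalising.
    """

    cell_id: str
    frame_period_s: float
    values: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if len(self.values) < 30:
            raise ValueError(
                "trace too short: need at least 30 frames to admit a "
                f"baseline window, got {len(self.values)}"
            )
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_s


@dataclass
class SweepRecording:
    """A uniformly sampled electrophysiology sweep.

    ``values`` are pA for voltage-clamp current sweeps and mV for field
    sweeps (``modality="field"``). Stimulus times are in ms from sweep
    start.
    """

    sample_rate_hz: float
    values: np.ndarray
    stim_times_ms: list[float] = field(default_factory=list)
    holding_mv: float | None = None
    modality: str = "voltage_clamp"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("sweep values must be 1-D")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        dur = self.duration_ms
        for t in self.stim_times_ms:
            if not 0 <= t <= dur:
                raise ValueError(f"stimulus at {t} ms outside sweep of {dur} ms")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sample_rate_hz

    def index_at_ms(self, t_ms: float) -> int:
        return int(round(t_ms * self.sample_rate_hz / 1000.0))


@dataclass
class LfpRecording:
    """A local field potential recording (mV) with an optional injection marker."""

    sample_rate_hz: float
    values: np.ndarray
    injection_time_s: float | None = None
    filter_band: tuple[float, float] = (0.1, 100.0)
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("LFP values must be 1-D")
        lo, hi = self.filter_band
        if not (0 < lo < hi < self.sample_rate_hz / 2):
            raise ValueError("filter band must satisfy 0 < low < high < Nyquist")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz
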