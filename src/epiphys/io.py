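"""Delimited-text readers/writers and run configuration.

All on-disk artifacts are plain text: two-column CSV per signal (time,
value), CSV metric tables, and a YAML comment header (# -prefixed) on
every file carrying provenance — the config hash and seed — so any table
can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CalciumParams",
    "PscParams",
    "FepspParams",
    "LfpParams",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_signal_csv",
    "read_signal_csv",
    "write_table",
    "read_table",
]


@dataclass
class CalciumParams:
    k_sd: float = 2.0
    min_frames: int = 5
    cutoff_s: float = 23.1
    percentile: float = 75.0
    min_quiet_frames: int = 30
    split_mode: str = "adjacent"


@dataclass
class PscParams:
    threshold_sd: float = 3.0
    min_interval_ms: float = 5.0
    isi_ms: float = 100.0
    decay_correction: bool = True
    blank_ms: float = 2.0
    baseline_ms: float = 10.0


@dataclass
class FepspParams:
    blank_ms: float = 2.0
    ps_prominence_frac: float = 0.10
    slope_span: tuple[float, float] = (0.2, 0.8)


@dataclass
class LfpParams:
    segment_ms: float = 4000.0
    overlap_ms: float = 500.0
    time_bandwidth: float = 5.0
    n_tapers: int = 9
    band_hz: tuple[float, float] = (1.0, 3.0)
    spike_width_ms: tuple[float, float] = (20.0, 70.0)
    envelope_threshold_sd: float = 4.0
    min_ad_duration_s: float = 2.0
    smooth_ms: float = 250.0


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; known: {sorted(known)}"
        )
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Per-module parameter blocks with the pipeline's printed defaults."""

    calcium: CalciumParams = field(default_factory=CalciumParams)
    psc: PscParams = field(default_factory=PscParams)
    fepsp: FepspParams = field(default_factory=FepspParams)
    lfp: LfpParams = field(default_factory=LfpParams)
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        positive = [
            self.calcium.k_sd, self.calcium.min_frames, self.calcium.cutoff_s,
            self.calcium.percentile, self.calcium.min_quiet_frames,
            self.psc.threshold_sd, self.psc.isi_ms,
            self.lfp.segment_ms, self.lfp.time_bandwidth, self.lfp.n_tapers,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all algorithmic constants must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {
            "calcium": CalciumParams, "psc": PscParams,
            "fepsp": FepspParams, "lfp": LfpParams,
        }
        kwargs = {}
        for key, sub_cls in sub.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data.pop(key))
        known = {"seed", "outdir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    dump = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha1(dump.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    dump = yaml.safe_dump(meta, sort_keys=True).rstrip("\n")
    return "".join(f"# {line}\n" for line in dump.split("\n"))


def _read_header(path: Path) -> dict:
    lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line[2:] if line.startswith("# ") else line[1:])
    return yaml.safe_load("".join(lines)) or {} if lines else {}


def write_signal_csv(
    path: str | Path, times: np.ndarray, values: np.ndarray, meta: dict | None = None
) -> None:
    """Two-column (time, value) CSV with a YAML comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time": times, "value": values})
    with open(path, "w") as fh:
        if meta:
            fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta = _read_header(Path(path))
    df = pd.read_csv(path, comment="#")
    return df["time"].to_numpy(), df["value"].to_numpy(), meta


def write_table(path: str | Path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta = _read_header(Path(path))
    return pd.read_csv(path, comment="#"), meta
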