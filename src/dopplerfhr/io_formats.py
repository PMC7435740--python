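"""Readers/writers for waveforms, event series and run configuration.

Waveforms travel as mono WAV (float or PCM; sample rate in the header)
or as raw float32 with a JSON sidecar ``{"fs": ...}``.  Event series
are CSV with the header ``tau_ms,T_ms,valid`` (times in ms, 3
decimals).  Run configuration is a flat YAML/JSON mapping validated
against the parameter sets the processing chain supports; every
pipeline run can embed its resolved configuration for provenance.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import events_d2, periodicity, preprocessing
from .events import BeatEventSeries
from .simulate import UltrasoundRecord

__all__ = [
    "RunConfig",
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
]


@dataclass
class RunConfig:
    """Resolved configuration of one processing run.

    Enumerated parameters are restricted to the values the sensitivity
    study covers unless ``allow_nonstandard`` is set.
    """

    band: tuple = (300.0, 600.0)
    envelope_kind: str = "hilbert"           # rectify_lowpass | hilbert
    envelope_cutoff: float | None = 50.0     # rectify_lowpass only
    envelope_ma_len: int | None = 21         # hilbert only
    D: float = 1.0
    K: float = 25.0
    S: float = 500.0
    p_th: float = 0.1
    pf_enabled: bool = True
    lag_range: tuple = (250.0, 1000.0)
    method: str = "d2"                       # d1 | d2
    rms_window: float = 500.0
    maa_enabled: bool = True
    validate: bool = True
    eval_window_s: tuple = (5.0, 55.0)
    seed: int = 0
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        self.band = tuple(float(b) for b in self.band)
        self.lag_range = tuple(float(v) for v in self.lag_range)
        self.eval_window_s = tuple(float(v) for v in self.eval_window_s)
        if self.method not in ("d1", "d2"):
            raise ValueError("method must be 'd1' or 'd2'")
        if self.envelope_kind not in ("rectify_lowpass", "hilbert"):
            raise ValueError("envelope_kind must be 'rectify_lowpass' or 'hilbert'")
        if not self.allow_nonstandard:
            std_bands = {(100.0, 300.0), (300.0, 600.0), (100.0, 600.0)}
            checks = [
                (self.band in std_bands, f"band {self.band}"),
                (self.D in periodicity.AF_WINDOW_WIDTHS, f"D {self.D}"),
                (self.K in periodicity.AF_STEPS, f"K {self.K}"),
                (not self.pf_enabled or self.S in periodicity.PF_WIDTHS, f"S {self.S}"),
                (self.rms_window in events_d2.RMS_WINDOWS, f"rms_window {self.rms_window}"),
                (
                    self.envelope_cutoff in preprocessing.RECTIFY_CUTOFFS,
                    f"envelope_cutoff {self.envelope_cutoff}",
                ),
                (
                    self.envelope_ma_len in preprocessing.HILBERT_MA_LENGTHS,
                    f"envelope_ma_len {self.envelope_ma_len}",
                ),
            ]
            for ok, what in checks:
                if not ok:
                    raise ValueError(f"nonstandard parameter {what}; set allow_nonstandard to use it")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["lag_range"] = list(self.lag_range)
        d["eval_window_s"] = list(self.eval_window_s)
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def read_signal(path: str | Path) -> UltrasoundRecord:
    """Load a mono waveform from WAV or raw float32 + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("multichannel WAV not supported; expected mono")
        if data.dtype.kind == "i":
            data = data.astype(float) / np.iinfo(data.dtype).max
        return UltrasoundRecord(np.asarray(data, dtype=float), float(fs))
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"raw waveform needs a JSON sidecar at {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError("sidecar missing 'fs'")
    data = np.fromfile(path, dtype=np.float32).astype(float)
    return UltrasoundRecord(data, float(meta["fs"]))


def write_signal(record: UltrasoundRecord, path: str | Path, meta: dict | None = None) -> None:
    """Write a waveform as float32 WAV, or raw float32 + sidecar otherwise."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(record.fs), record.samples.astype(np.float32))
    else:
        record.samples.astype(np.float32).tofile(path)
        sidecar = {"fs": record.fs, "duration": record.duration}
        sidecar.update(meta or {})
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def write_events(series: BeatEventSeries, path: str | Path) -> None:
    """Event CSV ``tau_ms,T_ms,valid`` with millisecond times at 3 decimals."""
    df = pd.DataFrame(
        {
            "tau_ms": np.round(series.tau, 3),
            "T_ms": np.round(series.T, 3),
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.3f")


def read_events(path: str | Path, source: str = "reference") -> BeatEventSeries:
    df = pd.read_csv(path)
    required = {"tau_ms", "T_ms", "valid"}
    if not required.issubset(df.columns):
        raise ValueError(f"event CSV must have columns {sorted(required)}")
    if len(df) == 0:
        return BeatEventSeries.empty(source)
    tau = df["tau_ms"].to_numpy(float)
    if len(tau) > 1 and np.any(np.diff(tau) <= 0):
        bad = (np.nonzero(np.diff(tau) <= 0)[0] + 1).tolist()
        raise ValueError(f"tau_ms not strictly increasing at rows {bad}")
    return BeatEventSeries(tau, df["T_ms"].to_numpy(float), df["valid"].to_numpy(bool), source=source)
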