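"""Multichannel haemodynamic recording: the interchange object between the
simulator and the analysis pipeline.

On disk a recording is a comma-delimited text file (one header row, a
``time`` column plus the canonical channels) next to a JSON sidecar holding
sampling rate, seed, config hash and event annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError

#: canonical channel names, in canonical column order
CHANNELS: Tuple[str, ...] = (
    "P_LV", "P_RV", "P_AO", "P_PA", "P_CV",
    "V_LV", "V_RV", "G_LV", "G_RV", "Q_pump",
)

_PRESSURE_CHANNELS = ("P_LV", "P_RV", "P_AO", "P_PA", "P_CV")


@dataclass
class SignalSet:
    """Uniformly sampled recording with event annotations.

    ``extras`` holds derived arrays (true flows, pericardial pressure,
    compartment volumes) that are recomputable from the model and are not
    serialised.
    """

    fs: float
    time: np.ndarray
    channels: Dict[str, np.ndarray]
    annotations: List[Tuple[float, str]] = field(default_factory=list)
    meta: Dict = field(default_factory=dict)
    extras: Dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n < 2:
            raise FormatError("signal set needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise FormatError("time base must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("time base must be uniform")
        for name in CHANNELS:
            if name not in self.channels:
                raise FormatError(f"missing channel {name!r}")
            if self.channels[name].shape != (n,):
                raise FormatError(f"channel {name!r} length mismatch")
        for name in _PRESSURE_CHANNELS:
            if not np.all(np.isfinite(self.channels[name])):
                raise FormatError(f"non-finite samples in pressure channel {name!r}")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def window(self, t0: float, t1: float) -> "SignalSet":
        """Sub-recording on [t0, t1] (annotations filtered, extras sliced)."""
        m = (self.time >= t0) & (self.time <= t1)
        extras = {}
        for k, v in self.extras.items():
            if isinstance(v, np.ndarray) and v.shape == self.time.shape:
                extras[k] = v[m]
        return SignalSet(
            fs=self.fs,
            time=self.time[m],
            channels={k: v[m] for k, v in self.channels.items()},
            annotations=[(t, tag) for t, tag in self.annotations if t0 <= t <= t1],
            meta=dict(self.meta),
            extras=extras,
        )


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_signals(ss: SignalSet, path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the sidecar path."""
    path = Path(path)
    df = pd.DataFrame({"time": ss.time})
    for name in CHANNELS:
        df[name] = ss.channels[name]
    df.to_csv(path, index=False, float_format="%.17g")
    side = {
        "sampling_rate": ss.fs,
        "seed": ss.meta.get("seed"),
        "config_hash": ss.meta.get("config_hash"),
        "annotations": [[float(t), tag] for t, tag in ss.annotations],
        "meta": {k: v for k, v in ss.meta.items() if _jsonable(v)},
    }
    sp = sidecar_path(path)
    sp.write_text(json.dumps(side, indent=1))
    return sp


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None), list, dict))


def read_signals(path) -> SignalSet:
    """Read a recording written by :func:`write_signals`.

    Columns are matched by header name, so column order is free; a missing
    channel or malformed sidecar raises :class:`FormatError` naming the
    defect.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"signal file not found: {path}")
    sp = sidecar_path(path)
    if not sp.exists():
        raise FormatError(f"sidecar not found: {sp}")
    try:
        side = json.loads(sp.read_text())
        fs = float(side["sampling_rate"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as e:
        raise FormatError(f"malformed sidecar {sp}: {e}") from e
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError("missing 'time' column")
    channels = {}
    for name in CHANNELS:
        if name not in df.columns:
            raise FormatError(f"missing channel {name!r}")
        channels[name] = df[name].to_numpy(dtype=float)
    meta = side.get("meta", {}) or {}
    meta.setdefault("seed", side.get("seed"))
    meta.setdefault("config_hash", side.get("config_hash"))
    return SignalSet(
        fs=fs,
        time=df["time"].to_numpy(dtype=float),
        channels=channels,
        annotations=[(float(t), str(tag)) for t, tag in side.get("annotations", [])],
        meta=meta,
    )
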