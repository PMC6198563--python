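"""Data model and plain-text I/O.

Signals travel as delimited text (CSV, header row = channel labels) with a JSON
sidecar carrying the sampling rate and trial metadata; results are written as
JSON that embeds the configuration snapshot and seed so a run can be repeated
byte-for-byte from its output.

Units are fixed throughout the package: EMG in millivolts, torque in Nm,
frequencies in Hz, times in seconds.  Stimulus-locked sweeps place the
stimulus at t = 0 and express analysis windows in seconds post-stimulus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

GROUPS = ("CP", "CON")
STATES = ("rest", "onset", "static")


@dataclass
class EmgRecord:
    """A multichannel surface-EMG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal in millivolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One unique label per channel (e.g. ``TA_prox``, ``TA_dist``, ``SOL``).
    subject_id : str
    group : str
        ``"CP"`` or ``"CON"``.
    state : str
        ``"rest"``, ``"onset"`` or ``"static"``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    subject_id: str = ""
    group: str = "CON"
    state: str = "static"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate channel labels: {labels}")
        if self.samples.shape[1] != len(labels):
            raise ValidationError(
                f"{self.samples.shape[1]} channels but {len(labels)} labels"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.state not in STATES:
            raise ValidationError(f"state must be one of {STATES}, got {self.state!r}")
        self.channel_labels = labels

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label as a 1-D array."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(
                f"no channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.samples[:, idx]


@dataclass
class SweepSet:
    """Stimulus-locked sweeps for one subject and one state.

    ``sweeps`` has shape (n_sweeps, n_samples) in millivolts with the stimulus
    at t = 0.  ``m_window`` and ``h_window`` delimit, in seconds post-stimulus,
    where the direct M-wave and the H-reflex are measured; ``m_max`` is the
    supramaximal M-response used as the normalisation denominator.
    """

    sweeps: np.ndarray
    fs: float
    state: str
    m_window: tuple[float, float] = (0.005, 0.025)
    h_window: tuple[float, float] = (0.025, 0.055)
    m_max: float = 1.0

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.state not in ("rest", "onset"):
            raise ValidationError(f"state must be 'rest' or 'onset', got {self.state!r}")
        if self.m_max <= 0:
            raise ValidationError("m_max must be positive")
        if not self.m_window[1] <= self.h_window[0]:
            raise ValidationError("M window must precede H window")
        extent = self.sweeps.shape[1] / self.fs
        for name, (lo, hi) in (("m_window", self.m_window), ("h_window", self.h_window)):
            if not (0 <= lo < hi <= extent):
                raise ValidationError(f"{name} {(lo, hi)} outside sweep extent {extent}")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


@dataclass
class TorqueTrial:
    """A single dorsiflexion torque trace in Nm."""

    torque: np.ndarray
    fs: float
    onset_index: int | None = None

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float).ravel()
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.onset_index is not None and not (0 <= self.onset_index < self.torque.size):
            raise ValidationError("onset_index outside trace")


@dataclass
class AnalysisConfig:
    """Analysis parameters shared across pipeline stages.

    Defaults follow the recording protocol the analyses assume: 1 Hz spectral
    resolution, alpha band 5-15 Hz, beta band 15-35 Hz, cumulant lags within
    +/-250 ms, 95% confidence limits, M-wave window 5-25 ms and H-reflex
    window 25-55 ms post-stimulus.
    """

    freq_resolution_hz: float = 1.0
    alpha_band: tuple[float, float] = (5.0, 15.0)
    beta_band: tuple[float, float] = (15.0, 35.0)
    cumulant_lag_s: float = 0.25
    confidence_alpha: float = 0.05
    seed: int = 0
    m_window: tuple[float, float] = (0.005, 0.025)
    h_window: tuple[float, float] = (0.025, 0.055)
    envelope_window_ms: float = 50.0
    qc_broadband_threshold: float = 0.1
    qc_zero_lag_ms: float = 3.0

    def __post_init__(self) -> None:
        for name in ("alpha_band", "beta_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be non-empty, got {(lo, hi)}")
        if not 0 < self.confidence_alpha < 1:
            raise ValidationError("confidence_alpha must lie in (0, 1)")
        if self.freq_resolution_hz <= 0:
            raise ValidationError("freq_resolution_hz must be positive")

    def segment_length(self, fs: float) -> int:
        """Segment length in samples giving the configured resolution at ``fs``."""
        T = fs / self.freq_resolution_hz
        if abs(T - round(T)) > 1e-9:
            raise ValidationError(
                f"resolution {self.freq_resolution_hz} Hz does not divide fs={fs} "
                "into an integer segment length"
            )
        return int(round(T))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_emg(path: str | Path, meta_path: str | Path) -> EmgRecord:
    """Read an EMG record from a CSV signal file plus its JSON metadata sidecar.

    The CSV carries one column per channel with a header row of channel labels;
    the sidecar must supply ``fs`` and may supply ``subject_id``, ``group`` and
    ``state``.
    """
    meta = json.loads(Path(meta_path).read_text())
    if "fs" not in meta:
        raise ConfigurationError(f"metadata {meta_path} lacks required key 'fs'")
    frame = pd.read_csv(path)
    labels = list(frame.columns)
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate channel labels in {path}: {labels}")
    return EmgRecord(
        samples=frame.to_numpy(dtype=float),
        fs=float(meta["fs"]),
        channel_labels=labels,
        subject_id=str(meta.get("subject_id", "")),
        group=meta.get("group", "CON"),
        state=meta.get("state", "static"),
    )


def write_emg(record: EmgRecord, path: str | Path, meta_path: str | Path) -> None:
    """Write an EMG record as CSV + JSON sidecar (inverse of :func:`read_emg`)."""
    frame = pd.DataFrame(record.samples, columns=record.channel_labels)
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": record.fs,
        "channel_labels": record.channel_labels,
        "subject_id": record.subject_id,
        "group": record.group,
        "state": record.state,
        "duration_s": record.duration_s,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return {"_complex": True, "re": obj.real.tolist(), "im": obj.imag.tolist()}
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return repr(obj)


def write_results(
    obj: Any,
    path: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> None:
    """Serialise any pipeline result to JSON, embedding config snapshot and seed.

    Dataclasses (including nested ones and numpy arrays) are expanded to plain
    JSON structures; floats keep full ``repr`` precision, so a write/read
    round-trip is exact to at least 12 significant digits.
    """
    if config is None:
        config = getattr(obj, "config", None)
    if seed is None:
        seed = getattr(obj, "seed", None)
        if seed is None and config is not None:
            seed = config.seed
    payload = {
        "result": _jsonable(obj),
        "config": _jsonable(config) if config is not None else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_results(path: str | Path) -> dict:
    """Read back a :func:`write_results` file as a plain dict.

    Complex arrays are reconstituted as numpy arrays; everything else stays in
    JSON-native types.
    """

    def hook(d: dict) -> Any:
        if d.get("_complex"):
            return np.asarray(d["re"]) + 1j * np.asarray(d["im"])
        return d

    return json.loads(Path(path).read_text(), object_hook=hook)
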