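"""CSV readers and writers for the interchange schemas between stages.

All streams are plain CSV with a ``time_s`` column, onset-referenced to
recording start:

* fNIRS:   time_s, optode{1..4}_wl730, optode{1..4}_wl850, optode{1..4}_ambient
* EEG:     time_s + the 14 channel columns in montage order
* face:    time_s + the 7 emotion columns
* protocol: trial_id, participant_id, kind, onset_s, duration_s, valence, likert
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import EEG_CHANNELS, EMOTIONS, N_OPTODES, WAVELENGTHS
from .signals import (
    DataError,
    EmotionProbStream,
    PROTOCOL_COLUMNS,
    RawEEGRecord,
    RawFNIRSRecord,
    validate_protocol,
)

_FLOAT_FMT = "%.10g"


def fnirs_columns() -> list[str]:
    cols = []
    for wl in WAVELENGTHS:
        cols += [f"optode{o + 1}_wl{wl}" for o in range(N_OPTODES)]
    cols += [f"optode{o + 1}_ambient" for o in range(N_OPTODES)]
    return cols


def write_fnirs_csv(record: RawFNIRSRecord, path: str | Path) -> None:
    data = {"time_s": record.time}
    for w, wl in enumerate(record.wavelengths):
        for o in range(N_OPTODES):
            data[f"optode{o + 1}_wl{wl}"] = record.intensity[:, o, w]
    for o in range(N_OPTODES):
        data[f"optode{o + 1}_ambient"] = record.ambient[:, o]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fnirs_csv(path: str | Path) -> RawFNIRSRecord:
    frame = pd.read_csv(path)
    missing = {"time_s", *fnirs_columns()} - set(frame.columns)
    if missing:
        raise DataError(f"fNIRS CSV missing columns: {sorted(missing)}")
    n = len(frame)
    intensity = np.empty((n, N_OPTODES, 2))
    for w, wl in enumerate(WAVELENGTHS):
        for o in range(N_OPTODES):
            intensity[:, o, w] = frame[f"optode{o + 1}_wl{wl}"]
    ambient = np.stack(
        [frame[f"optode{o + 1}_ambient"].to_numpy() for o in range(N_OPTODES)], axis=1)
    time = frame["time_s"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(time)) if n > 1 else 4.0
    return RawFNIRSRecord(time=time, intensity=intensity, ambient=ambient,
                          rate=float(round(rate, 6)))


def write_eeg_csv(record: RawEEGRecord, path: str | Path) -> None:
    data = {"time_s": record.time}
    for k, ch in enumerate(record.channels):
        data[ch] = record.potentials[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_eeg_csv(path: str | Path) -> RawEEGRecord:
    frame = pd.read_csv(path)
    missing = {"time_s", *EEG_CHANNELS} - set(frame.columns)
    if missing:
        raise DataError(f"EEG CSV missing columns: {sorted(missing)}")
    time = frame["time_s"].to_numpy(dtype=float)
    potentials = frame[list(EEG_CHANNELS)].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 128.0
    return RawEEGRecord(time=time, potentials=potentials, rate=float(round(rate, 6)))


def write_face_csv(stream: EmotionProbStream, path: str | Path) -> None:
    data = {"time_s": stream.time}
    for k, emo in enumerate(stream.emotions):
        data[emo] = stream.probs[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_face_csv(path: str | Path) -> EmotionProbStream:
    frame = pd.read_csv(path)
    missing = {"time_s", *EMOTIONS} - set(frame.columns)
    if missing:
        raise DataError(f"face CSV missing columns: {sorted(missing)}")
    time = frame["time_s"].to_numpy(dtype=float)
    probs = frame[list(EMOTIONS)].to_numpy(dtype=float)
    # renormalize away the CSV rounding so the simplex invariant holds
    probs = probs / probs.sum(axis=1, keepdims=True)
    rate = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 30.0
    return EmotionProbStream(time=time, probs=probs, rate=float(round(rate, 6)))


def write_protocol_csv(protocol: pd.DataFrame, path: str | Path) -> None:
    protocol[list(PROTOCOL_COLUMNS)].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_protocol_csv(path: str | Path) -> pd.DataFrame:
    return validate_protocol(pd.read_csv(path))
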