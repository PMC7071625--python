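"""In-memory containers for the three raw signal streams and trial protocol.

Protocols are plain pandas DataFrames with columns
``trial_id, participant_id, kind, onset_s, duration_s, valence, likert`` —
one row per stimulus presentation, onsets referenced to recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EEG_CHANNELS, EMOTIONS, N_OPTODES, WAVELENGTHS

PROTOCOL_COLUMNS = (
    "trial_id", "participant_id", "kind", "onset_s", "duration_s", "valence", "likert",
)


class DataError(ValueError):
    """Input data violates a structural precondition."""


class ProtocolError(ValueError):
    """Trial protocol inconsistent with the recording it describes."""


def validate_protocol(protocol: pd.DataFrame, baseline: float = 5.0) -> pd.DataFrame:
    """Check column schema, trial ordering and the pre-trial baseline gap."""
    missing = set(PROTOCOL_COLUMNS) - set(protocol.columns)
    if missing:
        raise ProtocolError(f"protocol is missing columns: {sorted(missing)}")
    bad = set(protocol["valence"].unique()) - {"positive", "negative"}
    if bad:
        raise ProtocolError(f"unknown valence labels: {sorted(bad)}")
    if not protocol["likert"].between(1, 10).all():
        raise ProtocolError("likert reports must lie in [1, 10]")
    for _, part in protocol.groupby("participant_id"):
        part = part.sort_values("onset_s")
        ends = (part["onset_s"] + part["duration_s"]).to_numpy()
        onsets = part["onset_s"].to_numpy()
        if (onsets[1:] - ends[:-1] < baseline - 1e-9).any():
            raise ProtocolError(
                f"trials overlap or lack a {baseline}-s pre-trial baseline")
        if onsets[0] < baseline:
            raise ProtocolError("first trial starts inside the baseline window")
    return protocol


@dataclass
class RawFNIRSRecord:
    """Raw two-wavelength optode intensities at 4 Hz.

    ``intensity`` has shape (n_samples, n_optodes, 2) ordered as
    :data:`~affectfuse.config.WAVELENGTHS`; ``ambient`` (n_samples,
    n_optodes) holds the dark/ambient-light channel, already on the same
    detector-unit scale.
    """

    time: np.ndarray
    intensity: np.ndarray
    ambient: np.ndarray
    rate: float = 4.0
    wavelengths: tuple[int, int] = WAVELENGTHS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.ambient = np.asarray(self.ambient, dtype=float)
        n = self.time.shape[0]
        if self.intensity.shape != (n, N_OPTODES, 2):
            raise DataError(
                f"intensity must have shape (n, {N_OPTODES}, 2), got {self.intensity.shape}")
        if self.ambient.shape != (n, N_OPTODES):
            raise DataError("ambient must have shape (n, n_optodes)")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")


@dataclass
class HemodynamicSignals:
    """Concentration-change series (uM) per optode: oxy/deoxy/total/oxygenation.

    ``hbt = hbo + hbr`` and ``oxy = hbo - hbr`` are maintained as exact
    identities by every operation that produces this type.
    """

    time: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    rate: float = 4.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.shape[0] != self.time.shape[0]:
            raise DataError("hbo/hbr/time shapes disagree")

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def oxy(self) -> np.ndarray:
        return self.hbo - self.hbr

    def signal(self, name: str) -> np.ndarray:
        try:
            return {"hbo": self.hbo, "hbr": self.hbr,
                    "hbt": self.hbt, "oxy": self.oxy}[name]
        except KeyError:
            raise DataError(f"unknown hemodynamic signal {name!r}") from None


@dataclass
class RawEEGRecord:
    """14-channel scalp potentials (uV) at 128 Hz, 10-20 montage order."""

    time: np.ndarray
    potentials: np.ndarray
    channels: tuple[str, ...] = EEG_CHANNELS
    rate: float = 128.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.shape != (self.time.shape[0], len(self.channels)):
            raise DataError("potentials must have shape (n_samples, n_channels)")
        if tuple(self.channels) != EEG_CHANNELS:
            raise DataError(f"expected the fixed 14-channel montage {EEG_CHANNELS}")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise DataError(f"channel {name!r} not present") from None
        return self.potentials[:, idx]


@dataclass
class EmotionProbStream:
    """Per-frame 7-class emotion probabilities on the simplex."""

    time: np.ndarray
    probs: np.ndarray
    emotions: tuple[str, ...] = EMOTIONS
    rate: float = 30.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.time.shape[0], len(self.emotions)):
            raise DataError("probs must have shape (n_frames, 7)")

    def validate_simplex(self, atol: float = 1e-9) -> None:
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise DataError("frame probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > atol):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise DataError(f"frame {bad} probabilities sum to {sums[bad]:.6f}, not 1")


def slice_window(time: np.ndarray, start: float, stop: float) -> slice:
    """Index slice for samples with start <= t < stop on a uniform grid."""
    i0 = int(np.searchsorted(time, start - 1e-9, side="left"))
    i1 = int(np.searchsorted(time, stop - 1e-9, side="left"))
    return slice(i0, i1)


@dataclass
class ParticipantData:
    """All raw streams plus the protocol for one participant."""

    participant_id: int
    protocol: pd.DataFrame
    fnirs: RawFNIRSRecord
    eeg: RawEEGRecord
    face: EmotionProbStream


@dataclass
class StudyDataset:
    """A complete synthetic study: per-participant streams plus config."""

    config: "object"
    participants: list[ParticipantData] = field(default_factory=list)

    @property
    def protocol(self) -> pd.DataFrame:
        return pd.concat([p.protocol for p in self.participants], ignore_index=True)
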