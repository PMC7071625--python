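"""Configuration dataclasses shared across the pipeline.

Every constant that the protocol fixes (sampling rates, filter cutoffs,
band edges, baseline windows) lives here with its fixed default, so that a
default-constructed config reproduces the published analysis settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

#: The 14 scalp electrodes of the consumer EEG headset, 10-20 positions,
#: in acquisition order.
EEG_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Homologous (left, right) frontal electrode pairs used for asymmetry
#: features.
ASYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
)

#: Emotion categories emitted by the facial expression recognizer, in the
#: fixed documented order used for tie-breaking.
EMOTIONS: tuple[str, ...] = (
    "Anger", "Disgust", "Fear", "Happiness", "Neutral", "Sadness", "Surprise",
)

POSITIVE_EMOTION = "Happiness"
NEGATIVE_EMOTIONS: tuple[str, ...] = ("Anger", "Disgust", "Fear", "Sadness")

#: fNIRS wavelengths in nm.
WAVELENGTHS: tuple[int, int] = (730, 850)
N_OPTODES = 4

FNIRS_RATE = 4.0    # Hz
EEG_RATE = 128.0    # Hz


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


@dataclass(frozen=True)
class BandDefinition:
    """Half-open EEG frequency bands, lower < f <= upper, in Hz."""

    theta: tuple[float, float] = (4.0, 8.0)
    slow_alpha: tuple[float, float] = (8.0, 10.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    beta: tuple[float, float] = (12.0, 30.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.items():
            if not lo < hi:
                raise ConfigurationError(f"band {name}: lower must be < upper")

    def items(self) -> list[tuple[str, tuple[float, float]]]:
        return [(f.name, getattr(self, f.name)) for f in dataclasses.fields(self)]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.items())


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters.

    ``amplitude`` scales the whole curve; (``alpha1``, ``beta1``) are the
    shape/rate of the positive response gamma, (``alpha2``, ``beta2``) of
    the undershoot gamma, and ``undershoot_ratio`` weights the undershoot.
    Defaults peak near 5 s with a late undershoot.
    """

    amplitude: float = 1.0
    alpha1: float = 6.0
    beta1: float = 1.0
    alpha2: float = 16.0
    beta2: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not (self.alpha1 > 1 and self.alpha2 > 1):
            raise ConfigurationError("HRF shape parameters alpha1, alpha2 must be > 1")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ConfigurationError("HRF rate parameters beta1, beta2 must be > 0")
        if self.undershoot_ratio < 0:
            raise ConfigurationError("undershoot_ratio must be >= 0")


def _default_extinction() -> dict[int, tuple[float, float]]:
    # (epsilon_HbO, epsilon_HbR) in 1/(mM*cm) at each wavelength, from a
    # standard in-vitro hemoglobin compilation.
    return {730: (0.3900, 1.1022), 850: (1.0580, 0.6913)}


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer-Lambert law constants.

    ``extinction`` maps wavelength (nm) to (epsilon_HbO, epsilon_HbR) in
    1/(mM*cm); ``dpf`` is the differential pathlength factor per wavelength
    and ``separation`` the source-detector distance in cm. Concentration
    changes are expressed in micromolar.
    """

    extinction: dict[int, tuple[float, float]] = field(default_factory=_default_extinction)
    dpf: dict[int, float] = field(default_factory=lambda: {730: 6.0, 850: 6.0})
    separation: float = 2.5

    def matrix(self, wavelengths: tuple[int, int] = WAVELENGTHS) -> np.ndarray:
        """2x2 system matrix mapping (dHbO, dHbR) in uM to optical density."""
        rows = []
        for wl in wavelengths:
            if wl not in self.extinction or wl not in self.dpf:
                raise ConfigurationError(f"no extinction/DPF entry for {wl} nm")
            e_hbo, e_hbr = self.extinction[wl]
            # extinction is per mM; concentrations are in uM, hence 1e-3
            rows.append([e_hbo * self.separation * self.dpf[wl] * 1e-3,
                         e_hbr * self.separation * self.dpf[wl] * 1e-3])
        mat = np.asarray(rows)
        if abs(np.linalg.det(mat)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        return mat


@dataclass(frozen=True)
class SVMConfig:
    """Polynomial-kernel SVM hyperparameters (degree-3, C=1, scaled gamma)."""

    kernel: str = "poly"
    degree: int = 3
    C: float = 1.0
    gamma: str | float = "scale"
    coef0: float = 1.0


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Effects are planted on the scale of the feature each modality extracts:
    ``effect_eeg`` is a log-power asymmetry shift (dimensionless),
    ``effect_fnirs`` a lateralized oxy-hemoglobin amplitude in uM, and
    ``effect_face`` a probability-mass bias on the emotion simplex.
    """

    n_participants: int = 12
    n_image_trials: int = 20
    n_video_trials: int = 20
    image_duration: float = 5.0
    video_duration_range: tuple[float, float] = (10.0, 17.0)
    baseline_duration: float = 5.0
    inter_trial_gap: float = 10.0
    initial_rest: float = 30.0
    fnirs_rate: float = FNIRS_RATE
    eeg_rate: float = EEG_RATE
    face_rate: float = 30.0
    effect_eeg: float = 0.3
    effect_fnirs: float = 0.3
    effect_face: float = 0.25
    misexpression_rate: float = 0.2
    noise_fnirs: float = 0.005
    noise_eeg: float = 3.0
    noise_face: float = 8.0
    drift_fnirs: float = 0.01
    expressiveness_shape: float = 2.0
    likert_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_image_trials", "n_video_trials"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("n_image_trials", "n_video_trials"):
            if getattr(self, name) % 2:
                raise ConfigurationError(
                    f"{name} must be even to balance positive/negative valence")
        for name in ("image_duration", "baseline_duration", "inter_trial_gap",
                     "initial_rest", "fnirs_rate", "eeg_rate", "face_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.video_duration_range
        if not 0 < lo <= hi:
            raise ConfigurationError("video_duration_range must satisfy 0 < low <= high")
        for name in ("effect_eeg", "effect_fnirs", "effect_face", "noise_fnirs",
                     "noise_eeg", "noise_face", "drift_fnirs",
                     "expressiveness_shape", "likert_noise"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.effect_face >= 1:
            raise ConfigurationError("effect_face must lie in [0, 1)")
        if not 0 <= self.misexpression_rate <= 1:
            raise ConfigurationError("misexpression_rate must lie in [0, 1]")
        if self.initial_rest < self.baseline_duration:
            raise ConfigurationError("initial_rest must cover the baseline window")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, YAML round-trippable."""

    study: StudyConfig = field(default_factory=StudyConfig)
    bands: BandDefinition = field(default_factory=BandDefinition)
    hrf: HRFParams = field(default_factory=HRFParams)
    mbll: MBLLParams = field(default_factory=MBLLParams)
    svm: SVMConfig = field(default_factory=SVMConfig)
    fnirs_lowpass_hz: float = 0.1
    eeg_lowpass_hz: float = 30.0
    baseline_seconds: float = 5.0
    face_calibration_seconds: float = 5.0
    i0_window_seconds: float = 30.0
    kurtosis_z: float = 3.0
    lowfreq_fraction: float = 0.6
    use_ica: bool = True
    seed: int = 0


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type if isinstance(f.type, type) else None):
            value = _from_plain(f.type, value)
        elif f.name in ("study", "bands", "hrf", "mbll", "svm"):
            value = _from_plain(
                {"study": StudyConfig, "bands": BandDefinition, "hrf": HRFParams,
                 "mbll": MBLLParams, "svm": SVMConfig}[f.name], value)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        elif isinstance(value, dict):
            value = {int(k) if isinstance(k, str) and k.isdigit() else k:
                     tuple(v) if isinstance(v, list) else v
                     for k, v in value.items()}
        kwargs[f.name] = value
    return cls(**kwargs)


def dump_config(config: PipelineConfig) -> str:
    """Serialize a pipeline config to YAML (fixed-point under a round trip)."""
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def load_config(text: str) -> PipelineConfig:
    """Parse a YAML pipeline config; missing fields take their defaults."""
    data = yaml.safe_load(text) or {}
    return _from_plain(PipelineConfig, data)
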