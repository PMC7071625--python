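"""Seeded synthetic studies with planted valence effects.

The generator emulates the recording session the pipeline expects: an
initial rest period, then a block of image trials and a block of video
trials separated by inter-trial gaps, with three simultaneous streams per
participant:

* fNIRS — target oxy/deoxy concentration changes built as boxcar * HRF
  with valence-lateralized amplitude across the left (optodes 1-2) and
  right (optodes 3-4) prefrontal sites, mapped to raw two-wavelength
  intensities through the exact algebraic inverse of the implemented
  modified Beer-Lambert law, plus intensity-scale noise and slow drift.
* EEG — 4-45 Hz background noise per channel plus a narrowband alpha
  (8-12 Hz) component whose log power shifts by +-effect_eeg/2 on the four
  homologous frontal pairs during trials, signed by valence (left-lateral
  activation for positive affect, i.e. positive right-minus-left alpha
  log-power asymmetry).
* face — per-frame Dirichlet draws on the 7-emotion simplex around a
  neutral-heavy resting profile, with effect_face probability mass moved
  to Happiness during positive trials or to one sampled negative emotion
  during negative trials.

Everything is deterministic for a fixed :class:`StudyConfig` seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    ASYMMETRY_PAIRS,
    EEG_CHANNELS,
    EMOTIONS,
    N_OPTODES,
    NEGATIVE_EMOTIONS,
    POSITIVE_EMOTION,
    HRFParams,
    MBLLParams,
    StudyConfig,
)
from .fnirs import hrf
from .signals import (
    EmotionProbStream,
    ParticipantData,
    RawEEGRecord,
    RawFNIRSRecord,
    StudyDataset,
    validate_protocol,
)

#: Resting-state emotion profile: mostly neutral with faint residual mass
#: on the expressive categories (a webcam recognizer is never exactly
#: one-hot on a resting face).
BASELINE_PROFILE = np.array([0.05, 0.05, 0.05, 0.10, 0.55, 0.05, 0.15])

_LEFT_OPTODES = (0, 1)
_RIGHT_OPTODES = (2, 3)
#: Contralateral attenuation of the hemodynamic response amplitude.
_CONTRA_FRACTION = 0.4
#: Resting amplitude (uV) of the narrowband alpha component.
_ALPHA_BASE_UV = 4.0
#: Clean detector intensity and ambient-light level, arbitrary units.
_I0 = 1000.0
_AMBIENT = 50.0


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def build_protocol(config: StudyConfig, participant_id: int) -> pd.DataFrame:
    """Trial table for one participant: image block then video block.

    Valence assignment and video durations are stimulus properties, shared
    across participants (drawn from the study seed only); Likert
    self-reports are participant-specific.
    """
    rng_stim = _spawn(config.seed, 0xA11CE)
    rng_part = _spawn(config.seed, 0xB0B, participant_id)

    def balanced_valences(n: int) -> np.ndarray:
        v = np.array(["positive"] * (n // 2) + ["negative"] * (n // 2))
        return rng_stim.permutation(v)

    image_val = balanced_valences(config.n_image_trials)
    video_val = balanced_valences(config.n_video_trials)
    lo, hi = config.video_duration_range
    video_dur = rng_stim.uniform(lo, hi, size=config.n_video_trials)

    rows = []
    t = config.initial_rest
    trial_id = 1
    for kind, valences, durations in (
        ("image", image_val, np.full(config.n_image_trials, config.image_duration)),
        ("video", video_val, video_dur),
    ):
        for valence, dur in zip(valences, durations):
            if valence == "positive":
                likert = int(rng_part.integers(8, 11))
                if rng_part.random() < config.likert_noise:
                    likert = int(rng_part.integers(1, 8))
            else:
                likert = int(rng_part.integers(1, 4))
                if rng_part.random() < config.likert_noise:
                    likert = int(rng_part.integers(4, 11))
            rows.append({
                "trial_id": trial_id,
                "participant_id": participant_id,
                "kind": kind,
                "onset_s": round(t, 6),
                "duration_s": round(float(dur), 6),
                "valence": valence,
                "likert": likert,
            })
            t += float(dur) + config.inter_trial_gap
            trial_id += 1
    protocol = pd.DataFrame(rows)
    return validate_protocol(protocol, baseline=config.baseline_duration)


def _session_length(config: StudyConfig, protocol: pd.DataFrame) -> float:
    last = protocol.iloc[-1]
    return float(last["onset_s"] + last["duration_s"] + config.inter_trial_gap)


_MODALITY_KEYS = {"fnirs": 1, "eeg": 2, "face": 3}


def trial_gains(
    config: StudyConfig, participant_id: int, modality: str, n_trials: int
) -> np.ndarray:
    """Per-trial expressiveness gains for one participant and modality.

    Unit-mean gamma draws (shape ``expressiveness_shape``) that scale the
    planted effect trial by trial, emulating participants who respond
    strongly to some stimuli and barely to others. Shape 0 disables the
    variability (all gains 1). Deterministic in (seed, participant,
    modality) and independent across modalities.
    """
    if config.expressiveness_shape == 0:
        return np.ones(n_trials)
    rng = _spawn(config.seed, 0x6A15, _MODALITY_KEYS[modality], participant_id)
    k = config.expressiveness_shape
    return rng.gamma(k, 1.0 / k, size=n_trials)


def _normalized_hrf_kernel(rate: float, hrf_params: HRFParams) -> np.ndarray:
    kernel = hrf(np.arange(0, 32.0, 1.0 / rate), hrf_params)
    return kernel / kernel.max()


def _valence_regressors(
    protocol: pd.DataFrame,
    n: int,
    rate: float,
    hrf_params: HRFParams,
    gains: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Boxcar * HRF regressor per valence, unit peak response per trial;
    optional per-trial gains scale each trial's boxcar."""
    time = np.arange(n) / rate
    kernel = _normalized_hrf_kernel(rate, hrf_params)
    if gains is None:
        gains = np.ones(len(protocol))
    out = {}
    for valence in ("positive", "negative"):
        box = np.zeros(n)
        for k, (_, row) in enumerate(protocol.iterrows()):
            if row["valence"] != valence:
                continue
            on, off = row["onset_s"], row["onset_s"] + row["duration_s"]
            box[(time >= on - 1e-9) & (time < off - 1e-9)] = gains[k]
        out[valence] = np.convolve(box, kernel)[:n]
    return out


def planted_concentrations(
    protocol: pd.DataFrame,
    config: StudyConfig,
    hrf_params: HRFParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The exact (hbo, hbr) target series (uM, per optode) the fNIRS
    generator embeds, before the intensity mapping and noise — the
    reference for round-trip checks."""
    hrf_params = hrf_params or HRFParams()
    pid = int(protocol["participant_id"].iloc[0])
    n = int(round(_session_length(config, protocol) * config.fnirs_rate))
    gains = trial_gains(config, pid, "fnirs", len(protocol))
    reg = _valence_regressors(protocol, n, config.fnirs_rate, hrf_params, gains)

    amp = np.zeros((N_OPTODES, 2))      # columns: response to pos / neg trials
    amp[list(_LEFT_OPTODES), 0] = config.effect_fnirs
    amp[list(_RIGHT_OPTODES), 0] = config.effect_fnirs * _CONTRA_FRACTION
    amp[list(_RIGHT_OPTODES), 1] = config.effect_fnirs
    amp[list(_LEFT_OPTODES), 1] = config.effect_fnirs * _CONTRA_FRACTION

    hbo = np.stack([reg["positive"], reg["negative"]], axis=1) @ amp.T
    return hbo, -hbo / 3.0


def plant_fnirs_response(
    protocol: pd.DataFrame,
    config: StudyConfig,
    mbll: MBLLParams | None = None,
    hrf_params: HRFParams | None = None,
    rng: np.random.Generator | None = None,
) -> RawFNIRSRecord:
    """Raw two-wavelength intensities carrying a lateralized hemodynamic
    response.

    Positive-valence trials drive the left optodes at ``effect_fnirs`` uM
    peak oxy-hemoglobin (right at 40%); negative trials mirror this. Deoxy
    responds at -1/3 of oxy. Concentrations map to intensities via
    ``I = I0 * 10^(-E c) + ambient`` with the same constants
    :func:`affectfuse.fnirs.mbll_convert` inverts, then Gaussian noise
    (sd ``noise_fnirs * I0``) and a slow sinusoidal drift (amplitude
    ``drift_fnirs * I0``) are added on the intensity scale.
    """
    mbll = mbll or MBLLParams()
    hrf_params = hrf_params or HRFParams()
    rng = rng or _spawn(config.seed, 0xF1)
    n = int(round(_session_length(config, protocol) * config.fnirs_rate))
    time = np.arange(n) / config.fnirs_rate
    hbo, hbr = planted_concentrations(protocol, config, hrf_params)
    conc = np.stack([hbo, hbr], axis=-1)                                  # (n, opt, 2)
    dod = np.einsum("wc,noc->now", mbll.matrix(), conc)
    intensity = _I0 * np.power(10.0, -dod)

    if config.drift_fnirs > 0:
        period = rng.uniform(60.0, 180.0, size=(N_OPTODES, 2))
        phase = rng.uniform(0, 2 * np.pi, size=(N_OPTODES, 2))
        intensity = intensity + config.drift_fnirs * _I0 * np.sin(
            2 * np.pi * time[:, None, None] / period + phase)
    if config.noise_fnirs > 0:
        intensity = intensity + rng.normal(
            0.0, config.noise_fnirs * _I0, size=intensity.shape)

    ambient = np.full((n, N_OPTODES), _AMBIENT)
    if config.noise_fnirs > 0:
        ambient = ambient + rng.normal(
            0.0, 0.1 * config.noise_fnirs * _I0, size=ambient.shape)
    return RawFNIRSRecord(
        time=time, intensity=intensity + ambient[:, :, None],
        ambient=ambient, rate=config.fnirs_rate)


def _narrowband_noise(
    rng: np.random.Generator, n: int, rate: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance noise band-limited to (lo, hi) Hz."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def plant_eeg_effect(
    protocol: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
) -> RawEEGRecord:
    """14-channel EEG with a valence-signed frontal alpha asymmetry.

    During a positive trial the right member of each frontal pair carries
    alpha amplitude scaled by exp(+effect_eeg/4) and the left by
    exp(-effect_eeg/4), so the right-minus-left alpha log-power difference
    is +effect_eeg; negative trials negate the sign. Non-frontal channels
    and inter-trial periods stay at the resting alpha level.
    """
    rng = rng or _spawn(config.seed, 0xEE)
    n = int(round(_session_length(config, protocol) * config.eeg_rate))
    time = np.arange(n) / config.eeg_rate

    side = {ch: 0.0 for ch in EEG_CHANNELS}
    for left, right in ASYMMETRY_PAIRS:
        side[left], side[right] = -1.0, 1.0

    pid = int(protocol["participant_id"].iloc[0])
    gains = trial_gains(config, pid, "eeg", len(protocol))
    shift = np.zeros(n)     # right-hemisphere log-power shift, in +-delta/2
    for k, (_, row) in enumerate(protocol.iterrows()):
        mask = (time >= row["onset_s"] - 1e-9) & (
            time < row["onset_s"] + row["duration_s"] - 1e-9)
        sign = 1.0 if row["valence"] == "positive" else -1.0
        shift[mask] = sign * gains[k] * config.effect_eeg / 4.0

    potentials = np.empty((n, len(EEG_CHANNELS)))
    for k, ch in enumerate(EEG_CHANNELS):
        background = config.noise_eeg * _narrowband_noise(
            rng, n, config.eeg_rate, 4.0, 45.0)
        alpha = _narrowband_noise(rng, n, config.eeg_rate, 8.0, 12.0)
        envelope = _ALPHA_BASE_UV * np.exp(side[ch] * shift)
        potentials[:, k] = background + envelope * alpha
    return RawEEGRecord(time=time, potentials=potentials, rate=config.eeg_rate)


def generate_face_stream(
    protocol: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
) -> EmotionProbStream:
    """Per-frame 7-class probabilities for one participant's session.

    Resting frames follow :data:`BASELINE_PROFILE`; during a trial,
    ``effect_face`` of the probability mass moves to Happiness (positive
    valence) or to one negative emotion sampled per trial (Anger, Disgust,
    Fear or Sadness). Frames are Dirichlet draws with concentration
    ``noise_face`` around the target profile (``noise_face = 0`` emits the
    profile exactly).
    """
    rng = rng or _spawn(config.seed, 0xFA)
    n = int(round(_session_length(config, protocol) * config.face_rate))
    time = np.arange(n) / config.face_rate

    pid = int(protocol["participant_id"].iloc[0])
    gains = trial_gains(config, pid, "face", len(protocol))
    expressive = (POSITIVE_EMOTION, *NEGATIVE_EMOTIONS)
    profile = np.tile(BASELINE_PROFILE, (n, 1))
    for k, (_, row) in enumerate(protocol.iterrows()):
        if rng.random() < config.misexpression_rate:
            # spontaneous displays are unreliable: sometimes the expressed
            # emotion does not track the felt valence at all
            target = expressive[int(rng.integers(len(expressive)))]
        elif row["valence"] == "positive":
            target = POSITIVE_EMOTION
        else:
            target = NEGATIVE_EMOTIONS[int(rng.integers(len(NEGATIVE_EMOTIONS)))]
        onehot = np.zeros(len(EMOTIONS))
        onehot[EMOTIONS.index(target)] = 1.0
        bias = min(config.effect_face * gains[k], 0.95)
        mask = (time >= row["onset_s"] - 1e-9) & (
            time < row["onset_s"] + row["duration_s"] - 1e-9)
        profile[mask] = (1 - bias) * BASELINE_PROFILE + bias * onehot
    if config.noise_face > 0:
        # Dirichlet with a per-frame concentration vector, via gamma draws.
        alphas = config.noise_face * profile
        gammas = rng.gamma(np.clip(alphas, 1e-12, None))
        probs = gammas / gammas.sum(axis=1, keepdims=True)
    else:
        probs = profile
    stream = EmotionProbStream(time=time, probs=probs, rate=config.face_rate)
    stream.validate_simplex(atol=1e-9)
    return stream


def generate_study(config: StudyConfig) -> StudyDataset:
    """Full synthetic study: protocol plus the three raw streams per
    participant, deterministic for a fixed ``config.seed``."""
    participants = []
    for pid in range(1, config.n_participants + 1):
        protocol = build_protocol(config, pid)
        participants.append(ParticipantData(
            participant_id=pid,
            protocol=protocol,
            fnirs=plant_fnirs_response(
                protocol, config, rng=_spawn(config.seed, 0xF1, pid)),
            eeg=plant_eeg_effect(
                protocol, config, rng=_spawn(config.seed, 0xEE, pid)),
            face=generate_face_stream(
                protocol, config, rng=_spawn(config.seed, 0xFA, pid)),
        ))
    return StudyDataset(config=config, participants=participants)
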