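"""EEG processing: 30 Hz low-pass, ICA artifact rejection, baseline
adjustment and the 72-feature band-power/asymmetry vector.

Band powers are Welch log-PSD averages over the four half-open bands
theta (4, 8], slow alpha (8, 10], alpha (8, 12] and beta (12, 30] Hz;
asymmetry features are right-minus-left log power for the four homologous
frontal pairs AF3-AF4, F7-F8, F3-F4 and FC5-FC6.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .config import ASYMMETRY_PAIRS, BandDefinition, EEG_CHANNELS
from .fnirs import _zero_phase_lowpass
from .signals import DataError, RawEEGRecord, slice_window

logger = logging.getLogger(__name__)

BAND_NAMES = BandDefinition().names

EEG_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{band}_logpsd" for ch in EEG_CHANNELS for band in BAND_NAMES
) + tuple(
    f"asym_{left}_{right}_{band}"
    for (left, right) in ASYMMETRY_PAIRS
    for band in BAND_NAMES
)


def lowpass_eeg(record: RawEEGRecord, cutoff: float = 30.0) -> RawEEGRecord:
    """Zero-phase 4th-order Butterworth low-pass, default 30 Hz cutoff."""
    return RawEEGRecord(
        time=record.time,
        potentials=_zero_phase_lowpass(record.potentials, cutoff, record.rate),
        channels=record.channels,
        rate=record.rate,
    )


def _lowfreq_fraction(x: np.ndarray, rate: float, edge: float = 3.0) -> float:
    freqs, psd = sps.welch(x, fs=rate, nperseg=min(len(x), int(4 * rate)))
    total = psd.sum()
    if total <= 0:
        return 0.0
    return float(psd[freqs < edge].sum() / total)


def ica_clean_eeg(
    record: RawEEGRecord,
    kurtosis_z: float = 3.0,
    lowfreq_fraction: float = 0.6,
    seed: int = 0,
    max_retries: int = 2,
    max_fit_samples: int = 30000,
) -> RawEEGRecord:
    """Remove artifact components found by FastICA.

    A component is flagged when its excess kurtosis is an outlier across
    components (z-score above ``kurtosis_z``, spike/pop artifacts) or when
    more than ``lowfreq_fraction`` of its spectral power lies below 3 Hz
    (blink and movement proxy). Flagged components are zeroed before
    reconstruction. Non-convergence after retries passes the input through
    with a warning.

    The unmixing matrix is estimated on an evenly strided subsample of at
    most ``max_fit_samples`` samples and applied to the full recording;
    strided subsampling does not bias the (time-independent) mixing
    estimate and keeps long sessions tractable.
    """
    data = record.potentials
    if not np.all(np.isfinite(data)):
        raise DataError("EEG record contains non-finite samples")
    n_comp = data.shape[1]
    mean = data.mean(axis=0)
    if np.allclose(data.std(axis=0), 0):
        return record
    centered = data - mean
    stride = max(1, int(np.ceil(centered.shape[0] / max_fit_samples)))
    for attempt in range(max_retries):
        ica = FastICA(n_components=n_comp, random_state=seed + attempt,
                      max_iter=300, tol=1e-3, whiten="unit-variance")
        try:
            with np.errstate(over="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica.fit(centered[::stride])
        except Exception:
            continue
        if ica.n_iter_ >= 300 and attempt < max_retries - 1:
            continue
        # components_ is square full-rank, so mixing_ = pinv(components_)
        # makes source->signal reconstruction exact.
        sources = (centered - ica.mean_) @ ica.components_.T
        kurt = stats.kurtosis(sources, axis=0)
        kz = (kurt - kurt.mean()) / kurt.std(ddof=0) if kurt.std(ddof=0) > 0 else kurt * 0
        lf = np.array([_lowfreq_fraction(sources[:, k], record.rate)
                       for k in range(n_comp)])
        artifact = (kz > kurtosis_z) | (lf > lowfreq_fraction)
        if artifact.any():
            logger.info("ICA flagged %d artifact component(s)", int(artifact.sum()))
        sources = sources * (~artifact)[None, :]
        cleaned = sources @ ica.mixing_.T + ica.mean_ + mean
        return RawEEGRecord(time=record.time, potentials=cleaned,
                            channels=record.channels, rate=record.rate)
    logger.warning("FastICA did not converge after %d retries; EEG passed "
                   "through uncleaned", max_retries)
    return record


def baseline_adjust_eeg(
    record: RawEEGRecord,
    protocol: pd.DataFrame,
    baseline: float = 5.0,
) -> dict[int, RawEEGRecord]:
    """Per-trial slices minus the mean over the 5 s before onset.

    At 128 Hz the default window averages 640 samples. Trials without a
    full pre-onset baseline are excluded with a log entry.
    """
    out: dict[int, RawEEGRecord] = {}
    for _, row in protocol.iterrows():
        onset, dur = float(row["onset_s"]), float(row["duration_s"])
        if onset - baseline < record.time[0] - 1e-9:
            logger.warning("trial %s lacks %g s of pre-onset EEG; excluded",
                           row["trial_id"], baseline)
            continue
        base_sl = slice_window(record.time, onset - baseline, onset)
        trial_sl = slice_window(record.time, onset, onset + dur)
        if trial_sl.stop <= trial_sl.start or base_sl.stop <= base_sl.start:
            logger.warning("trial %s has an empty slice; excluded", row["trial_id"])
            continue
        out[int(row["trial_id"])] = RawEEGRecord(
            time=record.time[trial_sl] - onset,
            potentials=(record.potentials[trial_sl]
                        - record.potentials[base_sl].mean(axis=0)),
            channels=record.channels,
            rate=record.rate,
        )
    return out


def band_logpsd(
    trial: RawEEGRecord,
    bands: BandDefinition | None = None,
    window_seconds: float = 2.0,
) -> pd.DataFrame:
    """Natural-log band power per channel: Welch PSD with Hann windows
    (default 2 s, 50% overlap) averaged over bins with lower < f <= upper.

    Returns a channels x bands DataFrame. Trials shorter than one window
    shrink the window with a warning.
    """
    bands = bands or BandDefinition()
    n = trial.potentials.shape[0]
    if n < 2 * trial.rate:
        raise DataError("trial too short to resolve 4 Hz (need >= 2 s)")
    if not np.all(np.isfinite(trial.potentials)):
        raise DataError("non-finite samples in trial")
    nperseg = int(window_seconds * trial.rate)
    if nperseg > n:
        logger.warning("trial shorter than one %g-s window; shrinking to %d "
                       "samples", window_seconds, n)
        nperseg = n
    freqs, psd = sps.welch(trial.potentials, fs=trial.rate, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2, axis=0)
    table = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs > lo) & (freqs <= hi)
        if not mask.any():
            raise DataError(f"band {name} contains no PSD bins")
        power = psd[mask].mean(axis=0)
        if np.any(power <= 0):
            raise DataError(f"non-positive band power in {name}")
        table[name] = np.log(power)
    return pd.DataFrame(table, index=list(trial.channels))


def extract_eeg_features(
    trial: RawEEGRecord,
    bands: BandDefinition | None = None,
) -> pd.Series:
    """72 named features: 14x4 channel band log-PSD values followed by 4x4
    right-minus-left asymmetry terms for the frontal pairs."""
    bands = bands or BandDefinition()
    table = band_logpsd(trial, bands)
    values: list[float] = []
    for ch in EEG_CHANNELS:
        if ch not in table.index:
            raise DataError(f"channel {ch} missing from band power table")
        values.extend(float(table.loc[ch, b]) for b in bands.names)
    for left, right in ASYMMETRY_PAIRS:
        values.extend(
            float(table.loc[right, b] - table.loc[left, b]) for b in bands.names)
    return pd.Series(values, index=list(EEG_FEATURE_NAMES))
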