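"""fNIRS processing: intensity-to-hemoglobin conversion, denoising and
per-trial feature extraction.

The chain implemented here is

    raw intensities --MBLL--> concentration changes --0.1 Hz low-pass-->
    --ICA with HRF-guided component selection--> --5-s baseline subtraction
    per trial--> 96 summary features per trial.

Concentration changes are relative (uM) with respect to a reference
intensity window; hbt/oxy are derived identities, never stored.
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

from .config import ConfigurationError, HRFParams, MBLLParams, N_OPTODES
from .signals import (
    DataError,
    HemodynamicSignals,
    ProtocolError,
    RawFNIRSRecord,
    slice_window,
)

logger = logging.getLogger(__name__)

#: Hemodynamic signal names in feature order.
SIGNALS = ("hbo", "hbr", "hbt", "oxy")
#: Per-trial summary statistics in feature order.
STATISTICS = ("mean", "median", "std", "max", "min", "range")

FNIRS_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"o{opt + 1}_{sig}_{stat}"
    for opt in range(N_OPTODES)
    for sig in SIGNALS
    for stat in STATISTICS
)


def hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    h(t) = A * [g(t; a1, b1) - c * g(t; a2, b2)] where g is the gamma
    probability density with shape a and rate b. h(0) = 0 for shapes > 1.
    """
    params = params or HRFParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is defined for t >= 0 only")
    g1 = stats.gamma.pdf(t, params.alpha1, scale=1.0 / params.beta1)
    g2 = stats.gamma.pdf(t, params.alpha2, scale=1.0 / params.beta2)
    return params.amplitude * (g1 - params.undershoot_ratio * g2)


def expected_response(
    protocol: pd.DataFrame,
    n_samples: int,
    rate: float = 4.0,
    params: HRFParams | None = None,
    hrf_span: float = 32.0,
) -> np.ndarray:
    """Model regressor: boxcar stimulus function convolved with the HRF.

    The boxcar is 1 during each trial and 0 elsewhere; the discrete
    convolution is evaluated on the recording grid and truncated to
    ``n_samples``, so a one-sample stimulus reproduces the sampled HRF.
    """
    box = np.zeros(n_samples)
    time = np.arange(n_samples) / rate
    for _, row in protocol.iterrows():
        if row["onset_s"] + row["duration_s"] > time[-1] + 1.0 / rate + 1e-9:
            raise ProtocolError(
                f"trial {row['trial_id']} extends past the recording end")
        sl = slice_window(time, row["onset_s"], row["onset_s"] + row["duration_s"])
        box[sl] = 1.0
    kernel = hrf(np.arange(0, hrf_span, 1.0 / rate), params)
    return np.convolve(box, kernel)[:n_samples]


def mbll_convert(
    record: RawFNIRSRecord,
    params: MBLLParams | None = None,
    baseline_window: float = 30.0,
    subtract_ambient: bool = True,
) -> HemodynamicSignals:
    """Convert raw intensities to concentration changes (uM) via the
    modified Beer-Lambert law.

    Optical density change per wavelength is
    ``dOD = -log10(I / mean(I over the reference window))``; the 2x2
    linear system with the extinction matrix, source-detector separation
    and differential pathlength factor is solved per optode and sample.
    The ambient channel, when enabled, is subtracted from both wavelength
    intensities first.
    """
    params = params or MBLLParams()
    intensity = record.intensity.copy()
    if subtract_ambient:
        intensity = intensity - record.ambient[:, :, None]
    if np.any(intensity <= 0):
        idx = np.argwhere(intensity <= 0)[0]
        raise DataError(
            f"non-positive intensity at sample {idx[0]}, optode {idx[1] + 1}, "
            f"wavelength {record.wavelengths[idx[2]]} nm")
    sl = slice_window(record.time, record.time[0], record.time[0] + baseline_window)
    if sl.stop <= sl.start:
        raise ConfigurationError("baseline_window selects no samples")
    i0 = intensity[sl].mean(axis=0)                       # (optode, wavelength)
    dod = -np.log10(intensity / i0)                       # (n, optode, wavelength)
    # Solve E @ [dHbO, dHbR] = dOD for every (sample, optode) at once.
    inv = np.linalg.inv(params.matrix(record.wavelengths))
    conc = np.einsum("cw,now->noc", inv, dod)             # (n, optode, 2)
    return HemodynamicSignals(
        time=record.time, hbo=conc[..., 0], hbr=conc[..., 1], rate=record.rate)


def _zero_phase_lowpass(x: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    if cutoff >= rate / 2:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {rate / 2} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def lowpass_fnirs(signals: HemodynamicSignals, cutoff: float = 0.1) -> HemodynamicSignals:
    """Zero-phase 4th-order Butterworth low-pass (default 0.1 Hz) on hbo/hbr."""
    return HemodynamicSignals(
        time=signals.time,
        hbo=_zero_phase_lowpass(signals.hbo, cutoff, signals.rate),
        hbr=_zero_phase_lowpass(signals.hbr, cutoff, signals.rate),
        rate=signals.rate,
    )


def _regression_tstat(component: np.ndarray, regressor: np.ndarray) -> tuple[float, float]:
    """Slope t-statistic and two-sided p-value of component ~ regressor."""
    res = stats.linregress(regressor, component)
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return float(t), float(res.pvalue)


def _ica_filter_channels(
    data: np.ndarray,
    regressor: np.ndarray,
    alpha: float,
    seed: int,
    max_retries: int,
) -> np.ndarray:
    """FastICA on (n_samples, n_channels); keep the highest-|t| component
    plus any with p < alpha against the model regressor; reconstruct."""
    n_comp = data.shape[1]
    mean = data.mean(axis=0)
    if np.allclose(data.std(axis=0), 0):
        return data
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=n_comp, random_state=seed + attempt,
            max_iter=500, whiten="unit-variance")
        try:
            with np.errstate(over="ignore", invalid="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                sources = ica.fit_transform(data - mean)
        except Exception:
            continue
        if ica.n_iter_ >= 500 and attempt < max_retries - 1:
            continue
        tvals, pvals = zip(*(
            _regression_tstat(sources[:, k], regressor) for k in range(n_comp)))
        keep = np.asarray(pvals) < alpha
        keep[int(np.argmax(np.abs(tvals)))] = True
        sources = sources * keep[None, :]
        return sources @ ica.mixing_.T + mean
    logger.warning("FastICA did not converge after %d retries; passing signal "
                   "through unfiltered", max_retries)
    return data


def ica_select_hemodynamic(
    signals: HemodynamicSignals,
    regressor: np.ndarray,
    alpha: float = 0.05,
    seed: int = 0,
    max_retries: int = 3,
) -> HemodynamicSignals:
    """HRF-guided ICA denoising, applied per chromophore.

    Each chromophore's optode-by-time matrix is decomposed with FastICA;
    each component is regressed on the expected-response regressor and the
    component with the highest |t| (plus any significant at ``alpha``) is
    retained, all others zeroed, before reconstruction. With fewer than two
    optodes the signal passes through unchanged.
    """
    if regressor.shape[0] != signals.time.shape[0]:
        raise DataError("regressor length must match the recording")
    if signals.hbo.ndim < 2 or signals.hbo.shape[1] < 2:
        logger.warning("fewer than 2 optodes: ICA skipped, signal passed through")
        return signals
    return HemodynamicSignals(
        time=signals.time,
        hbo=_ica_filter_channels(signals.hbo, regressor, alpha, seed, max_retries),
        hbr=_ica_filter_channels(signals.hbr, regressor, alpha, seed + 101, max_retries),
        rate=signals.rate,
    )


def baseline_adjust(
    signals: HemodynamicSignals,
    protocol: pd.DataFrame,
    baseline: float = 5.0,
) -> dict[int, HemodynamicSignals]:
    """Per-trial slices with the mean of the preceding ``baseline`` seconds
    subtracted.

    Trials without a full pre-onset baseline in the recording are excluded
    with a log entry. Returns ``{trial_id: trial signals}``.
    """
    out: dict[int, HemodynamicSignals] = {}
    for _, row in protocol.iterrows():
        onset, dur = float(row["onset_s"]), float(row["duration_s"])
        if onset - baseline < signals.time[0] - 1e-9:
            logger.warning("trial %s lacks %g s of pre-onset data; excluded",
                           row["trial_id"], baseline)
            continue
        base_sl = slice_window(signals.time, onset - baseline, onset)
        trial_sl = slice_window(signals.time, onset, onset + dur)
        if trial_sl.stop <= trial_sl.start or base_sl.stop <= base_sl.start:
            logger.warning("trial %s has an empty slice; excluded", row["trial_id"])
            continue
        out[int(row["trial_id"])] = HemodynamicSignals(
            time=signals.time[trial_sl] - onset,
            hbo=signals.hbo[trial_sl] - signals.hbo[base_sl].mean(axis=0),
            hbr=signals.hbr[trial_sl] - signals.hbr[base_sl].mean(axis=0),
            rate=signals.rate,
        )
    return out


def extract_fnirs_features(trial: HemodynamicSignals) -> pd.Series:
    """96 named features: {mean, median, std, max, min, range} of
    {hbo, hbr, hbt, oxy} per optode, optode-major order.

    Standard deviation uses the sample (n-1) convention.
    """
    if trial.hbo.ndim != 2 or trial.hbo.shape[1] != N_OPTODES:
        raise DataError(
            f"expected {N_OPTODES} optodes, got shape {trial.hbo.shape}")
    if trial.hbo.shape[0] == 0:
        raise DataError("empty trial slice")
    values: list[float] = []
    for opt in range(N_OPTODES):
        for sig in SIGNALS:
            x = trial.signal(sig)[:, opt]
            if not np.all(np.isfinite(x)):
                raise DataError(f"non-finite samples in optode {opt + 1} {sig}")
            mx, mn = float(np.max(x)), float(np.min(x))
            values.extend([
                float(np.mean(x)), float(np.median(x)),
                float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                mx, mn, mx - mn,
            ])
    return pd.Series(values, index=list(FNIRS_FEATURE_NAMES))
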