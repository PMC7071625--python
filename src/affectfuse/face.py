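"""Facial-affect aggregation: per-clip emotion and valence calls from
per-frame 7-class probability streams.

A clip is calibrated by subtracting the mean probability profile of its
first 5 s (a pre-stimulus window), clipping at zero and renormalizing each
frame onto the simplex; the remaining frames are summed per emotion and the
winning emotion / positive-negative affect ratio derived from the sums.
Happiness carries positive valence; Anger, Disgust, Fear and Sadness carry
negative valence; Surprise and Neutral are excluded from the valence call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EMOTIONS, NEGATIVE_EMOTIONS, POSITIVE_EMOTION
from .signals import DataError, EmotionProbStream, slice_window

logger = logging.getLogger(__name__)

_POS_IDX = EMOTIONS.index(POSITIVE_EMOTION)
_NEG_IDX = tuple(EMOTIONS.index(e) for e in NEGATIVE_EMOTIONS)


@dataclass(frozen=True)
class EmotionAggregate:
    """Summed per-emotion probability mass over a clip and the argmax."""

    totals: pd.Series           # index = EMOTIONS, values >= 0
    winning_emotion: str
    n_frames: int


@dataclass(frozen=True)
class AffectCall:
    """Positive/negative affect ratings for one clip.

    ``p_pos + p_neg == 1`` whenever the call is defined; ``strength`` is
    max(p_pos, p_neg) in [0.5, 1]. ``defined`` is False when neither
    happiness nor any negative emotion carries mass (clip excluded
    downstream). ``signed_rating`` = p_pos - p_neg in [-1, 1] is the
    continuous affect used for correlation analyses.
    """

    p_pos: float
    p_neg: float
    label: str
    defined: bool = True

    @property
    def strength(self) -> float:
        return max(self.p_pos, self.p_neg)

    @property
    def signed_rating(self) -> float:
        return self.p_pos - self.p_neg


def slice_face_trial(
    stream: EmotionProbStream,
    onset: float,
    duration: float,
    calibration: float = 5.0,
) -> EmotionProbStream:
    """Cut the clip [onset - calibration, onset + duration) from a session
    stream so that the calibration window is the pre-stimulus baseline."""
    start = max(onset - calibration, stream.time[0])
    sl = slice_window(stream.time, start, onset + duration)
    return EmotionProbStream(
        time=stream.time[sl] - start,
        probs=stream.probs[sl],
        emotions=stream.emotions,
        rate=stream.rate,
    )


def calibrate_stream(
    stream: EmotionProbStream,
    window: float = 5.0,
) -> EmotionProbStream:
    """Subtract the mean emotion profile of the first ``window`` seconds
    from all later frames; clip at 0 and renormalize each frame to sum 1.

    The calibration window itself is dropped from the returned stream. A
    frame whose calibrated values are all zero becomes uniform over the
    seven emotions. Streams not longer than the window are returned
    unchanged with a warning. ``window=0`` is the identity.
    """
    if window == 0:
        return stream
    n_cal = int(np.searchsorted(stream.time, stream.time[0] + window - 1e-9))
    if n_cal >= stream.probs.shape[0]:
        logger.warning("stream (%d frames) not longer than the %g-s calibration "
                       "window; calibration skipped", stream.probs.shape[0], window)
        return stream
    mean = stream.probs[:n_cal].mean(axis=0)
    adjusted = np.clip(stream.probs[n_cal:] - mean, 0.0, None)
    sums = adjusted.sum(axis=1, keepdims=True)
    uniform = np.full(len(stream.emotions), 1.0 / len(stream.emotions))
    # frames fully cancelled by calibration (within rounding) become uniform
    ok = sums > 1e-9
    adjusted = np.where(ok, adjusted / np.where(ok, sums, 1.0), uniform)
    return EmotionProbStream(
        time=stream.time[n_cal:],
        probs=adjusted,
        emotions=stream.emotions,
        rate=stream.rate,
    )


def aggregate_emotion(stream: EmotionProbStream) -> EmotionAggregate:
    """Sum frame probabilities per emotion; the winner is the argmax with
    ties broken by the documented emotion order."""
    if stream.probs.shape[0] == 0:
        raise DataError("cannot aggregate an empty stream")
    totals = stream.probs.sum(axis=0)
    winner = EMOTIONS[int(np.argmax(totals))]   # argmax takes first on ties
    return EmotionAggregate(
        totals=pd.Series(totals, index=list(stream.emotions)),
        winning_emotion=winner,
        n_frames=stream.probs.shape[0],
    )


def affect_ratio(aggregate: EmotionAggregate) -> AffectCall:
    """Positive/negative affect ratings from the aggregated emotion mass.

    p_pos = H / (H + M) and p_neg = M / (H + M), where H is the happiness
    mass and M the maximum mass among the four negative emotions; Surprise
    and Neutral never enter. The label is positive when p_pos >= p_neg
    (ties positive). A zero denominator yields an undefined call.
    """
    totals = aggregate.totals.to_numpy()
    happiness = float(totals[_POS_IDX])
    max_negative = float(max(totals[i] for i in _NEG_IDX))
    denom = happiness + max_negative
    if denom <= 0:
        logger.warning("affect undefined: no happiness or negative emotion mass")
        return AffectCall(p_pos=np.nan, p_neg=np.nan, label="undefined", defined=False)
    p_pos = happiness / denom
    p_neg = max_negative / denom
    return AffectCall(
        p_pos=p_pos, p_neg=p_neg,
        label="positive" if p_pos >= p_neg else "negative",
    )


def classify_stimulus(labels: list[str] | pd.Series) -> str:
    """Explicit/ambiguous stimulus rule across participants.

    Returns the majority affect label when strictly more than 50% of
    participants share it, else ``"ambiguous"`` (a 50/50 split is
    ambiguous).
    """
    labels = pd.Series(list(labels))
    if labels.empty:
        raise DataError("need at least one participant label")
    counts = labels.value_counts()
    if counts.iloc[0] * 2 > len(labels):
        return str(counts.index[0])
    return "ambiguous"


def recognition_rate(
    calls: pd.DataFrame,
    by: str = "trial",
) -> pd.Series:
    """Fraction of correct affect calls per trial or per participant.

    ``calls`` needs columns ``trial_id, participant_id, label, truth``.
    ``by="trial"`` averages across participants within each trial;
    ``by="participant"`` across trials within each participant.
    """
    required = {"trial_id", "participant_id", "label", "truth"}
    if not required <= set(calls.columns):
        raise DataError(f"calls table needs columns {sorted(required)}")
    key = {"trial": "trial_id", "participant": "participant_id"}.get(by)
    if key is None:
        raise ValueError("by must be 'trial' or 'participant'")
    correct = (calls["label"] == calls["truth"]).astype(float)
    return correct.groupby(calls[key]).mean()


def rate_summary(rates: pd.Series) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a rate series."""
    values = np.asarray(rates, dtype=float)
    if values.size != len(rates) or values.size == 0:
        raise DataError("empty rate series")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd


def call_trials(
    stream: EmotionProbStream,
    protocol: pd.DataFrame,
    calibration: float = 5.0,
) -> pd.DataFrame:
    """Affect calls for every protocol trial of one participant's session
    stream. Returns trial_id, participant_id, p_pos, p_neg, label,
    signed_rating rows; undefined calls keep label ``"undefined"``."""
    rows = []
    for _, trial in protocol.iterrows():
        clip = slice_face_trial(stream, float(trial["onset_s"]),
                                float(trial["duration_s"]), calibration)
        call = affect_ratio(aggregate_emotion(calibrate_stream(clip, calibration)))
        rows.append({
            "trial_id": int(trial["trial_id"]),
            "participant_id": int(trial["participant_id"]),
            "p_pos": call.p_pos,
            "p_neg": call.p_neg,
            "label": call.label,
            "signed_rating": call.signed_rating,
        })
    return pd.DataFrame(rows)
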