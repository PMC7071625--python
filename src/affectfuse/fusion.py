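"""Valence classification: feature fusion, leave-one-trial-out
cross-validation with a polynomial-kernel SVM, and ROC summaries.

The cross-validation scheme holds out one trial index at a time across all
participants: the model trains on the pooled remaining trials of every
participant and is tested on every participant's held-out trial, giving
``n_participants`` test observations per fold and
``n_trials x n_participants`` observations overall. Standardization
statistics come from the training fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import SVMConfig
from .signals import DataError

logger = logging.getLogger(__name__)

MODALITY_WIDTHS = {"fnirs": 96, "eeg": 72, "fused": 168}


@dataclass
class FeatureMatrix:
    """Feature rows keyed by (participant_id, trial_id) with valence labels."""

    X: pd.DataFrame
    y: pd.Series
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_WIDTHS:
            raise DataError(f"unknown modality {self.modality!r}")
        if self.X.shape[1] != MODALITY_WIDTHS[self.modality]:
            raise DataError(
                f"{self.modality} matrix must have {MODALITY_WIDTHS[self.modality]} "
                f"columns, got {self.X.shape[1]}")
        if not self.X.index.equals(self.y.index):
            raise DataError("features and labels must share an index")
        if self.X.isna().any().any():
            raise DataError("feature matrix contains missing values")


@dataclass
class FoldResult:
    """One leave-one-trial-out fold: held-out trial and its predictions."""

    held_out_trial_id: int
    predictions: pd.DataFrame     # participant_id, truth, predicted, score
    accuracy: float


@dataclass(frozen=True)
class ROCSummary:
    """ROC area with its Hanley-McNeil standard error and normal 95% CI."""

    auc: float
    standard_error: float
    ci95: tuple[float, float]
    n_observations: int


def build_matrix(
    fnirs_features: pd.DataFrame,
    eeg_features: pd.DataFrame,
    labels: pd.Series,
    modality: str = "fused",
) -> FeatureMatrix:
    """Assemble one modality's matrix on the common (participant, trial)
    keys; rows excluded from any modality are dropped from all of them.

    ``fnirs_features``/``eeg_features`` are indexed by (participant_id,
    trial_id); ``labels`` maps the same keys to positive/negative.
    """
    common = fnirs_features.index.intersection(eeg_features.index) \
        .intersection(labels.index)
    dropped = set(labels.index) - set(common)
    if dropped:
        logger.info("dropping %d labeled rows missing from a feature table: %s",
                    len(dropped), sorted(dropped)[:5])
    if len(common) == 0:
        raise DataError("no common (participant, trial) keys across modalities")
    if modality == "fnirs":
        X = fnirs_features.loc[common]
    elif modality == "eeg":
        X = eeg_features.loc[common]
    elif modality == "fused":
        X = pd.concat([fnirs_features.loc[common], eeg_features.loc[common]], axis=1)
    else:
        raise DataError(f"unknown modality {modality!r}")
    return FeatureMatrix(X=X, y=labels.loc[common], modality=modality)


def train_predict_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: SVMConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the polynomial-kernel SVM (with training-fold standardization)
    and return predicted labels and signed decision scores for the test
    rows. Scores are oriented so positive means the positive class."""
    config = config or SVMConfig()
    if len(np.unique(y_train)) < 2:
        raise DataError("training rows must contain both classes")
    if np.allclose(np.std(X_train, axis=0), 0):
        raise DataError("degenerate training features: zero variance everywhere")
    model = make_pipeline(
        StandardScaler(),
        SVC(kernel=config.kernel, degree=config.degree, C=config.C,
            gamma=config.gamma, coef0=config.coef0),
    )
    model.fit(X_train, y_train)
    scores = model.decision_function(X_test)
    # SVC orients decision_function toward classes_[1]; flip so that
    # positive scores always mean the "positive" valence label.
    if model[-1].classes_[1] != "positive":
        scores = -scores
    predicted = np.where(scores >= 0, "positive", "negative")
    return predicted, scores


def loto_cv(
    matrix: FeatureMatrix,
    config: SVMConfig | None = None,
) -> list[FoldResult]:
    """Leave-one-trial-out cross-validation over the trial_id index level.

    Folds with a single-class training set are skipped with a warning.
    """
    trial_ids = sorted(matrix.X.index.get_level_values("trial_id").unique())
    folds: list[FoldResult] = []
    for tid in trial_ids:
        test_mask = matrix.X.index.get_level_values("trial_id") == tid
        y_train = matrix.y[~test_mask]
        if len(y_train.unique()) < 2:
            logger.warning("fold %s skipped: single-class training set", tid)
            continue
        predicted, scores = train_predict_svm(
            matrix.X[~test_mask].to_numpy(), y_train.to_numpy(),
            matrix.X[test_mask].to_numpy(), config)
        truth = matrix.y[test_mask]
        predictions = pd.DataFrame({
            "participant_id": truth.index.get_level_values("participant_id"),
            "truth": truth.to_numpy(),
            "predicted": predicted,
            "score": scores,
        })
        folds.append(FoldResult(
            held_out_trial_id=int(tid),
            predictions=predictions,
            accuracy=float((predictions["truth"] == predictions["predicted"]).mean()),
        ))
    return folds


def fold_observations(folds: list[FoldResult]) -> pd.DataFrame:
    """All test observations across folds, one row each."""
    frames = []
    for fold in folds:
        frame = fold.predictions.copy()
        frame.insert(0, "trial_id", fold.held_out_trial_id)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def roc_summary(scores: np.ndarray, labels: np.ndarray) -> ROCSummary:
    """ROC area via the rank (Mann-Whitney) formulation, with the
    Hanley-McNeil standard error and a normal-approximation 95% CI
    clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "positive"]
    neg = scores[labels == "negative"]
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC undefined: both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = float(np.clip(auc - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.96 * se, 0.0, 1.0))
    return ROCSummary(auc=float(auc), standard_error=se, ci95=(lo, hi),
                      n_observations=n_pos + n_neg)


@dataclass
class ModalityReport:
    """Per-trial accuracies and ROC summaries for the three model variants
    on one content type."""

    content: str
    per_trial_accuracy: pd.DataFrame = field(default_factory=pd.DataFrame)
    summaries: dict[str, ROCSummary] = field(default_factory=dict)
    mean_accuracy: dict[str, float] = field(default_factory=dict)
    observations: dict[str, pd.DataFrame] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Model / Observation / ROC Area / Standard Error / 95% CI rows."""
        rows = []
        for name, s in self.summaries.items():
            rows.append({
                "Model": {"fused": "EEG+fNIRS", "fnirs": "fNIRS", "eeg": "EEG"}[name],
                "Observation": s.n_observations,
                "ROC Area": round(s.auc, 2),
                "Standard Error": round(s.standard_error, 2),
                "95% Confidence Interval": f"{s.ci95[0]:.2f}-{s.ci95[1]:.2f}",
            })
        return pd.DataFrame(rows)


def compare_modalities(
    fnirs_features: pd.DataFrame,
    eeg_features: pd.DataFrame,
    labels: pd.Series,
    content: str = "all",
    svm: SVMConfig | None = None,
) -> ModalityReport:
    """Run leave-one-trial-out evaluation for fused, fNIRS-only and
    EEG-only matrices on one content type and tabulate accuracies and ROC
    summaries."""
    report = ModalityReport(content=content)
    acc_cols = {}
    for modality in ("fused", "fnirs", "eeg"):
        matrix = build_matrix(fnirs_features, eeg_features, labels, modality)
        folds = loto_cv(matrix, svm)
        obs = fold_observations(folds)
        report.observations[modality] = obs
        report.summaries[modality] = roc_summary(
            obs["score"].to_numpy(), obs["truth"].to_numpy())
        report.mean_accuracy[modality] = float(
            (obs["truth"] == obs["predicted"]).mean())
        acc_cols[modality] = pd.Series(
            {f.held_out_trial_id: f.accuracy for f in folds})
    report.per_trial_accuracy = pd.DataFrame(acc_cols).rename_axis("trial_id")
    return report
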