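"""End-to-end orchestration: simulate -> preprocess -> features ->
classify -> similarity -> report.

Each stage logs its parameters and row counts; a run with a fixed config
and seed writes byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg as eeg_mod
from . import face as face_mod
from . import fnirs as fnirs_mod
from . import fusion, io, similarity
from .config import PipelineConfig
from .signals import ParticipantData, RawEEGRecord, RawFNIRSRecord, StudyDataset
from .synthetic import generate_study

logger = logging.getLogger(__name__)


def fnirs_trial_features(
    record: RawFNIRSRecord,
    protocol: pd.DataFrame,
    config: PipelineConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial 96-feature table for one participant's fNIRS recording.

    Chain: MBLL conversion (reference window at recording start) ->
    0.1 Hz zero-phase low-pass -> HRF-guided ICA (optional) -> 5-s
    baseline subtraction -> summary statistics. Indexed by
    (participant_id, trial_id).
    """
    signals = fnirs_mod.mbll_convert(
        record, config.mbll, baseline_window=config.i0_window_seconds)
    signals = fnirs_mod.lowpass_fnirs(signals, config.fnirs_lowpass_hz)
    if config.use_ica:
        regressor = fnirs_mod.expected_response(
            protocol, signals.time.shape[0], record.rate, config.hrf)
        signals = fnirs_mod.ica_select_hemodynamic(signals, regressor, seed=seed)
    trials = fnirs_mod.baseline_adjust(signals, protocol, config.baseline_seconds)
    rows = {tid: fnirs_mod.extract_fnirs_features(t) for tid, t in trials.items()}
    frame = pd.DataFrame(rows).T
    pid = int(protocol["participant_id"].iloc[0])
    frame.index = pd.MultiIndex.from_product(
        [[pid], frame.index], names=["participant_id", "trial_id"])
    return frame


def eeg_trial_features(
    record: RawEEGRecord,
    protocol: pd.DataFrame,
    config: PipelineConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial 72-feature table for one participant's EEG recording.

    Chain: 30 Hz zero-phase low-pass -> ICA artifact rejection (optional)
    -> 5-s baseline subtraction -> Welch band log-PSD + frontal asymmetry.
    """
    record = eeg_mod.lowpass_eeg(record, config.eeg_lowpass_hz)
    if config.use_ica:
        record = eeg_mod.ica_clean_eeg(
            record, kurtosis_z=config.kurtosis_z,
            lowfreq_fraction=config.lowfreq_fraction, seed=seed)
    trials = eeg_mod.baseline_adjust_eeg(record, protocol, config.baseline_seconds)
    rows = {tid: eeg_mod.extract_eeg_features(t, config.bands)
            for tid, t in trials.items()}
    frame = pd.DataFrame(rows).T
    pid = int(protocol["participant_id"].iloc[0])
    frame.index = pd.MultiIndex.from_product(
        [[pid], frame.index], names=["participant_id", "trial_id"])
    return frame


@dataclass
class StudyFeatures:
    """All per-trial tables for one study, keyed by (participant, trial)."""

    fnirs: pd.DataFrame
    eeg: pd.DataFrame
    face_calls: pd.DataFrame
    protocol: pd.DataFrame

    def labels(self, content: str | None = None) -> pd.Series:
        proto = self.protocol
        if content is not None:
            proto = proto[proto["kind"] == content]
        return proto.set_index(["participant_id", "trial_id"])["valence"]


def extract_study_features(
    dataset: StudyDataset,
    config: PipelineConfig,
) -> StudyFeatures:
    """Run the three per-participant pipelines over a whole study."""
    fnirs_frames, eeg_frames, face_frames = [], [], []
    for part in dataset.participants:
        seed = config.seed * 1009 + part.participant_id
        logger.info("participant %d: extracting features", part.participant_id)
        fnirs_frames.append(
            fnirs_trial_features(part.fnirs, part.protocol, config, seed))
        eeg_frames.append(
            eeg_trial_features(part.eeg, part.protocol, config, seed))
        face_frames.append(face_mod.call_trials(
            part.face, part.protocol, config.face_calibration_seconds))
    return StudyFeatures(
        fnirs=pd.concat(fnirs_frames),
        eeg=pd.concat(eeg_frames),
        face_calls=pd.concat(face_frames, ignore_index=True),
        protocol=dataset.protocol,
    )


@dataclass
class PipelineReport:
    """Everything one run produces, before serialization."""

    features: StudyFeatures
    modality_reports: dict[str, fusion.ModalityReport]
    recognition: dict[str, pd.DataFrame]
    phi_tables: dict[str, pd.DataFrame]
    face_correlations: pd.DataFrame
    band_correlations: pd.DataFrame
    stimulus_classes: pd.DataFrame = field(default_factory=pd.DataFrame)


def _face_truth_table(features: StudyFeatures) -> pd.DataFrame:
    truth = features.protocol[["participant_id", "trial_id", "kind", "valence", "likert"]]
    return features.face_calls.merge(truth, on=["participant_id", "trial_id"]) \
        .rename(columns={"valence": "truth"})


def analyze_study(
    dataset: StudyDataset,
    config: PipelineConfig,
    contents: tuple[str, ...] = ("image", "video"),
) -> PipelineReport:
    """Full analysis on an in-memory study."""
    features = extract_study_features(dataset, config)
    calls = _face_truth_table(features)

    modality_reports: dict[str, fusion.ModalityReport] = {}
    recognition: dict[str, pd.DataFrame] = {}
    phi_tables: dict[str, pd.DataFrame] = {}
    stim_rows = []
    for content in contents:
        labels = features.labels(content)
        modality_reports[content] = fusion.compare_modalities(
            features.fnirs, features.eeg, labels, content, config.svm)

        sub = calls[calls["kind"] == content]
        per_trial = face_mod.recognition_rate(sub, by="trial")
        per_part = face_mod.recognition_rate(sub, by="participant")
        mean, sd = face_mod.rate_summary(per_trial)
        recognition[content] = pd.DataFrame({
            "unit": (["trial"] * len(per_trial)
                     + ["participant"] * len(per_part)),
            "unit_id": list(per_trial.index) + list(per_part.index),
            "rate": list(per_trial) + list(per_part),
            "mean_per_trial": mean,
            "sd_per_trial": sd,
        })

        brain = modality_reports[content].observations["fused"] \
            .rename(columns={"predicted": "label"})
        phi_tables[content] = similarity.per_participant_phi(
            sub[["participant_id", "trial_id", "label"]],
            brain[["participant_id", "trial_id", "label"]])

        for tid, group in sub.groupby("trial_id"):
            stim_rows.append({
                "content": content, "trial_id": tid,
                "classification": face_mod.classify_stimulus(group["label"]),
            })

    corr_rows = []
    for pid, group in calls.groupby("participant_id"):
        res = similarity.face_vs_groundtruth(
            group["signed_rating"].to_numpy(),
            np.where(group["truth"] == "positive", 1.0, -1.0))
        corr_rows.append({"participant_id": pid, "r": res.r,
                          "p_value": res.p_value, "n": res.n})

    band_corr = similarity.band_affect_correlation(
        features.eeg, features.labels(), config.bands)

    return PipelineReport(
        features=features,
        modality_reports=modality_reports,
        recognition=recognition,
        phi_tables=phi_tables,
        face_correlations=pd.DataFrame(corr_rows),
        band_correlations=band_corr,
        stimulus_classes=pd.DataFrame(stim_rows),
    )


def write_raw(dataset: StudyDataset, out: Path) -> None:
    raw = out / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    for part in dataset.participants:
        pid = part.participant_id
        io.write_protocol_csv(part.protocol, raw / f"p{pid:02d}_protocol.csv")
        io.write_fnirs_csv(part.fnirs, raw / f"p{pid:02d}_fnirs.csv")
        io.write_eeg_csv(part.eeg, raw / f"p{pid:02d}_eeg.csv")
        io.write_face_csv(part.face, raw / f"p{pid:02d}_face.csv")


def write_report(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.features.fnirs.to_csv(out / "features_fnirs.csv", float_format=fmt)
    report.features.eeg.to_csv(out / "features_eeg.csv", float_format=fmt)
    report.features.face_calls.to_csv(
        out / "affect_calls.csv", index=False, float_format=fmt)
    for content, mr in report.modality_reports.items():
        mr.table().to_csv(out / f"roc_summary_{content}.csv", index=False)
        mr.per_trial_accuracy.to_csv(
            out / f"per_trial_accuracy_{content}.csv", float_format=fmt)
        pd.concat(
            [obs.assign(modality=m) for m, obs in mr.observations.items()],
            ignore_index=True,
        ).to_csv(out / f"fold_predictions_{content}.csv", index=False, float_format=fmt)
    for content, table in report.recognition.items():
        table.to_csv(out / f"recognition_{content}.csv", float_format=fmt)
    for content, table in report.phi_tables.items():
        table.to_csv(out / f"phi_{content}.csv", index=False, float_format=fmt)
    report.face_correlations.to_csv(
        out / "face_vs_truth.csv", index=False, float_format=fmt)
    report.band_correlations.to_csv(
        out / "band_affect_correlation.csv", index=False, float_format=fmt)
    report.stimulus_classes.to_csv(
        out / "stimulus_classes.csv", index=False, float_format=fmt)


def run_pipeline(config: PipelineConfig, out: str | Path) -> PipelineReport:
    """Simulate a study, analyze it and write every stage output under
    ``out``. Deterministic for a fixed config (seed included)."""
    out = Path(out)
    study_config = config.study
    if study_config.seed != config.seed:
        study_config = dataclasses.replace(study_config, seed=config.seed)
    logger.info("simulating %d participants (seed %d)",
                study_config.n_participants, study_config.seed)
    dataset = generate_study(study_config)
    write_raw(dataset, out)
    report = analyze_study(dataset, config)
    write_report(report, out)
    logger.info("report written to %s", out)
    return report
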