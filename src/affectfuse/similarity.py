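"""Agreement statistics between face-decoded affect, brain-decoded affect,
self-report and ground truth.

The headline statistic is the phi coefficient — the Pearson correlation of
two binary label vectors, computed from their 2x2 contingency table — with
a chi-square p-value (n * phi^2, 1 d.f., no continuity correction; Fisher's
exact test available for small samples). Continuous facial affect ratings
are compared with ground truth / Likert self-report by Pearson correlation,
and channel-band log-powers with binary affect by point-biserial
correlation with Benjamini-Hochberg FDR control across the 56 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import BandDefinition, EEG_CHANNELS
from .signals import DataError


@dataclass(frozen=True)
class PhiResult:
    """Phi coefficient with its contingency table and p-value.

    ``defined`` is False when a marginal of the 2x2 table is zero (one of
    the vectors is constant), in which case phi and p are NaN.
    """

    phi: float
    p_value: float
    contingency: np.ndarray
    n: int
    defined: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


def phi_coefficient(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    method: str = "chi2",
) -> PhiResult:
    """Phi coefficient of two binary label vectors.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) on the 2x2 table
    [[a, b], [c, d]] whose rows index ``labels_a`` and columns
    ``labels_b`` (level order sorted). ``method="chi2"`` tests with the
    1-d.f. chi-square statistic n*phi^2; ``method="fisher"`` uses Fisher's
    exact test.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("label vectors must be equal-length 1-D arrays")
    if a.size < 2:
        raise DataError("need at least 2 paired labels")
    levels_a, levels_b = np.unique(a), np.unique(b)
    if len(levels_a) > 2 or len(levels_b) > 2:
        raise DataError("phi coefficient requires binary vectors")
    table = np.zeros((2, 2))
    for i, la in enumerate(levels_a[:2]):
        for j, lb in enumerate(levels_b[:2]):
            table[i, j] = np.sum((a == la) & (b == lb))
    margins = [table.sum(axis=1), table.sum(axis=0)]
    if any(m == 0 for pair in margins for m in pair):
        return PhiResult(phi=np.nan, p_value=np.nan, contingency=table,
                         n=a.size, defined=False)
    (ta, tb), (tc, td) = table
    phi = (ta * td - tb * tc) / np.sqrt(
        (ta + tb) * (tc + td) * (ta + tc) * (tb + td))
    if method == "chi2":
        p = float(stats.chi2.sf(a.size * phi**2, df=1))
    elif method == "fisher":
        p = float(stats.fisher_exact(table)[1])
    else:
        raise ValueError("method must be 'chi2' or 'fisher'")
    return PhiResult(phi=float(phi), p_value=p, contingency=table, n=a.size)


def face_vs_groundtruth(
    ratings: np.ndarray,
    targets: np.ndarray,
) -> CorrelationResult:
    """Pearson correlation of continuous facial affect ratings (signed,
    p_pos - p_neg) against ground-truth or Likert values, two-sided p."""
    x = np.asarray(ratings, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("rating and target vectors must be equal-length 1-D")
    if x.size < 3:
        raise DataError("need n >= 3 for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=np.nan, p_value=np.nan, n=x.size, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=x.size)


def per_participant_phi(
    face_calls: pd.DataFrame,
    brain_calls: pd.DataFrame,
    method: str = "chi2",
) -> pd.DataFrame:
    """Phi between face-decoded and brain-decoded affect per participant.

    Both tables need ``participant_id, trial_id`` keys and a ``label``
    column; undefined face calls are excluded pairwise. Returns one row
    per participant: participant_id, phi, p_value, n, defined.
    """
    merged = face_calls.merge(
        brain_calls, on=["participant_id", "trial_id"], suffixes=("_face", "_brain"))
    merged = merged[merged["label_face"].isin(["positive", "negative"])
                    & merged["label_brain"].isin(["positive", "negative"])]
    rows = []
    for pid, group in merged.groupby("participant_id"):
        res = phi_coefficient(group["label_face"].to_numpy(),
                              group["label_brain"].to_numpy(), method=method)
        rows.append({"participant_id": pid, "phi": res.phi,
                     "p_value": res.p_value, "n": res.n, "defined": res.defined})
    return pd.DataFrame(rows)


def band_affect_correlation(
    eeg_features: pd.DataFrame,
    labels: pd.Series,
    bands: BandDefinition | None = None,
) -> pd.DataFrame:
    """Point-biserial correlation of each channel-band log-power feature
    with the binary affect label.

    Returns 56 rows (14 channels x 4 bands) ranked by |r|, with raw
    two-sided p-values and Benjamini-Hochberg FDR q-values; constant
    features are flagged undefined and rank last.
    """
    bands = bands or BandDefinition()
    y = labels.loc[eeg_features.index].map({"negative": 0, "positive": 1})
    if y.isna().any():
        raise DataError("labels must be positive/negative for every feature row")
    rows = []
    for ch in EEG_CHANNELS:
        for band in bands.names:
            col = f"{ch}_{band}_logpsd"
            if col not in eeg_features.columns:
                raise DataError(f"feature column {col} missing")
            x = eeg_features[col].to_numpy(dtype=float)
            if np.std(x) == 0 or y.nunique() < 2:
                rows.append({"channel": ch, "band": band, "r": np.nan,
                             "p_value": np.nan, "defined": False})
                continue
            r, p = stats.pointbiserialr(y.to_numpy(), x)
            rows.append({"channel": ch, "band": band, "r": float(r),
                         "p_value": float(p), "defined": True})
    table = pd.DataFrame(rows)
    defined = table["defined"]
    q = np.full(len(table), np.nan)
    if defined.any():
        q[defined.to_numpy()] = _bh_fdr(table.loc[defined, "p_value"].to_numpy())
    table["q_value"] = q
    table["abs_r"] = table["r"].abs()
    table = table.sort_values("abs_r", ascending=False, na_position="last")
    return table.drop(columns="abs_r").reset_index(drop=True)


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
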