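"""Group comparison and cognitive-score prediction.

Group differences use the Mann-Whitney U rank-sum test in its normal
approximation with tie-corrected variance and continuity correction,
reporting a signed z (positive when the first sample tends larger) and a
two-sided p.  Score prediction is ordinary multiple linear regression under
leave-one-subject-out (LOSO) cross-validation: for each fold, features are
min-max scaled to [0, 1] using the training fold only (the held-out value is
clipped), the model is fit on the training fold, and the held-out subject is
predicted; R-squared, MSE, RMSE and MAE are computed on the pooled held-out
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (AssemblyError, DegenerateInputError, MicrodynError,
                     ParameterError)
from .microstate import LabelSequence, microstate_stats
from .sequence import mslzc, msnri, to_transition_sequence

FEATURE_M_VALUES = (4, 5, 6, 7, 8)
META_COLUMNS = ("subject_id", "group", "score")


def mann_whitney_z(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, normal approximation.

    Returns ``(z, p_two_sided)``.  z is positive when ``x`` tends to be
    larger than ``y``.  Raises if every value across both samples is tied
    (zero variance).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise DegenerateInputError("all values tied; rank variance is zero")
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward zero
    z = (diff - cc) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """R-squared, MSE, RMSE and MAE between observed and predicted scores."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ParameterError("y_true and y_pred must be equal nonzero length")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("zero variance in y_true; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    mse = ss_res / y_true.size
    return {"r2": 1.0 - ss_res / ss_tot, "mse": mse,
            "rmse": float(np.sqrt(mse)),
            "mae": float(np.mean(np.abs(y_true - y_pred)))}


@dataclass
class PredictionResult:
    """Pooled LOSO predictions and their agreement metrics."""

    predictions: pd.Series  # indexed by subject_id
    metrics: dict[str, float]


def loso_predict(table: pd.DataFrame) -> PredictionResult:
    """Leave-one-subject-out linear prediction of the ``score`` column.

    ``table`` must carry ``subject_id``, ``group``, ``score`` and one column
    per feature.  Per fold, features are min-max scaled on the training
    subjects only; the regression is solved by least squares (minimum-norm
    when rank-deficient, with a warning).
    """
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise ParameterError("no feature columns in table")
    if len(table) < 3:
        raise ParameterError("need at least 3 subjects for LOSO")
    if table[feature_cols].isna().any().any():
        raise AssemblyError("feature table contains missing values")
    x_all = table[feature_cols].to_numpy(float)
    y_all = table["score"].to_numpy(float)
    n = len(table)
    if len(feature_cols) + 1 > n - 1:
        warnings.warn(
            f"{len(feature_cols)} features exceed the {n - 1}-subject "
            "training folds; using minimum-norm least squares",
            RuntimeWarning, stacklevel=2)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        x_tr, y_tr = x_all[mask], y_all[mask]
        lo = x_tr.min(axis=0)
        span = x_tr.max(axis=0) - lo
        span[span == 0] = 1.0
        xs_tr = (x_tr - lo) / span
        xs_te = np.clip((x_all[i] - lo) / span, 0.0, 1.0)
        a = np.column_stack([np.ones(len(xs_tr)), xs_tr])
        coef, *_ = np.linalg.lstsq(a, y_tr, rcond=None)
        preds[i] = coef[0] + xs_te @ coef[1:]
    metrics = regression_metrics(y_all, preds)
    return PredictionResult(
        predictions=pd.Series(preds, index=table["subject_id"].to_numpy()),
        metrics=metrics)


@dataclass
class SubjectScales:
    """One subject's per-scale label sequences, ready for feature assembly.

    ``label_seqs`` maps a scale name (``"broadband"``, ``"IMF2"``, ...) to
    the backfitted, smoothed :class:`LabelSequence` at that scale.
    """

    subject_id: str
    group: str
    score: float
    label_seqs: dict[str, LabelSequence]


def _scale_features(subject_id: str, scale: str, seq: LabelSequence,
                    k: int, m_values, n_surrogates: int,
                    seed: int) -> dict[str, float]:
    feats: dict[str, float] = {}
    try:
        ts = to_transition_sequence(seq)
        for j, m in enumerate(m_values):
            feats[f"{scale}_msnri_m{m}"] = msnri(ts, m=m,
                                                 n_surrogates=n_surrogates,
                                                 seed=seed + j)
        feats[f"{scale}_mslzc"] = mslzc(ts)
    except AssemblyError:
        raise
    except MicrodynError as exc:
        raise AssemblyError(
            f"subject {subject_id}, scale {scale}: {exc}") from exc
    stats_df = microstate_stats(seq, k=k)
    for cls, row in stats_df.iterrows():
        for metric in ("duration_ms", "occurrence_per_s", "coverage"):
            val = row[metric]
            if not np.isfinite(val):
                raise AssemblyError(
                    f"subject {subject_id}: feature "
                    f"{scale}_{cls}_{metric} is missing (class {cls} never "
                    f"occurs at scale {scale})")
            feats[f"{scale}_{cls}_{metric}"] = float(val)
    return feats


def assemble_features(subjects: list[SubjectScales], k: int = 4,
                      variant: str = "ceemd",
                      m_values=FEATURE_M_VALUES,
                      n_surrogates: int = 20, seed: int = 0) -> pd.DataFrame:
    """Build the subjects x features table for group stats and prediction.

    ``variant="baseline"`` uses broadband features only; ``"ceemd"`` adds
    every IMF scale present in the subjects' ``label_seqs``.  Column order is
    deterministic: scales in broadband-then-IMF order, and per scale the
    MSNRI values for each m, MSLZC, then per-class duration/occurrence/
    coverage.
    """
    if variant not in ("baseline", "ceemd"):
        raise ParameterError(f"unknown variant {variant!r}")
    if not subjects:
        raise ParameterError("no subjects supplied")
    scale_names = list(subjects[0].label_seqs)
    if variant == "baseline":
        scale_names = [s for s in scale_names if s == "broadband"]
        if not scale_names:
            raise AssemblyError("baseline variant requires a 'broadband' "
                                "scale on every subject")
    rows = []
    for idx, sub in enumerate(subjects):
        row: dict[str, object] = {"subject_id": sub.subject_id,
                                  "group": sub.group, "score": sub.score}
        for scale in scale_names:
            if scale not in sub.label_seqs:
                raise AssemblyError(
                    f"subject {sub.subject_id}: missing scale {scale}")
            row.update(_scale_features(sub.subject_id, scale,
                                       sub.label_seqs[scale], k, m_values,
                                       n_surrogates,
                                       seed + 1000 * idx))
        rows.append(row)
    return pd.DataFrame(rows)
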