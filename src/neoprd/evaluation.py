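"""Performance statistics: AUC with per-infant bootstrap CIs, threshold
metrics, per-feature discrimination, the grand-average event curve, and
Fisher's exact test.

An AUC is flagged significant when both the point estimate and the lower
bootstrap confidence bound exceed 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import rankdata

from .modelling import InfantPrediction

__all__ = [
    "CohortEvaluation",
    "auc",
    "bootstrap_auc_ci",
    "confusion_metrics",
    "evaluate_predictions",
    "per_feature_auc",
    "grand_average_prd",
    "fisher_exact",
]


@dataclass
class CohortEvaluation:
    model_name: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    n_boot: int
    decision_threshold: float
    significant: bool


def _scores_labels(predictions) -> tuple[np.ndarray, np.ndarray]:
    if predictions and isinstance(predictions[0], InfantPrediction):
        scores = np.array([p.probability for p in predictions], dtype=float)
        labels = np.array([p.label for p in predictions], dtype=int)
    else:
        scores, labels = predictions
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
    return scores, labels


def auc(predictions) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Accepts a list of :class:`InfantPrediction` or a ``(scores, labels)``
    pair. Requires both classes.
    """
    scores, labels = _scores_labels(predictions)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)            # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(
    predictions,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraw_factor: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling infants with
    replacement. Single-class resamples are discarded and redrawn (the
    count is logged); an error is raised if the redraw budget runs out.
    """
    scores, labels = _scores_labels(predictions)
    if len(np.unique(labels)) < 2:
        raise ValueError("bootstrap CI undefined: only one class present")
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(n_boot)
    discarded = 0
    budget = max_redraw_factor * n_boot
    i = 0
    while i < n_boot:
        if discarded + i >= budget:
            raise RuntimeError("bootstrap infeasible: too many single-class resamples")
        idx = rng.integers(0, n, n)
        lab = labels[idx]
        if lab.min() == lab.max():
            discarded += 1
            continue
        aucs[i] = auc((scores[idx], lab))
        i += 1
    if discarded:
        warnings.warn(f"{discarded} single-class bootstrap resamples discarded and redrawn")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def confusion_metrics(predictions, threshold: float = 0.4) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, MCC) at the probability
    threshold; predictions >= threshold count as positive calls. A zero
    MCC denominator yields 0 with a warning."""
    scores, labels = _scores_labels(predictions)
    if len(np.unique(labels)) < 2:
        raise ValueError("confusion metrics undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator zero; reporting 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return float(sens), float(spec), float(acc), float(mcc)


def evaluate_predictions(
    predictions,
    model_name: str,
    n_boot: int = 1000,
    level: float = 0.95,
    threshold: float = 0.4,
    seed: int = 0,
    with_confusion: bool = True,
) -> CohortEvaluation:
    """Full evaluation of one model's per-infant predictions."""
    a = auc(predictions)
    lo, hi = bootstrap_auc_ci(predictions, n_boot=n_boot, level=level, seed=seed)
    if with_confusion:
        sens, spec, acc, mcc = confusion_metrics(predictions, threshold)
    else:
        sens = spec = acc = mcc = np.nan
    return CohortEvaluation(
        model_name=model_name,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        mcc=mcc,
        n_boot=n_boot,
        decision_threshold=threshold,
        significant=bool(a > 0.5 and lo > 0.5),
    )


def per_feature_auc(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Discrimination of each feature on its own: AUC + bootstrap CI.

    ``feature_table`` has one row per infant (indexed by infant id). The
    AUC is computed on the raw feature value — orientation is *not*
    corrected, so values below 0.5 indicate an inverted direction.
    All-missing features are emitted with missing AUC.
    """
    rows = []
    lab_all = labels.loc[feature_table.index]
    for j, col in enumerate(feature_table.columns):
        vals = feature_table[col]
        ok = vals.notna()
        if ok.sum() == 0 or lab_all[ok].nunique() < 2:
            rows.append({"feature": col, "auc": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        pair = (vals[ok].to_numpy(dtype=float), lab_all[ok].to_numpy(dtype=int))
        a = auc(pair)
        lo, hi = bootstrap_auc_ci(pair, n_boot=n_boot, level=level, seed=seed + j)
        rows.append({"feature": col, "auc": a, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def grand_average_prd(
    events_by_infant: dict,
    signals_by_infant: dict,
    labels: pd.Series,
    window_min: float = 20.0,
    grid_step_s: float = 6.0,
) -> pd.DataFrame:
    """Grand-average desaturation curve per outcome group.

    Every event contributes the original-signal excursion relative to its
    baseline, aligned at the nadir and interpolated onto a common
    relative-time grid spanning ``±window_min`` minutes; samples outside
    the event's own span count as zero (back at baseline). Curves are
    averaged within each label group. Returns columns
    ``relative_time_min, mean_injury, mean_nomild`` (a group with no
    events is omitted with a warning).
    """
    rel = np.arange(-window_min * 60.0, window_min * 60.0 + grid_step_s, grid_step_s)
    curves: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for iid, events in events_by_infant.items():
        sig = signals_by_infant[iid]
        lab = int(labels[iid])
        t = sig.times
        for ev in events:
            inside = (t >= ev.onset_time) & (t <= ev.offset_time)
            if inside.sum() < 2:
                continue
            exc = np.zeros(len(rel))
            src_t = t[inside] - ev.nadir_time
            src_v = sig.values[inside] - ev.baseline_level
            exc = np.interp(rel, src_t, src_v, left=0.0, right=0.0)
            # outside the event span the excursion is zero by definition
            exc[(rel < src_t[0]) | (rel > src_t[-1])] = 0.0
            curves[lab].append(exc)
    out = {"relative_time_min": rel / 60.0}
    for lab, name in ((1, "mean_injury"), (0, "mean_nomild")):
        if curves[lab]:
            out[name] = np.mean(curves[lab], axis=0)
        else:
            warnings.warn(f"no events in group {name}; curve omitted")
    return pd.DataFrame(out)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table (the sum of
    hypergeometric probabilities no larger than the observed table's)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if (table < 0).any() or not np.allclose(table, np.round(table)):
            raise ValueError("counts must be nonnegative integers")
        table = table.astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1")
        return 1.0
    return float(_scipy_fisher(table, alternative="two-sided").pvalue)
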