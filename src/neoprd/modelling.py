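"""Tree-ensemble classifiers under leave-one-infant-out cross-validation.

Signal models are gradient-boosted trees (depth 3, 50 trees, learning
rate 0.1) on per-epoch or per-recording feature rows; the clinical model
is a 500-tree random forest on one row per infant. In every fold all rows
of the held-out infant are removed from training, the model predicts that
infant's rows, and the per-row probabilities are aggregated (mean by
default) to a single per-infant probability. Signal and clinical models
are combined late-stage by the geometric mean of their probabilities.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "InfantPrediction",
    "loso_cv",
    "aggregate_epoch_probabilities",
    "fuse_geometric",
    "predictions_frame",
]


@dataclass
class ModelConfig:
    """Hyperparameters; the stated values are the fixed study settings."""

    model_kind: str = "gbt"          # "gbt" (XGBoost) or "rf" (random forest)
    gbt_max_depth: int = 3
    gbt_n_trees: int = 50
    gbt_learning_rate: float = 0.1
    use_scale_pos_weight: bool = False   # per-fold n_neg/n_pos reweighting
    rf_n_trees: int = 500
    aggregate: str = "mean"          # per-infant aggregation of row probabilities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("gbt", "rf"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown aggregation {self.aggregate!r}")


@dataclass
class InfantPrediction:
    infant_id: str
    probability: float
    label: int
    n_epochs_used: int


def _fold_seed(seed: int, infant_id: str) -> int:
    return (seed + zlib.crc32(infant_id.encode())) % (2**31 - 1)


def _make_model(cfg: ModelConfig, fold_seed: int, scale_pos_weight: float | None):
    if cfg.model_kind == "gbt":
        return XGBClassifier(
            max_depth=cfg.gbt_max_depth,
            n_estimators=cfg.gbt_n_trees,
            learning_rate=cfg.gbt_learning_rate,
            scale_pos_weight=scale_pos_weight if scale_pos_weight is not None else 1.0,
            tree_method="hist",
            n_jobs=1,
            random_state=fold_seed,
            eval_metric="logloss",
        )
    return RandomForestClassifier(
        n_estimators=cfg.rf_n_trees,
        random_state=fold_seed,
        n_jobs=1,
    )


def aggregate_epoch_probabilities(probs: np.ndarray, method: str = "mean") -> float:
    """Collapse per-row probabilities of one infant to a single probability."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) == 0:
        raise ValueError("no probabilities to aggregate")
    return float(np.median(probs) if method == "median" else probs.mean())


def fuse_geometric(p_signal, p_clinical):
    """Late-stage fusion: geometric mean of two probabilities."""
    return np.sqrt(np.asarray(p_signal, dtype=float) * np.asarray(p_clinical, dtype=float))


def loso_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    cfg: ModelConfig | None = None,
    return_audit: bool = False,
):
    """Leave-one-infant-out cross-validation.

    ``features`` holds one row per epoch (or per infant) with an
    ``infant_id`` column plus feature columns; ``labels`` maps infant_id
    to the binary outcome. Every fold drops all rows of the held-out
    infant from training, fits a fresh model, predicts the held-out rows
    and aggregates them to one probability.

    Returns a list of :class:`InfantPrediction` (one per infant with
    usable rows); with ``return_audit=True`` also a dict mapping each
    held-out infant to the sorted set of infant ids its training table
    contained.
    """
    cfg = cfg or ModelConfig()
    if "infant_id" not in features.columns:
        raise ValueError("features must carry an infant_id column")
    feat_cols = [c for c in features.columns
                 if c not in ("infant_id", "epoch_index", "epoch_start_age_h")]
    infants = list(labels.index)
    if len(infants) < 2:
        raise ValueError("need at least 2 infants")
    if labels.nunique() < 2:
        raise ValueError("both outcome classes must be present")

    usable = features.dropna(how="all", subset=feat_cols)
    predictions: list[InfantPrediction] = []
    audit: dict[str, list[str]] = {}
    for held in infants:
        test_rows = usable[usable["infant_id"] == held]
        if len(test_rows) == 0:
            logger.warning("infant %s has no usable feature rows; excluded", held)
            continue
        train_rows = usable[usable["infant_id"] != held]
        train_labels = train_rows["infant_id"].map(labels)
        if train_labels.nunique() < 2:
            raise ValueError(
                f"training fold for infant {held} contains a single outcome class"
            )
        spw = None
        if cfg.use_scale_pos_weight:
            n_pos = int((train_labels == 1).sum())
            n_neg = int((train_labels == 0).sum())
            spw = n_neg / n_pos
        model = _make_model(cfg, _fold_seed(cfg.seed, str(held)), spw)
        X = train_rows[feat_cols].to_numpy(dtype=float)
        if cfg.model_kind == "rf" and np.isnan(X).any():
            raise ValueError("random forest cannot handle missing feature values")
        model.fit(X, train_labels.to_numpy(dtype=int))
        probs = model.predict_proba(test_rows[feat_cols].to_numpy(dtype=float))[:, 1]
        predictions.append(
            InfantPrediction(
                infant_id=str(held),
                probability=aggregate_epoch_probabilities(probs, cfg.aggregate),
                label=int(labels[held]),
                n_epochs_used=len(test_rows),
            )
        )
        audit[str(held)] = sorted(train_rows["infant_id"].unique())
    if return_audit:
        return predictions, audit
    return predictions


def predictions_frame(preds: list[InfantPrediction], model_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "infant_id": p.infant_id,
                "model_name": model_name,
                "probability": p.probability,
                "label": p.label,
            }
            for p in preds
        ]
    )


def feature_importance(
    features: pd.DataFrame, labels: pd.Series, cfg: ModelConfig | None = None
) -> pd.Series:
    """Gain-based importance of a model fit on the full cohort (no CV);
    exported for inspection only, never used for evaluation."""
    cfg = cfg or ModelConfig()
    feat_cols = [c for c in features.columns
                 if c not in ("infant_id", "epoch_index", "epoch_start_age_h")]
    y = features["infant_id"].map(labels).to_numpy(dtype=int)
    model = _make_model(cfg, cfg.seed, None)
    model.fit(features[feat_cols].to_numpy(dtype=float), y)
    if cfg.model_kind == "gbt":
        booster = model.get_booster()
        gain = booster.get_score(importance_type="gain")
        imp = pd.Series({feat_cols[int(k[1:])]: v for k, v in gain.items()})
    else:
        imp = pd.Series(model.feature_importances_, index=feat_cols)
    return imp.sort_values(ascending=False)
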