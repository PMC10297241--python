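"""End-to-end orchestration: cohort -> preprocessing -> decomposition ->
features -> leave-one-infant-out models -> evaluation tables.

The model battery mirrors the study design: a clinical random forest,
gradient-boosted-tree models on the 66-feature epoch matrices of the raw
signal and of the desaturation-free residual, a gradient-boosted-tree
model on the 14-feature PRD descriptor, geometric-mean fusions of each
signal model with the clinical model, the same family for SpO2 (with
per-fold class reweighting), and time-below-threshold comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .epoch_features import EpochSpec, FilterBankSpec, extract_epoch_features
from .evaluation import (CohortEvaluation, auc, bootstrap_auc_ci,
                         evaluate_predictions, fisher_exact, grand_average_prd,
                         per_feature_auc)
from .modelling import (InfantPrediction, ModelConfig, fuse_geometric,
                        loso_cv, predictions_frame)
from .prd import SSAConfig, extract_prd_component, segment_events
from .prd_features import PRD_FEATURE_NAMES, compute_prd_features
from .preprocess import preprocess_channel
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["ChannelResult", "process_channel", "prd_feature_table",
           "epoch_feature_table", "run_signal_model", "evaluate_cohort"]


@dataclass
class ChannelResult:
    """Everything the pipeline derives from one raw channel."""

    signal: object               # UniformSignal
    decomposition: object        # PRDDecomposition
    events: list
    prd_features: pd.Series


def process_channel(raw, cfg: PipelineConfig | None = None,
                    ssa_cfg: SSAConfig | None = None) -> ChannelResult:
    """Preprocess one channel, extract its PRD component and events, and
    compute the 14-feature descriptor."""
    cfg = cfg or PipelineConfig()
    ssa_cfg = ssa_cfg or SSAConfig()
    sig = preprocess_channel(raw, cfg)
    dec = extract_prd_component(sig, ssa_cfg)
    events = segment_events(dec, detect_threshold=cfg.detect_threshold)
    thr = cfg.rcso2_threshold if raw.channel == "rcSO2" else cfg.spo2_threshold
    feats = compute_prd_features(events, dec, thr).as_series()
    return ChannelResult(signal=sig, decomposition=dec, events=events,
                         prd_features=feats)


def _channel_results(cohort: SyntheticCohort, channel: str,
                     cfg: PipelineConfig, ssa_cfg: SSAConfig) -> dict:
    out = {}
    for iid, channels in cohort.recordings.items():
        if channel in channels:
            out[iid] = process_channel(channels[channel], cfg, ssa_cfg)
    return out


def prd_feature_table(results: dict) -> pd.DataFrame:
    """One row per infant with the 14 PRD features plus ``infant_id``."""
    rows = []
    for iid, res in results.items():
        row = {"infant_id": iid}
        row.update(res.prd_features.to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["infant_id"] + PRD_FEATURE_NAMES)


def epoch_feature_table(results: dict, cfg: PipelineConfig,
                        use_residual: bool = False) -> pd.DataFrame:
    """Stacked 66-feature epoch matrices of all infants (original signal
    or desaturation-free residual)."""
    espec = EpochSpec(epoch_hours=cfg.epoch_hours, overlap=cfg.overlap,
                      min_valid_fraction=cfg.min_valid_fraction)
    frames = []
    for iid, res in results.items():
        values = res.decomposition.residual if use_residual else None
        try:
            frames.append(extract_epoch_features(res.signal, espec,
                                                 values=values))
        except ValueError as exc:
            logger.warning("infant %s: %s", iid, exc)
    return pd.concat(frames, ignore_index=True)


def run_signal_model(features: pd.DataFrame, labels: pd.Series,
                     cfg: PipelineConfig, use_scale_pos_weight: bool = False):
    mc = ModelConfig(model_kind="gbt", seed=cfg.seed,
                     use_scale_pos_weight=use_scale_pos_weight)
    present = labels.loc[labels.index.intersection(features["infant_id"].unique())]
    return loso_cv(features, present, mc)


def _fused(signal_preds: list, clinical_preds: list) -> list:
    clin = {p.infant_id: p.probability for p in clinical_preds}
    fused = []
    for p in signal_preds:
        if p.infant_id not in clin:
            continue
        fused.append(InfantPrediction(
            infant_id=p.infant_id,
            probability=float(fuse_geometric(p.probability, clin[p.infant_id])),
            label=p.label,
            n_epochs_used=p.n_epochs_used,
        ))
    return fused


def evaluate_cohort(
    cohort: SyntheticCohort,
    cfg: PipelineConfig | None = None,
    ssa_cfg: SSAConfig | None = None,
    with_epoch_models: bool = True,
    with_spo2: bool = True,
) -> dict:
    """Run the full model battery on a cohort.

    Returns a dict with ``results`` (per-model AUC/CI/metrics table),
    ``predictions`` (per-infant probabilities of every model),
    ``per_feature`` (per-PRD-feature AUC table, rcSO2),
    ``grand_average`` (mean event curves per group) and ``fisher_p``
    (sampling dialect vs outcome).
    """
    cfg = cfg or PipelineConfig()
    ssa_cfg = ssa_cfg or SSAConfig()
    labels = cohort.labels

    rc = _channel_results(cohort, "rcSO2", cfg, ssa_cfg)
    evaluations: list[CohortEvaluation] = []
    all_preds: list[pd.DataFrame] = []
    preds: dict[str, list] = {}

    # clinical random forest (one row per infant)
    clin_feats = cohort.clinical.reset_index().rename(columns={"index": "infant_id"})
    preds["clinical"] = loso_cv(clin_feats, labels,
                                ModelConfig(model_kind="rf", seed=cfg.seed))

    # rcSO2 PRD-descriptor model
    rc_prd = prd_feature_table(rc)
    preds["rcso2_prd"] = run_signal_model(rc_prd, labels, cfg)
    preds["rcso2_prd_and_clinical"] = _fused(preds["rcso2_prd"], preds["clinical"])

    if with_epoch_models:
        rc_epochs = epoch_feature_table(rc, cfg, use_residual=False)
        rc_epochs_resid = epoch_feature_table(rc, cfg, use_residual=True)
        preds["rcso2"] = run_signal_model(rc_epochs, labels, cfg)
        preds["rcso2_no_prd"] = run_signal_model(rc_epochs_resid, labels, cfg)
        preds["rcso2_and_clinical"] = _fused(preds["rcso2"], preds["clinical"])
        preds["rcso2_no_prd_and_clinical"] = _fused(preds["rcso2_no_prd"], preds["clinical"])

    sp = {}
    if with_spo2:
        sp = _channel_results(cohort, "SpO2", cfg, ssa_cfg)
        sp_labels = labels.loc[[i for i in labels.index if i in sp]]
        if len(sp) >= 2 and sp_labels.nunique() == 2 and sp_labels.value_counts().min() >= 2:
            sp_prd = prd_feature_table(sp)
            preds["spo2_prd"] = run_signal_model(sp_prd, sp_labels, cfg,
                                                 use_scale_pos_weight=True)
            preds["spo2_prd_and_clinical"] = _fused(preds["spo2_prd"], preds["clinical"])
            if with_epoch_models:
                sp_epochs = epoch_feature_table(sp, cfg, use_residual=False)
                sp_epochs_resid = epoch_feature_table(sp, cfg, use_residual=True)
                preds["spo2"] = run_signal_model(sp_epochs, sp_labels, cfg,
                                                 use_scale_pos_weight=True)
                preds["spo2_no_prd"] = run_signal_model(sp_epochs_resid, sp_labels, cfg,
                                                        use_scale_pos_weight=True)
                preds["spo2_and_clinical"] = _fused(preds["spo2"], preds["clinical"])
                preds["spo2_no_prd_and_clinical"] = _fused(preds["spo2_no_prd"],
                                                           preds["clinical"])
        else:
            logger.warning("SpO2 subset lacks 2 infants of each outcome class; "
                           "SpO2 models skipped")

    for name, plist in preds.items():
        evaluations.append(
            evaluate_predictions(plist, name, n_boot=cfg.n_boot,
                                 level=cfg.ci_level,
                                 threshold=cfg.decision_threshold,
                                 seed=cfg.seed)
        )
        all_preds.append(predictions_frame(plist, name))

    # time-below-threshold comparators: the feature value is the score
    for name, results, thr_name in (
        ("rcso2_time_below_63", rc, "rcSO2"),
        ("spo2_time_below_85", sp, "SpO2"),
    ):
        if not results:
            continue
        iids = list(results.keys())
        lab = labels.loc[iids]
        if lab.nunique() < 2:
            continue
        scores = np.array([results[i].prd_features["time_below_threshold"]
                           for i in iids])
        pair = (scores, lab.to_numpy(dtype=int))
        a = auc(pair)
        lo, hi = bootstrap_auc_ci(pair, n_boot=cfg.n_boot, level=cfg.ci_level,
                                  seed=cfg.seed)
        evaluations.append(CohortEvaluation(
            model_name=name, auc=a, ci_low=lo, ci_high=hi,
            sensitivity=np.nan, specificity=np.nan, accuracy=np.nan,
            mcc=np.nan, n_boot=cfg.n_boot,
            decision_threshold=np.nan,
            significant=bool(a > 0.5 and lo > 0.5),
        ))

    results_df = pd.DataFrame([vars(e) for e in evaluations])

    rc_feature_table = prd_feature_table(rc).set_index("infant_id")
    per_feat = per_feature_auc(rc_feature_table, labels, n_boot=cfg.n_boot,
                               level=cfg.ci_level, seed=cfg.seed)

    ga = grand_average_prd(
        {i: r.events for i, r in rc.items()},
        {i: r.signal for i, r in rc.items()},
        labels,
    )

    dialects = pd.Series({i: cohort.recordings[i]["rcSO2"].dialect
                          for i in labels.index})
    tab = pd.crosstab(dialects == "external", labels).reindex(
        index=[False, True], columns=[0, 1], fill_value=0).to_numpy()
    fisher_p = fisher_exact(tab)

    return {
        "results": results_df,
        "predictions": pd.concat(all_preds, ignore_index=True) if all_preds else pd.DataFrame(),
        "per_feature": per_feat,
        "grand_average": ga,
        "fisher_p": fisher_p,
        "channel_results": {"rcSO2": rc, "SpO2": sp},
    }
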