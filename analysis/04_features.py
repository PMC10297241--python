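#!/usr/bin/env python
"""Compute the feature sets.

Per channel: the 66-feature 4-h-epoch matrices of the raw signal and of
the desaturation-free residual, and the 14-feature PRD descriptor per
recording. Tables go to scratch/derived; a compact group comparison of
the rcSO2 PRD descriptor goes to results/.
"""

from pathlib import Path

import pandas as pd

from neoprd.config import PipelineConfig
from neoprd.io import read_cohort
from neoprd.pipeline import (_channel_results, epoch_feature_table,
                             prd_feature_table)
from neoprd.prd import SSAConfig
from neoprd.prd_features import PRD_FEATURE_NAMES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort" / "manifest.csv")
    cfg = PipelineConfig(seed=7)
    out = ROOT / "scratch" / "derived"
    for channel in ("rcSO2", "SpO2"):
        results = _channel_results(cohort, channel, cfg, SSAConfig())
        if not results:
            continue
        key = channel.lower()
        prd_tab = prd_feature_table(results)
        prd_tab.to_csv(out / f"{key}_prd_features.csv", index=False)
        epoch_feature_table(results, cfg).to_csv(
            out / f"{key}_epoch_features.csv", index=False)
        epoch_feature_table(results, cfg, use_residual=True).to_csv(
            out / f"{key}_epoch_features_residual.csv", index=False)
        if channel == "rcSO2":
            tab = prd_tab.set_index("infant_id")
            tab["label"] = cohort.labels
            comp = tab.groupby("label")[PRD_FEATURE_NAMES].mean().T.round(3)
            comp.columns = ["no_mild_mean", "injury_mean"]
            comp.to_csv(ROOT / "results" / "rcso2_prd_feature_group_means.csv")
            print("rcSO2 PRD descriptor, group means:")
            print(comp)
    print(f"feature tables -> {out}")


if __name__ == "__main__":
    main()
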