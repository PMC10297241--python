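"""AUC, bootstrap CIs, threshold metrics, per-feature discrimination,
grand-average curves and Fisher's exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoprd.evaluation import (auc, bootstrap_auc_ci, confusion_metrics,
                               evaluate_predictions, fisher_exact,
                               grand_average_prd, per_feature_auc)
from neoprd.modelling import InfantPrediction
from neoprd.prd import PRDEvent

from conftest import make_uniform

FS = 1.0 / 6.0


class TestAUC:
    def test_perfect_separation(self):
        assert auc((np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))) == 1.0

    def test_all_ties(self):
        assert auc((np.full(10, 0.5), np.array([1] * 4 + [0] * 6))) == 0.5

    def test_pairwise_example(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: 3 wins, 1 loss of 4 pairs
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc((scores, labels)) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            auc((np.array([0.1, 0.2]), np.array([1, 1])))

    def test_accepts_infant_predictions(self):
        preds = [InfantPrediction("a", 0.9, 1, 3), InfantPrediction("b", 0.2, 0, 3)]
        assert auc(preds) == 1.0


class TestBootstrap:
    def test_perfect_cohort_upper_bound_is_one(self):
        scores = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
        labels = np.array([1] * 10 + [0] * 10)
        lo, hi = bootstrap_auc_ci((scores, labels), n_boot=200, seed=1)
        assert hi == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(2)
        pair = (rng.uniform(0, 1, 30), rng.integers(0, 2, 30))
        assert bootstrap_auc_ci(pair, seed=5) == bootstrap_auc_ci(pair, seed=5)

    def test_monte_carlo_stability(self):
        rng = np.random.default_rng(3)
        labels = np.array([1] * 12 + [0] * 34)
        scores = rng.uniform(0, 1, 46) + 0.3 * labels
        a = bootstrap_auc_ci((scores, labels), n_boot=1000, seed=7)
        b = bootstrap_auc_ci((scores, labels), n_boot=2000, seed=7)
        assert abs(a[0] - b[0]) < 0.02 and abs(a[1] - b[1]) < 0.02

    def test_interval_brackets_auc(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 40)
        labels[:3], labels[-3:] = 1, 0
        scores = rng.uniform(0, 1, 40) + 0.4 * labels
        a = auc((scores, labels))
        lo, hi = bootstrap_auc_ci((scores, labels), seed=0)
        assert lo <= a <= hi


class TestConfusion:
    def test_perfect_classifier(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert confusion_metrics((scores, labels)) == (1.0, 1.0, 1.0, 1.0)

    def test_all_positive_calls(self):
        scores = np.full(6, 0.9)
        labels = np.array([1, 1, 0, 0, 0, 0])
        sens, spec, acc, mcc = confusion_metrics((scores, labels))
        assert sens == 1.0 and spec == 0.0 and mcc == 0.0

    def test_mcc_formula_example(self):
        # TP=3, FP=1, FN=1, TN=5 -> MCC = 14/sqrt(4*4*6*6) = 14/24
        scores = np.array([0.9] * 3 + [0.9] + [0.1] + [0.1] * 5)
        labels = np.array([1] * 3 + [0] + [1] + [0] * 5)
        _, _, _, mcc = confusion_metrics((scores, labels))
        assert mcc == pytest.approx(14 / 24)

    def test_threshold_is_inclusive(self):
        scores = np.array([0.4, 0.39])
        labels = np.array([1, 0])
        sens, spec, acc, _ = confusion_metrics((scores, labels), threshold=0.4)
        assert sens == 1.0 and spec == 1.0


def test_significance_rule():
    preds = ([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
    ev = evaluate_predictions(list(zip(*[]) ) if False else preds, "m", n_boot=100, seed=0)
    assert ev.significant == (ev.auc > 0.5 and ev.ci_low > 0.5)
    assert ev.ci_low <= ev.auc <= ev.ci_high


class TestPerFeature:
    def test_label_copy_and_row_count(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(20)]
        labels = pd.Series([1] * 6 + [0] * 14, index=ids)
        table = pd.DataFrame(
            {f"f{j}": rng.normal(0, 1, 20) for j in range(14)}, index=ids)
        table["f0"] = labels.astype(float)  # identical to the label
        out = per_feature_auc(table, labels, n_boot=50, seed=1)
        assert len(out) == 14
        assert out.loc[out["feature"] == "f0", "auc"].iloc[0] == 1.0

    def test_permuted_feature_is_chance(self):
        rng = np.random.default_rng(1)
        ids = [f"i{k}" for k in range(30)]
        labels = pd.Series([1] * 10 + [0] * 20, index=ids)
        aucs = []
        for s in range(20):
            table = pd.DataFrame({"f": rng.permutation(np.arange(30.0))}, index=ids)
            aucs.append(per_feature_auc(table, labels, n_boot=10, seed=s)["auc"].iloc[0])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_all_missing_feature_emits_nan_row(self):
        ids = ["a", "b", "c", "d"]
        labels = pd.Series([1, 1, 0, 0], index=ids)
        table = pd.DataFrame({"f": [np.nan] * 4}, index=ids)
        out = per_feature_auc(table, labels, n_boot=10)
        assert np.isnan(out["auc"].iloc[0])


class TestGrandAverage:
    def _clone_setup(self, depth):
        n = int(4 * 3600 * FS)
        t = np.arange(n) / FS
        events, sigs = {}, {}
        labels = {}
        for iid, lab in (("a", 1), ("b", 0)):
            d = depth if lab else depth - 3.0
            centre = 2 * 3600.0
            dip = d * np.exp(-0.5 * ((t - centre) / 60.0) ** 2)
            sig = make_uniform(70.0 - dip, infant_id=iid)
            ev = PRDEvent(onset_time=centre - 300, nadir_time=centre,
                          offset_time=centre + 300, baseline_level=70.0,
                          nadir_amplitude=d, duration=600.0,
                          slope_down=-d, slope_up=d)
            events[iid] = [ev]
            sigs[iid] = sig
            labels[iid] = lab
        return events, sigs, pd.Series(labels)

    def test_cloned_event_equals_its_shape_and_aligns_at_zero(self):
        events, sigs, labels = self._clone_setup(14.0)
        out = grand_average_prd(events, sigs, labels, window_min=10.0)
        rel = out["relative_time_min"].to_numpy()
        inj = out["mean_injury"].to_numpy()
        assert rel[np.argmin(inj)] == pytest.approx(0.0, abs=0.11)
        assert inj.min() == pytest.approx(-14.0, abs=0.1)
        # outside the event the curve returns to baseline
        assert abs(inj[0]) < 0.1 and abs(inj[-1]) < 0.1

    def test_group_depth_separation(self):
        events, sigs, labels = self._clone_setup(14.0)
        out = grand_average_prd(events, sigs, labels, window_min=10.0)
        sep = out["mean_nomild"].min() - out["mean_injury"].min()
        assert sep == pytest.approx(3.0, abs=0.2)

    def test_empty_group_warns(self):
        events, sigs, labels = self._clone_setup(14.0)
        labels[:] = 1
        with pytest.warns(UserWarning, match="curve omitted"):
            out = grand_average_prd(events, sigs, labels, window_min=5.0)
        assert "mean_nomild" not in out.columns


class TestFisher:
    def test_homogeneous_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        # 2/C(20,10) by symmetry of the two extreme tables
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / 184756, rel=1e-9)

    def test_row_and_column_swap_invariance(self):
        t = np.array([[7, 2], [3, 9]])
        p = fisher_exact(t)
        assert fisher_exact(t[::-1]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-12)

    def test_zero_margin(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


@settings(derandomize=True, deadline=None, max_examples=50)
@given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                          st.integers(0, 1)), min_size=4, max_size=40))
def test_auc_is_rank_statistic(pairs):
    """AUC is invariant under strictly increasing score transforms and
    bounded in [0, 1]."""
    # quantize so the transforms below stay strictly increasing in floats
    scores = np.round([p[0] for p in pairs], 3)
    labels = np.array([p[1] for p in pairs])
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    a = auc((scores, labels))
    assert 0.0 <= a <= 1.0
    assert auc((3.0 * scores + 1.0, labels)) == pytest.approx(a, abs=1e-12)
    assert auc((np.exp(scores), labels)) == pytest.approx(a, abs=1e-12)


def test_bootstrap_ci_coverage_on_null_cohorts():
    """95 % percentile intervals contain 0.5 in >= 85 % of no-signal
    cohorts of the study's size (percentile bootstrap is slightly
    anticonservative at n = 46)."""
    rng = np.random.default_rng(42)
    labels = np.array([1] * 12 + [0] * 34)
    hits = 0
    n_runs = 200
    for i in range(n_runs):
        scores = rng.uniform(0, 1, 46)
        lo, hi = bootstrap_auc_ci((scores, labels), n_boot=300, seed=i)
        hits += lo <= 0.5 <= hi
    assert hits / n_runs >= 0.85
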