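"""AUC, cutoffs, stepwise-AIC selection, trees and LOOCV."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecvnet import discriminate as disc
from ecvnet.io_formats import SampleLabels, TPMMatrix


def labels_for(case, ctrl):
    ids = [f"c{i}" for i in range(len(case))] + [f"h{i}" for i in range(len(ctrl))]
    return (np.concatenate([case, ctrl]),
            SampleLabels(pd.Series(["case"] * len(case) + ["control"] * len(ctrl),
                                   index=ids)))


def brute_force_auc(case, ctrl):
    wins = ties = 0
    for a, b in itertools.product(case, ctrl):
        wins += a > b
        ties += a == b
    return (wins + 0.5 * ties) / (len(case) * len(ctrl))


def tpm_from(values: np.ndarray, genes, samples) -> TPMMatrix:
    frame = pd.DataFrame(values, index=list(genes), columns=list(samples))
    frame = frame / frame.sum(axis=0) * 1e6
    return TPMMatrix(frame, column_sum_rtol=1e-9)


class TestAuc:
    def test_worked_pair_example(self):
        values, labels = labels_for([1, 3], [2, 4])
        res = disc.auc(values, labels)
        assert res.raw == pytest.approx(0.25)
        assert res.folded == pytest.approx(0.75)

    def test_complete_separation_and_all_ties(self):
        v, lab = labels_for([5, 6], [1, 2])
        assert disc.auc(v, lab) == (1.0, 1.0)
        v, lab = labels_for([3, 3], [3, 3])
        assert disc.auc(v, lab).raw == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n1, n0 = rng.integers(1, 16, 2)
            case = np.round(rng.normal(0, 1, n1), 1)   # rounding induces ties
            ctrl = np.round(rng.normal(0, 1, n0), 1)
            values, labels = labels_for(case, ctrl)
            assert disc.auc(values, labels).raw == pytest.approx(
                brute_force_auc(case, ctrl), abs=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(11)
        values, labels = labels_for(rng.normal(1, 1, 8), rng.normal(0, 1, 7))
        raw = disc.auc(values, labels).raw
        assert disc.auc(np.exp(scale * values + shift), labels).raw == \
            pytest.approx(raw, abs=1e-12)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(5)
        values, labels = labels_for(rng.normal(0, 1, 6), rng.normal(0, 1, 9))
        assert disc.auc(values, labels).raw + disc.auc(-values, labels).raw == \
            pytest.approx(1.0)


class TestBestCutoff:
    def test_separable_case_low(self):
        values, labels = labels_for([1, 2], [9, 10])
        res = disc.best_cutoff(values, labels)
        assert res.cutoff == pytest.approx(5.5)
        assert res.direction == "case-low"
        assert res.sensitivity == res.specificity == 1.0

    def test_agrees_with_exhaustive_midpoint_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            case = rng.normal(1, 1, rng.integers(2, 10))
            ctrl = rng.normal(0, 1, rng.integers(2, 10))
            values, labels = labels_for(case, ctrl)
            res = disc.best_cutoff(values, labels)
            case_high = disc.auc(values, labels).raw >= 0.5
            uniq = np.unique(values)
            best_j = -np.inf
            for t in (uniq[:-1] + uniq[1:]) / 2:
                if case_high:
                    j = (case > t).mean() + (ctrl <= t).mean() - 1
                else:
                    j = (case < t).mean() + (ctrl >= t).mean() - 1
                best_j = max(best_j, j)
            assert res.sensitivity + res.specificity - 1 == pytest.approx(best_j)


def planted_dataset(seed, n_genes=9, n_case=10, n_ctrl=10, shift=2.0):
    """Independent log-normal genes; gene 0 shifted down in cases."""
    rng = np.random.default_rng(seed)
    log = rng.normal(8, 1, (n_genes, n_case + n_ctrl))
    log[0, :n_case] -= shift
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_ctrl)]
    labels = SampleLabels(pd.Series(["case"] * n_case + ["control"] * n_ctrl,
                                    index=samples))
    return tpm_from(2.0 ** log, genes, samples), labels, genes


class TestStepwise:
    def test_planted_gene_selected_alone(self):
        tpm, labels, genes = planted_dataset(1, shift=3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, aic, trace = disc.stepwise_logistic_aic(genes, tpm, labels)
        assert selected == ("g0",)
        assert trace[0]["aic"] > aic

    def test_matches_exhaustive_subset_minimum(self):
        """Greedy bidirectional stepwise lands on the global AIC optimum."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(8):
                tpm, labels, genes = planted_dataset(seed, n_genes=6,
                                                     n_case=20, n_ctrl=20,
                                                     shift=1.0)
                selected, aic, _ = disc.stepwise_logistic_aic(genes, tpm, labels)
                x, y = disc._feature_frame(genes, tpm, labels)
                best = (None, np.inf)
                for r in range(len(genes) + 1):
                    for subset in itertools.combinations(range(len(genes)), r):
                        a = disc.logistic_aic(x[:, list(subset)], y)
                        if a < best[1] - 1e-9:
                            best = (tuple(sorted(genes[i] for i in subset)), a)
                assert tuple(sorted(selected)) == best[0]
                assert aic == pytest.approx(best[1], abs=1e-6)

    def test_single_null_candidate_rarely_selected(self):
        """One noise candidate enters the model only at the AIC false-inclusion
        rate (~16%), so the selection is empty in the large majority of seeds."""
        empty = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(25):
                tpm, labels, genes = planted_dataset(100 + seed, shift=0.0)
                selected, _, _ = disc.stepwise_logistic_aic(["g3"], tpm, labels)
                empty += not selected
        assert empty >= 15

    def test_too_many_candidates_rejected(self):
        tpm, labels, genes = planted_dataset(0, n_genes=16)
        with pytest.raises(ValueError):
            disc.stepwise_logistic_aic(genes, tpm, labels)


class TestInteractionScan:
    def test_retained_flag_follows_delta_rule(self):
        tpm, labels, genes = planted_dataset(3, shift=2.0)
        dup = TPMMatrix(pd.concat([tpm.tpm,
                                   tpm.tpm.loc[["g0"]].set_axis(["g0copy"])]),
                        column_sum_rtol=10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = disc.interaction_scan("g0", ["g0copy", "g1"], dup, labels)
        for row in table:
            assert row["retained"] == (row["delta_aic"] > 1.0)
            assert np.isfinite(row["delta_aic"])

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(1)
        n = 40
        a = rng.normal(0, 1, 2 * n)
        b = rng.normal(0, 1, 2 * n)
        logit = 3.0 * a * b
        y = rng.uniform(size=2 * n) < 1 / (1 + np.exp(-logit))
        order = np.argsort(~y)  # cases first
        a, b, y = a[order], b[order], y[order]
        genes = ["base", "other"]
        samples = [f"s{i}" for i in range(2 * n)]
        labels = SampleLabels(pd.Series(np.where(y, "case", "control"),
                                        index=samples))
        tpm = tpm_from(2.0 ** np.vstack([a + 8, b + 8]), genes, samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = disc.interaction_scan("base", ["other"], tpm, labels)
        assert table[0]["delta_aic"] > 1.0 and table[0]["retained"]

    def test_noise_interactions_mostly_rejected(self):
        retained = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                tpm, labels, genes = planted_dataset(200 + seed, shift=2.5)
                table = disc.interaction_scan("g0", ["g1"], tpm, labels)
                retained += table[0]["retained"]
        assert retained <= 8   # penalty of 2 per parameter dominates

    def test_base_among_others_rejected(self):
        tpm, labels, genes = planted_dataset(0)
        with pytest.raises(ValueError):
            disc.interaction_scan("g0", genes, tpm, labels)


class TestFitTree:
    def test_constant_labels_give_stump(self):
        tpm, _, genes = planted_dataset(4)
        one_class = SampleLabels(pd.Series(
            ["case"] * 19 + ["control"], index=tpm.sample_ids))
        # nearly constant labels: min_leaf prevents isolating one sample
        tree, used = disc.fit_tree(genes, tpm, one_class, min_leaf=2)
        assert used == () or len(used) <= 1

    def test_perfect_separator_used_at_root(self):
        tpm, labels, genes = planted_dataset(5, shift=8.0)
        tree, used = disc.fit_tree(genes, tpm, labels)
        assert tree["gene"] == "g0"
        assert used == ("g0",)

    def test_root_threshold_matches_brute_force_gini(self):
        tpm, labels, genes = planted_dataset(6, shift=2.0)
        tree, _ = disc.fit_tree(genes, tpm, labels)
        x = tpm.tpm.loc[genes, labels.sample_ids].to_numpy().T
        y = (np.array(labels.group) == "case").astype(float)
        best = None
        for j in range(x.shape[1]):
            uniq = np.unique(x[:, j])
            for t in (uniq[:-1] + uniq[1:]) / 2:
                left = x[:, j] <= t
                if left.sum() < 2 or (~left).sum() < 2:
                    continue
                def gini(v):
                    return 2 * v.mean() * (1 - v.mean()) if v.size else 0.0
                imp = (left.sum() * gini(y[left]) +
                       (~left).sum() * gini(y[~left])) / y.size
                if best is None or imp < best[0] - 1e-12:
                    best = (imp, j, t)
        assert tree["feature"] == best[1]
        assert tree["threshold"] == pytest.approx(best[2])


class TestLoocv:
    @staticmethod
    def _single_feature_tpm(feature, labels):
        """Two-gene matrix (signal + constant ballast) so the feature's TPM
        is a strictly monotone function of the raw signal."""
        raw = np.vstack([feature, np.full_like(feature, np.mean(feature))])
        return tpm_from(raw, ["g", "ballast"], labels.sample_ids)

    def test_perfect_feature_classifies_perfectly(self):
        values, labels = labels_for(np.arange(10) + 100.0, np.arange(10) + 1.0)
        tpm = self._single_feature_tpm(values, labels)
        sens, spec, conf = disc.loocv_ensemble(["g"], tpm, labels,
                                               ensemble_size=50, seed=0)
        assert sens == 1.0 and spec == 1.0
        assert conf["tp"] + conf["fn"] == 10

    def test_two_gaussians_match_bayes_rate(self):
        """Single feature, groups two sd apart: pooled sensitivity and
        specificity sit near the single-threshold optimum Phi(1) ~ 0.84."""
        rng = np.random.default_rng(2)
        n = 50
        case = rng.normal(2, 1, n)
        ctrl = rng.normal(0, 1, n)
        samples = [f"c{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
        labels = SampleLabels(pd.Series(["case"] * n + ["control"] * n,
                                        index=samples))
        tpm = self._single_feature_tpm(
            2.0 ** (np.concatenate([case, ctrl]) + 8), labels)
        sens, spec, _ = disc.loocv_ensemble(["g"], tpm, labels,
                                            ensemble_size=150, seed=2)
        # +-0.1 ~ 2 standard errors of a proportion at n=50
        assert abs(sens - 0.8413) < 0.1
        assert abs(spec - 0.8413) < 0.1

    def test_deterministic_given_seed(self):
        tpm, labels, genes = planted_dataset(8, shift=1.0)
        a = disc.loocv_ensemble(["g0", "g1"], tpm, labels, 80, seed=3)
        b = disc.loocv_ensemble(["g0", "g1"], tpm, labels, 80, seed=3)
        assert a == b

    def test_too_small_cohort_rejected(self):
        tpm, labels, genes = planted_dataset(9, n_case=1, n_ctrl=2)
        with pytest.raises(ValueError):
            disc.loocv_ensemble(["g0"], tpm, labels, 10, seed=0)


class TestEvaluateMarkers:
    def test_report_is_complete_and_consistent(self):
        tpm, labels, genes = planted_dataset(10, shift=3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = disc.evaluate_markers(genes[:5], tpm, labels,
                                           ensemble_size=50, seed=0)
        assert set(report.stepwise_selected) <= set(genes[:5])
        assert set(report.tree_genes) <= set(genes[:5])
        assert report.interaction_base == "g0"
        assert len(report.interaction_table) == 4
        d = report.to_dict()
        assert d["loocv"]["features"] == ["g0"]
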