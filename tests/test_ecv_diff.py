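"""Edge contribution values, differential-edge selection, subnetworks."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import BSpline

from ecvnet import ecv_diff, network
from ecvnet.benchmarks import chain_dataset
from ecvnet.ecv_diff import ECvMatrix, Subnetwork
from ecvnet.io_formats import SampleLabels


def independent_contribution(smoother, x: float) -> float:
    """Evaluate a fitted smoother by raw scipy basis expansion (oracle)."""
    basis = smoother.basis
    t = basis.knots
    xc = min(max(x, basis.lo), basis.hi)
    row = np.empty(basis.n_basis)
    drow = np.empty(basis.n_basis)
    for i in range(basis.n_basis):
        coef = np.zeros(basis.n_basis)
        coef[i] = 1.0
        b = BSpline(t, coef, 3, extrapolate=True)
        row[i] = b(xc)
        drow[i] = b.derivative()(xc)
    row = row + (x - xc) * drow
    centered = row[1:] - np.asarray(smoother.col_means)
    return float(centered @ np.asarray(smoother.coef))


class TestComputeEcv:
    def test_linear_smoother_closed_form(self):
        x = np.linspace(-2, 2, 80)
        fit = network.fit_smoother(x, 2 * x, spline_df=4)
        assert fit.contribution(np.array([3.0]))[0] == pytest.approx(
            2 * (3.0 - x.mean()), abs=1e-6)

    def test_zero_mean_over_training_samples(self, config):
        data = chain_dataset(2, n=150)
        model = network.learn_structure(data, config, seed=2)
        ecv = ecv_diff.compute_ecv(model, data)
        assert np.allclose(ecv.values.mean(axis=1), 0.0, atol=1e-9)

    def test_matches_independent_basis_expansion(self, config):
        data = chain_dataset(4, n=150)
        model = network.learn_structure(data, config, seed=4)
        assert model.edges, "chain fixture should produce edges"
        ecv = ecv_diff.compute_ecv(model, data)
        rng = np.random.default_rng(0)
        for _ in range(200):
            i = rng.integers(len(ecv.edges))
            j = rng.integers(len(ecv.sample_ids))
            edge = ecv.edges[i]
            x = float(data.frame.loc[edge[0]].iloc[j])
            oracle = independent_contribution(model.smoothers[edge], x)
            assert ecv.values[i, j] == pytest.approx(oracle, abs=1e-9)

    def test_missing_gene_rejected(self, config):
        data = chain_dataset(1, n=100)
        model = network.learn_structure(data, config, seed=1)
        with pytest.raises(KeyError):
            ecv_diff.compute_ecv(
                model, type(data)(data.frame.drop(index="u"), data.scale))


def ecv_matrix(deltas, n_case=3, n_control=3):
    """Edges a->b, c->d, ... with exact group-mean differences ``deltas``."""
    edges = tuple((f"p{i}", f"q{i}") for i in range(len(deltas)))
    samples = [f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_control)]
    values = np.zeros((len(deltas), n_case + n_control))
    for i, d in enumerate(deltas):
        values[i, :n_case] = d
    labels = SampleLabels(pd.Series(["case"] * n_case + ["control"] * n_control,
                                    index=samples))
    return ECvMatrix(edges, tuple(samples), values), labels


class TestDifferentialEdges:
    def test_hand_ranked_selection(self):
        ecv, labels = ecv_matrix([0.0, 1.0, 2.0, 3.0, 4.0])
        result = ecv_diff.differential_edges(ecv, labels, q=0.6, floor=1)
        assert result.n_selected == 3
        assert list(result.edges) == [("p4", "q4"), ("p3", "q3"), ("p2", "q2")]
        assert [round(d, 9) for d in result.deltas.values()] == [4.0, 3.0, 2.0]

    def test_identical_groups_tie_break_is_lexical(self):
        ecv, labels = ecv_matrix([0.0, 0.0, 0.0])
        result = ecv_diff.differential_edges(ecv, labels, q=1e-5, floor=1)
        assert result.n_selected == 1
        assert result.edges == (("p0", "q0"),)

    def test_selection_count_formula(self):
        # round(q * E) with the floor and the cap
        ecv, labels = ecv_matrix(list(range(200)))
        assert ecv_diff.differential_edges(ecv, labels, 0.025, 1).n_selected == 5
        assert ecv_diff.differential_edges(ecv, labels, 1e-5, 1).n_selected == 1
        assert ecv_diff.differential_edges(ecv, labels, 1.0, 1).n_selected == 200
        assert ecv_diff._round_half_up(1e-5 * 1_000_000) == 10

    def test_monotone_in_q(self):
        rng = np.random.default_rng(3)
        ecv, labels = ecv_matrix(rng.uniform(0, 5, 40))
        previous = set()
        for q in (0.05, 0.2, 0.5, 1.0):
            selected = set(ecv_diff.differential_edges(ecv, labels, q, 1).edges)
            assert previous <= selected
            previous = selected

    def test_empty_group_rejected(self):
        ecv, labels = ecv_matrix([1.0])
        bad = SampleLabels(pd.Series(["case", "control"], index=["c0", "h0"]))
        with pytest.raises(ValueError):
            ecv_diff.differential_edges(
                ECvMatrix(ecv.edges, ("c0", "h0"), ecv.values[:, :2]),
                SampleLabels(pd.Series(["case", "case", "control"],
                                       index=["c0", "h0", "x"])), 0.5)


class TestExtractSubnetworks:
    def _edge_set(self, edges, deltas=None):
        deltas = deltas or [1.0] * len(edges)
        table = pd.DataFrame({
            "parent": [e[0] for e in edges], "child": [e[1] for e in edges],
            "mean_case": deltas, "mean_control": [0.0] * len(edges),
            "delta": deltas, "rank": range(1, len(edges) + 1),
            "selected": [1] * len(edges),
        })
        return ecv_diff.DifferentialEdgeSet(table, 1.0, len(edges))

    def test_disjoint_pairs(self):
        subnets = ecv_diff.extract_subnetworks(
            self._edge_set([("a", "b"), ("c", "d")]))
        assert [sn.genes for sn in subnets] == [("a", "b"), ("c", "d")]

    def test_hand_traced_components_and_ordering(self):
        subnets = ecv_diff.extract_subnetworks(
            self._edge_set([("d", "e"), ("a", "b"), ("b", "c")]))
        assert [sn.genes for sn in subnets] == [("a", "b", "c"), ("d", "e")]
        assert subnets[0].component_id == 1

    def test_partition_invariant(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        edges = list({(genes[rng.integers(10)], genes[10 + rng.integers(10)])
                      for _ in range(15)})
        subnets = ecv_diff.extract_subnetworks(self._edge_set(edges))
        seen = [e for sn in subnets for e in sn.edges]
        assert sorted(seen) == sorted(edges)          # every edge exactly once
        gene_sets = [set(sn.genes) for sn in subnets]
        for i, a in enumerate(gene_sets):
            for b in gene_sets[i + 1:]:
                assert not (a & b)
        # edges - genes + components >= 0
        total_edges = sum(len(sn.edges) for sn in subnets)
        total_genes = sum(len(sn.genes) for sn in subnets)
        assert total_edges - total_genes + len(subnets) >= 0

    def test_empty_selection_rejected(self):
        edge_set = self._edge_set([("a", "b")])
        edge_set.table["selected"] = 0
        with pytest.raises(ValueError):
            ecv_diff.extract_subnetworks(
                ecv_diff.DifferentialEdgeSet(edge_set.table, 1.0, 0))


class TestSubnetworkStats:
    def test_proportional_rows_have_unit_correlation(self, tpm_factory,
                                                     labels_factory):
        labels = labels_factory(3, 3)
        base = np.array([[1, 2, 3, 4, 5, 6.0]])
        values = np.vstack([base, 3 * base, np.ones((1, 6))])
        tpm = tpm_factory(values, ["a", "b", "z"], labels.sample_ids)
        subnets = ecv_diff.subnetwork_stats(
            [Subnetwork(1, ("a", "b"), (("a", "b"),), {("a", "b"): 1.0})],
            tpm, labels)
        assert subnets[0].min_abs_correlation == pytest.approx(1.0)

    def test_representative_is_best_auc_gene(self, tpm_factory, labels_factory):
        labels = labels_factory(3, 3)
        perfect = [10, 11, 12, 1, 2, 3]      # separates the groups, AUC 1
        noisy = [5, 1, 4, 2, 6, 3]
        tpm = tpm_factory(np.array([perfect, noisy], dtype=float),
                          ["hi", "lo"], labels.sample_ids)
        subnets = ecv_diff.subnetwork_stats(
            [Subnetwork(1, ("hi", "lo"), (("hi", "lo"),), {("hi", "lo"): 1.0})],
            tpm, labels)
        assert subnets[0].representative == "hi"
        assert subnets[0].best_auc == pytest.approx(1.0)
        assert 0.5 <= subnets[0].gene_aucs["lo"] <= 1.0

    def test_missing_gene_rejected(self, tpm_factory, labels_factory):
        labels = labels_factory(2, 2)
        tpm = tpm_factory(np.ones((1, 4)), ["a"], labels.sample_ids)
        with pytest.raises(KeyError):
            ecv_diff.subnetwork_stats(
                [Subnetwork(1, ("a", "b"), (("a", "b"),), {})], tpm, labels)
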