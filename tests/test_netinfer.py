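"""CLR transform, neighborhood selection, StARS and symmetrization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umbranet import (
    AbundanceTable,
    CooccurrenceNetworkModel,
    clr_transform,
    infer_network,
    neighborhood_fit,
    null_penalty,
    stars_select,
    symmetrize,
)
from umbranet.netinfer import CompositionMatrix, default_penalty_path
from umbranet.synthetic import GroundTruth

from umbranet import generate_association_graph, sample_counts


def _table(values, taxa=None):
    values = np.asarray(values)
    taxa = taxa or [f"t{j}" for j in range(values.shape[1])]
    return AbundanceTable(
        pd.DataFrame(values, columns=taxa, index=[f"s{i}" for i in range(len(values))])
    )


def _clr_from_values(values, taxa=None):
    return clr_transform(_table(values, taxa), pseudocount=1.0)


class TestCLR:
    def test_constant_row_maps_to_zero(self):
        out = clr_transform(_table([[1, 1, 1, 1]]), pseudocount=1.0)
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_two_entry_row_frozen_value(self):
        """(1,3) with pseudocount 1: log2 and log4 centered -> -/+0.34657."""
        out = clr_transform(_table([[1, 3]]), pseudocount=1.0)
        np.testing.assert_allclose(
            out.values.to_numpy(), [[-0.34657359, 0.34657359]], atol=1e-6
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.lists(st.integers(0, 10_000), min_size=4, max_size=4),
            min_size=1,
            max_size=6,
        )
    )
    def test_rows_sum_to_zero(self, rows):
        out = clr_transform(_table(rows), pseudocount=1.0)
        np.testing.assert_allclose(out.values.sum(axis=1), 0.0, atol=1e-8)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            clr_transform(_table([[1, 2]]), pseudocount=0.0)
        bad = pd.DataFrame([[1.0, 1.0]], columns=["a", "b"], index=["s"])
        good = CompositionMatrix(values=bad * 0, source_pseudocount=1.0)
        with pytest.raises(ValueError):
            CompositionMatrix(values=bad, source_pseudocount=1.0)


def exhaustive_best_subset(y, X, penalty):
    """Oracle for tiny problems: minimize the lasso objective over all
    support patterns by unpenalized least squares + L1 cost on the
    minimizer of each support (exact for orthonormal-ish designs, used
    only to identify which predictors matter)."""
    n, p = X.shape
    best, best_support = np.inf, ()
    for r in range(p + 1):
        for sub in itertools.combinations(range(p), r):
            cols = list(sub)
            if cols:
                beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
                resid = y - X[:, cols] @ beta
                cost = resid @ resid / (2 * n) + penalty * np.abs(beta).sum()
            else:
                cost = y @ y / (2 * n)
            if cost < best - 1e-12:
                best, best_support = cost, tuple(cols)
    return set(best_support)


class TestNeighborhoodFit:
    def test_null_penalty_gives_empty_neighborhoods(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.integers(0, 100, size=(30, 5)))
        clr = clr_transform(tab)
        lam = null_penalty(clr)
        nbrs = neighborhood_fit(clr, lam * 1.0001)
        assert all(len(v) == 0 for v in nbrs.values())

    def test_duplicated_columns_select_each_other(self):
        """Two proportional columns plus independent noise: each duplicate's
        neighborhood is exactly the other, matching the best-subset oracle."""
        rng = np.random.default_rng(1)
        base = rng.integers(1, 200, size=50)
        noise = rng.integers(1, 200, size=(50, 3))
        tab = _table(np.column_stack([base, base * 2, noise]))
        clr = clr_transform(tab)
        lam = null_penalty(clr) * 0.4
        nbrs = neighborhood_fit(clr, lam)
        assert "t1" in nbrs["t0"]
        assert "t0" in nbrs["t1"]
        # cross-check against exhaustive subset search on the same design
        z = clr.values.to_numpy()
        z = (z - z.mean(0)) / z.std(0)
        oracle = exhaustive_best_subset(z[:, 0], z[:, 1:], lam)
        assert 0 in oracle  # predictor index 0 is column t1

    def test_taxon_order_equivariance(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 500, size=(40, 6))
        taxa = [f"t{j}" for j in range(6)]
        clr1 = _clr_from_values(values, taxa)
        perm = [3, 0, 5, 1, 4, 2]
        clr2 = _clr_from_values(values[:, perm], [taxa[j] for j in perm])
        lam = null_penalty(clr1) * 0.5
        n1 = neighborhood_fit(clr1, lam)
        n2 = neighborhood_fit(clr2, lam)
        assert {k: dict(v) for k, v in n1.items()} == {k: dict(v) for k, v in n2.items()}

    def test_rejects_degenerate_inputs(self):
        clr = _clr_from_values([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError):
            neighborhood_fit(clr, 0.1)  # only 2 samples
        clr4 = _clr_from_values(np.random.default_rng(0).integers(0, 9, (10, 4)))
        with pytest.raises(ValueError):
            neighborhood_fit(clr4, -0.1)


class TestStars:
    def test_instability_zero_when_subsamples_agree(self):
        """Strong duplicated signal: at small penalties every subsample
        selects the same edge, at huge penalties none does; both ends of
        the path have instability ~0."""
        rng = np.random.default_rng(3)
        base = rng.integers(1, 2000, size=200)
        tab = _table(np.column_stack([base, base, rng.integers(1, 2000, (200, 2))]))
        clr = clr_transform(tab)
        lam0 = null_penalty(clr)
        path = np.array([lam0 * 1.01, lam0 * 0.9])
        _, _, curve = stars_select(clr, penalty_path=path, n_subsamples=8, seed=0)
        assert curve[0] == pytest.approx(0.0, abs=1e-12)

    def test_threshold_half_admits_densest(self):
        """Instability is bounded by 1/2, so threshold 0.5 admits the
        densest (last) penalty on the path."""
        rng = np.random.default_rng(4)
        tab = _table(rng.integers(0, 300, size=(60, 5)))
        clr = clr_transform(tab)
        path = default_penalty_path(clr, length=6)
        sel, _, curve = stars_select(
            clr, penalty_path=path, n_subsamples=6, instability_threshold=0.5, seed=1
        )
        assert (curve <= 0.5 + 1e-12).all()
        assert sel == pytest.approx(path[-1])

    def test_independent_data_selects_near_empty_network(self):
        """On association-free data the stable network is (near-)empty:
        edge recovery F1 against the empty truth is at least 0.9."""
        gt = GroundTruth(precision_matrix=np.eye(10), true_edges=frozenset())
        tab = sample_counts(gt, 500, (2000, 10000), seed=11)
        net = infer_network(tab, seed=12)
        f1 = 1.0 if net.n_edges == 0 else 0.0
        assert net.n_edges <= 1
        assert f1 >= 0.9

    def test_path_validation(self):
        clr = _clr_from_values(np.random.default_rng(0).integers(0, 9, (10, 4)))
        with pytest.raises(ValueError):
            stars_select(clr, penalty_path=np.array([]))
        with pytest.raises(ValueError):
            stars_select(clr, penalty_path=np.array([0.1, 0.2]))  # increasing


class TestSymmetrize:
    def test_or_and_rules(self):
        nbrs = {"a": {"b": 1}, "b": {}, "c": {}}
        net_or = symmetrize(nbrs, rule="OR")
        net_and = symmetrize(nbrs, rule="AND")
        assert ("a", "b") in net_or.edges
        assert ("a", "b") not in net_and.edges

    def test_symmetric_neighborhoods_agree(self):
        nbrs = {"a": {"b": 1}, "b": {"a": 1}, "c": {}}
        assert symmetrize(nbrs, "OR").edges == symmetrize(nbrs, "AND").edges

    def test_and_subset_of_or(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(8)]
        nbrs = {
            v: {w: 1 for w in rng.choice(nodes, size=3) if w != v} for v in nodes
        }
        assert symmetrize(nbrs, "AND").edges <= symmetrize(nbrs, "OR").edges

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            symmetrize({"a": {}}, rule="XOR")


class TestEndToEnd:
    def test_no_self_loops_and_node_set_preserved(self):
        gt = generate_association_graph(8, "band", 0.2, seed=6)
        tab = sample_counts(gt, 200, (1000, 2000), seed=7)
        net = infer_network(tab, seed=8)
        assert set(net.nodes) == set(tab.taxon_ids)
        assert all(i != j for i, j in net.edges)
        assert net.selected_penalty in net.penalty_path

    def test_edge_count_monotone_along_path(self):
        """For fixed data, decreasing the penalty never removes edges."""
        gt = generate_association_graph(8, "band", 0.2, seed=6)
        tab = sample_counts(gt, 200, (1000, 2000), seed=7)
        clr = clr_transform(tab)
        path = default_penalty_path(clr, length=8)
        counts = [
            symmetrize(neighborhood_fit(clr, lam)).n_edges for lam in path
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_band_recovery(self):
        """Support recovery on a band graph: 20 taxa, 1000 samples,
        default path -> F1 >= 0.8 against the true edges."""
        gt = generate_association_graph(20, "band", 0.1, seed=3)
        tab = sample_counts(gt, 1000, (2000, 10000), seed=4)
        res = CooccurrenceNetworkModel(tab).fit(seed=5)
        pred = {
            tuple(sorted((int(i[1:]) - 1, int(j[1:]) - 1)))
            for i, j in res.network.edges
        }
        true = set(gt.true_edges)
        tp = len(pred & true)
        prec = tp / len(pred) if pred else 0.0
        rec = tp / len(true)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert f1 >= 0.8
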