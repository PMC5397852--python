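import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncprop import (
    ExpressionDataset,
    PairCorrelation,
    consensus_edges,
    dataset_coexpression,
    filter_genes,
    fisher_z,
)


def make_dataset(values, ids=None, biotypes=None, dataset_id="D1"):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=ids,
        biotypes=biotypes or ["coding"] * len(ids),
        values=values,
    )


def pair_call(a, b, r, flagged_rank=True, p=1e-6):
    return PairCorrelation(
        gene_a=min(a, b), gene_b=max(a, b), r=r, z=math.atanh(r),
        z_std_a=5.0 if r > 0 else -5.0, z_std_b=5.0 if r > 0 else -5.0,
        p_adj=p, rank_pass_a=flagged_rank, rank_pass_b=flagged_rank,
    )


class TestFilterGenes:
    def test_mean_floor_removes_low_expression(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(3, 8))
        vals = base + np.array([[0.5], [2.0], [3.0]])
        vals = np.abs(vals)
        vals[0] *= 0.5 / vals[0].mean()
        vals[1] *= 2.0 / vals[1].mean()
        vals[2] *= 3.0 / vals[2].mean()
        out = filter_genes(make_dataset(vals))
        assert out.gene_ids == ["G1", "G2"]

    def test_identical_variances_all_kept(self):
        vals = np.tile(np.linspace(8, 12, 10), (5, 1))
        out = filter_genes(make_dataset(vals))
        assert out.n_genes == 5

    def test_bottom_quartile_variance_dropped(self):
        rng = np.random.default_rng(1)
        rows = [10 + np.sqrt(v) * rng.standard_normal(200) for v in (1, 2, 3, 4)]
        vals = np.abs(np.array(rows))
        out = filter_genes(make_dataset(vals))
        assert out.gene_ids == ["G1", "G2", "G3"]

    def test_order_preserved(self):
        rng = np.random.default_rng(2)
        vals = np.abs(10 + rng.standard_normal((20, 12)))
        out = filter_genes(make_dataset(vals))
        order = {g: i for i, g in enumerate(out.gene_ids)}
        assert sorted(order.values()) == list(order.values())

    def test_no_survivors_is_an_error(self):
        vals = np.full((3, 6), 0.1)
        with pytest.raises(ValueError, match="no genes pass"):
            filter_genes(make_dataset(vals))


class TestFisherZ:
    def test_examples(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(-0.5) == pytest.approx(-fisher_z(0.5), abs=1e-15)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_degenerate_correlation_rejected(self, r):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_z(r)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(-0.999, 0.999),
        st.floats(-0.999, 0.999),
    )
    def test_strictly_increasing_and_odd(self, r1, r2):
        assert fisher_z(-r1) == pytest.approx(-fisher_z(r1), abs=1e-12)
        if r1 < r2:
            assert fisher_z(r1) < fisher_z(r2)


class TestDatasetCoexpression:
    def _planted(self, n=200, n_samples=20, seed=0, rho=0.99):
        rng = np.random.default_rng(seed)
        log_x = rng.uniform(1, 3, size=(n, 1)) + 0.5 * rng.standard_normal(
            (n, n_samples)
        )
        f = rng.standard_normal(n_samples)
        s = 0.15
        log_x[0] = 3.5 + s * (np.sqrt(rho) * f
                              + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
        log_x[1] = 3.5 + s * (np.sqrt(rho) * f
                              + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
        return make_dataset(np.exp(log_x))

    def test_planted_pair_flagged_positive(self):
        calls = dataset_coexpression(self._planted())
        pairs = {c.pair: c for c in calls}
        assert ("G0", "G1") in pairs
        assert pairs[("G0", "G1")].sign == 1
        assert pairs[("G0", "G1")].p_adj < 0.01

    def test_independent_genes_rarely_called(self):
        # under the null the per-gene Bonferroni + mutual rank rule keeps
        # the false-call rate far below 1e-4 of tested pairs
        rng = np.random.default_rng(3)
        n = 1000
        vals = np.abs(10 + rng.standard_normal((n, 20)))
        calls = dataset_coexpression(make_dataset(vals))
        assert len(calls) / (n * (n - 1) / 2) < 1e-4

    def test_rank_rule_enforced_on_both_endpoints(self):
        # b's best partner is x (r ~ 1); the a-b pair is rank 1 for a but
        # rank 2 for b, so it must not be flagged.
        rng = np.random.default_rng(4)
        n, m = 50, 40
        vals = np.abs(10 + rng.standard_normal((n, m)))
        b = np.linspace(5, 20, m) + 0.05 * rng.standard_normal(m)
        x = b + 0.01 * rng.standard_normal(m)
        a = b + 0.6 * rng.standard_normal(m)
        vals[0], vals[1], vals[2] = a, b, x
        ids = ["a", "b", "x"] + [f"n{i}" for i in range(n - 3)]
        calls = dataset_coexpression(make_dataset(vals, ids=ids))
        pairs = {c.pair for c in calls}
        r_ab = np.corrcoef(a, b)[0, 1]
        r_bx = np.corrcoef(b, x)[0, 1]
        assert r_bx > r_ab > 0.9
        assert ("a", "b") not in pairs
        assert ("b", "x") in pairs

    def test_symmetric_in_gene_order(self):
        ds = self._planted(n=60, seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(ds.n_genes)
        shuffled = ExpressionDataset(
            dataset_id="D1s",
            gene_ids=[ds.gene_ids[i] for i in perm],
            biotypes=[ds.biotypes[i] for i in perm],
            values=ds.values[perm],
        )
        set_a = {(c.pair, c.sign) for c in dataset_coexpression(ds)}
        set_b = {(c.pair, c.sign) for c in dataset_coexpression(shuffled)}
        assert set_a == set_b

    def test_constant_gene_excluded_with_warning(self, caplog):
        ds = self._planted(n=30, seed=7)
        vals = ds.values.copy()
        vals[5] = 7.0
        ds2 = make_dataset(vals, ids=ds.gene_ids)
        with caplog.at_level(logging.WARNING):
            calls = dataset_coexpression(ds2)
        assert any("constant-expression" in r.message for r in caplog.records)
        assert all("G5" not in c.pair for c in calls)


class TestConsensusEdges:
    def test_three_of_five_positive_kept(self):
        per = [[pair_call("A", "B", 0.9)]] * 3 + [[], []]
        (edge,) = consensus_edges(per)
        assert (edge.sign, edge.support) == (1, 3)

    def test_conflicting_signs_dropped(self):
        per = [
            [pair_call("A", "B", 0.9)],
            [pair_call("A", "B", 0.9)],
            [pair_call("A", "B", -0.9)],
        ]
        assert consensus_edges(per) == []

    def test_empty_input(self):
        assert consensus_edges([[], [], []]) == []

    def test_same_sign_required(self):
        per = [[pair_call("A", "B", 0.9)]] * 2 + [[pair_call("A", "B", -0.9)]] * 3
        (edge,) = consensus_edges(per)
        assert (edge.sign, edge.support) == (-1, 3)

    @pytest.mark.parametrize("low,high", [(1, 2), (2, 3), (3, 5)])
    def test_monotone_in_min_support(self, low, high):
        rng = np.random.default_rng(8)
        per = []
        for _ in range(6):
            calls = []
            for i in range(10):
                if rng.random() < 0.5:
                    calls.append(
                        pair_call(f"A{i}", f"B{i}", 0.9 if rng.random() < 0.7 else -0.9)
                    )
            per.append(calls)
        lo = {(e.pair, e.sign) for e in consensus_edges(per, min_support=low)}
        hi = {(e.pair, e.sign) for e in consensus_edges(per, min_support=high)}
        assert hi <= lo
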