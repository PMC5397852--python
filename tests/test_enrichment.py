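import logging

import numpy as np
import pytest
from scipy import stats

from lncprop import (
    PathwayGeneSet,
    PropagationResult,
    bh_fdr,
    core_genes,
    enrichment_score,
    filter_pathways,
    flag_differential_core_genes,
    rank_coding_genes,
    rwr,
)
from lncprop.enrichment import empirical_pvalue, permutation_test

from conftest import coding_chain


def pw(genes, pid="P1"):
    return PathwayGeneSet(pid, pid, frozenset(genes))


def ranked_from_scores(genes, scores):
    return PropagationResult(
        steady_state={g: s**2 for g, s in zip(genes, scores)},
        seed_ids=("L",),
        propagation_scores=dict(zip(genes, scores)),
        ranked_list=list(genes),
    )


class TestFilterPathways:
    @pytest.mark.parametrize(
        "n_in_net,kept", [(14, False), (15, True), (500, True), (501, False)]
    )
    def test_size_window(self, n_in_net, kept):
        net = coding_chain(501, with_lnc_seed=False)
        genes = {f"C{i:04d}" for i in range(1, n_in_net + 1)}
        out = filter_pathways([pw(genes | {"ABSENT1", "ABSENT2"})], net)
        assert bool(out) is kept  # absent genes never count toward size

    def test_pathway_with_no_network_genes_excluded(self):
        net = coding_chain(20, with_lnc_seed=False)
        assert filter_pathways([pw({"X1", "X2"})], net) == []


class TestEnrichmentScore:
    def test_hand_computed_toy_example(self, toy_ranked):
        es, peak, rs = enrichment_score(toy_ranked, pw({"g1", "g3"}))
        assert es == pytest.approx(2 / 3, abs=1e-12)
        assert peak == 3
        expected = [0.625, 0.625 - 1 / 3, 2 / 3, 1 / 3, 0.0]
        assert np.allclose(rs, expected, atol=1e-12)

    def test_prefix_pathway_scores_one(self, toy_ranked):
        es, peak, _ = enrichment_score(toy_ranked, pw({"g1", "g2"}))
        assert es == pytest.approx(1.0, abs=1e-12)
        assert peak == 2

    def test_scale_invariance(self, toy_ranked):
        genes = toy_ranked.ranked_list
        scaled = ranked_from_scores(
            genes, [7.3 * toy_ranked.propagation_scores[g] for g in genes]
        )
        for pathway in (pw({"g1", "g3"}), pw({"g2", "g4", "g5"})):
            es1, pk1, _ = enrichment_score(toy_ranked, pathway)
            es2, pk2, _ = enrichment_score(scaled, pathway)
            assert es2 == pytest.approx(es1, abs=1e-12)
            assert pk1 == pk2

    def test_running_fractions_both_terminate_at_unity(self, toy_ranked):
        # F_InP(n) = F_NotP(n) = 1 implies the running sum ends at zero
        for pathway in (pw({"g1"}), pw({"g2", "g5"}), pw({"g1", "g3", "g4"})):
            _, _, rs = enrichment_score(toy_ranked, pathway)
            assert rs[-1] == pytest.approx(0.0, abs=1e-12)

    def test_weight_zero_matches_two_sample_ks_oracle(self):
        rng = np.random.default_rng(31)
        n, size = 200, 25
        genes = [f"g{i:03d}" for i in range(n)]
        for _ in range(50):
            scores = np.sort(rng.uniform(0.01, 1, n))[::-1]
            members = set(rng.choice(genes, size=size, replace=False).tolist())
            ranked = ranked_from_scores(genes, scores)
            es, _, _ = enrichment_score(ranked, pw(members), weight_exponent=0)
            ranks_in = [i + 1 for i, g in enumerate(genes) if g in members]
            ranks_out = [i + 1 for i, g in enumerate(genes) if g not in members]
            oracle = stats.ks_2samp(
                ranks_in, ranks_out, alternative="greater", method="asymp"
            ).statistic
            assert es == pytest.approx(oracle, abs=1e-12)

    def test_unreachable_pathway_rejected(self):
        ranked = ranked_from_scores(["g1", "g2", "g3"], [0.5, 0.4, 0.0])
        with pytest.raises(ValueError, match="unreachable"):
            enrichment_score(ranked, pw({"g3"}))


class TestCoreGenes:
    def test_toy_core_set(self, toy_ranked):
        es, peak, _ = enrichment_score(toy_ranked, pw({"g1", "g3"}))
        assert core_genes(toy_ranked, pw({"g1", "g3"}), peak) == ["g1", "g3"]

    def test_single_core_gene_at_rank_one(self, toy_ranked):
        assert core_genes(toy_ranked, pw({"g1"}), 1) == ["g1"]

    def test_members_after_peak_excluded_with_warning(self, toy_ranked, caplog):
        with caplog.at_level(logging.WARNING):
            out = core_genes(toy_ranked, pw({"g4", "g5"}), 2)
        assert out == []
        assert any("empty core" in rec.message for rec in caplog.records)


class TestEmpiricalPvalue:
    def test_strict_count_rule(self):
        assert empirical_pvalue(0.6, [0.2, 0.5, 0.7, 0.9]) == 0.5

    def test_observed_above_all_nulls(self):
        assert empirical_pvalue(0.99, [0.1, 0.2, 0.3]) == 0.0

    def test_pseudocount_variant(self):
        assert empirical_pvalue(0.99, [0.1, 0.2, 0.3], pseudocount=True) == 0.25


class TestPermutationTest:
    def test_planted_pathway_significant(self, synthetic_net, synthetic_bundle):
        prop = rank_coding_genes(
            rwr(synthetic_net, set(synthetic_bundle.seeds)), synthetic_net
        )
        pathways = [synthetic_bundle.planted_pathway,
                    *synthetic_bundle.decoy_pathways[:5]]
        observed = {
            p.pathway_id: enrichment_score(prop, p)[0] for p in pathways
        }
        out = permutation_test(
            synthetic_net, observed, pathways,
            seed_count=len(prop.seed_ids), n_permutations=100, rng_seed=5,
        )
        assert out["PLANTED"].p_value <= 0.02
        assert all(o.n_permutations == 100 for o in out.values())

    def test_too_few_lncrnas_rejected(self, two_node_net):
        with pytest.raises(ValueError, match="fewer"):
            permutation_test(
                two_node_net, {"P1": 0.5}, [pw({"B"})],
                seed_count=5, n_permutations=10,
            )


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(33)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFoldChangeFlags:
    def test_threshold_is_strict(self):
        core = ["up4", "up2", "down"]
        case = {"up4": [4.0, 4.0], "up2": [2.0, 2.0], "down": [0.4, 0.4]}
        ctrl = {g: [1.0, 1.0] for g in core}
        out = {r.gene: r for r in flag_differential_core_genes(core, case, ctrl)}
        assert out["up4"].flagged          # FC = 4
        assert not out["up2"].flagged      # FC = 2 exactly: not flagged
        assert out["down"].flagged         # FC = 0.4

    def test_missing_gene_not_evaluable(self):
        out = flag_differential_core_genes(["g1"], {}, {"g1": [1.0]})
        assert not out[0].evaluable and not out[0].flagged

    def test_zero_denominator_uses_pseudocount(self):
        (r,) = flag_differential_core_genes(
            ["g1"], {"g1": [1.0]}, {"g1": [0.0]}
        )
        assert r.used_pseudocount and r.flagged
        assert r.log2_fc == pytest.approx(np.log2(1.0 / 0.01))
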