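"""Pathway-pair TF-sharing enrichment and regional-enrichment ranking."""

import math

import pytest

from bindnet import build_network, pairwise_pathway_sharing, regional_enrichment_rank
from bindnet.pairs import PathwayPairResult, sharing_graph, to_dataframe
from bindnet.stats import EnrichmentResult
from helpers import oracle_fisher_greater


def _network_from_sets(tf_sets):
    """Build a network where pathway membership mirrors the given TF sets."""
    edges = []
    pathway_table = {}
    for pw, tfs in tf_sets.items():
        prom = f"P_{pw}"
        pathway_table[prom] = {pw}
        edges += [(tf, prom) for tf in tfs]
    return build_network(edges, pathway_table=pathway_table)


def _pair_result(results, pa, pb):
    return next(r for r in results if {r.pathway_a, r.pathway_b} == {pa, pb})


class TestPairwiseSharing:
    def test_identical_sets_match_hypergeometric_tail(self):
        tfs = {f"T{i}" for i in range(10)}
        net = _network_from_sets({"A": tfs, "B": tfs})
        (res,) = pairwise_pathway_sharing(net, universe=100)
        assert (res.n_a, res.n_b, res.n_shared) == (10, 10, 10)
        # a=10, b=0, c=0, d=90 -> P(X >= 10) with N=100, K=n=10
        assert res.enrichment.p_raw == pytest.approx(
            oracle_fisher_greater(10, 0, 0, 90), rel=1e-12
        )
        assert res.enrichment.odds_ratio == math.inf

    def test_disjoint_sets_give_p_one(self):
        net = _network_from_sets(
            {"A": {f"T{i}" for i in range(5)}, "B": {f"U{i}" for i in range(5)}}
        )
        (res,) = pairwise_pathway_sharing(net, universe=50)
        assert res.n_shared == 0
        assert res.enrichment.p_raw == 1.0

    def test_symmetric_in_pathway_order(self):
        net = _network_from_sets(
            {"A": {"T1", "T2", "T3"}, "B": {"T2", "T3", "T4", "T5"}}
        )
        (res,) = pairwise_pathway_sharing(net, universe=30)
        # swapping the roles of the two sets transposes b and c only
        swapped = oracle_fisher_greater(2, 2, 1, 25)
        assert res.enrichment.p_raw == pytest.approx(swapped, rel=1e-12)
        assert res.enrichment.odds_ratio == pytest.approx((2 * 25) / (1 * 2))

    def test_universe_too_small_raises(self):
        net = _network_from_sets({"A": {"T1", "T2"}, "B": {"T3"}})
        with pytest.raises(ValueError, match="universe"):
            pairwise_pathway_sharing(net, universe=2)

    def test_single_pathway_warns_and_returns_empty(self):
        net = _network_from_sets({"A": {"T1"}})
        with pytest.warns(UserWarning, match="fewer than two"):
            assert pairwise_pathway_sharing(net, universe=10) == []

    def test_adjustment_spans_all_pairs(self, small_sim):
        results = pairwise_pathway_sharing(small_sim.network, universe=500)
        n_pathways = len(small_sim.network.pathway_labels())
        assert len(results) == n_pathways * (n_pathways - 1) // 2
        for r in results:
            assert r.enrichment.p_adj >= r.enrichment.p_raw - 1e-12
            assert r.n_shared <= min(r.n_a, r.n_b)

    def test_shrinking_universe_never_decreases_one_tailed_p(self):
        # fixed a, b, c: a larger universe makes the same overlap more
        # surprising, so p is non-increasing in d (and a smaller universe can
        # only weaken the evidence of sharing)
        a, b, c = 4, 3, 2
        ps = [oracle_fisher_greater(a, b, c, d) for d in range(1, 40)]
        assert all(x >= y - 1e-15 for x, y in zip(ps, ps[1:]))
        net = _network_from_sets(
            {"A": {f"T{i}" for i in range(7)}, "B": {f"T{i}" for i in range(4, 10)}}
        )
        p_small = pairwise_pathway_sharing(net, universe=12)[0].enrichment.p_raw
        p_large = pairwise_pathway_sharing(net, universe=60)[0].enrichment.p_raw
        assert p_small >= p_large


def _result(pa, pb, n_shared, p_adj, odds_ratio):
    enr = EnrichmentResult(odds_ratio, p_adj, "greater", p_adj=p_adj, adjust_method="BH")
    score = math.nan if math.isnan(odds_ratio) else (
        math.inf if odds_ratio == 0 else p_adj / odds_ratio
    )
    return PathwayPairResult(pa, pb, 10, 10, n_shared, 100, enr, regional_score=score)


class TestRegionalRank:
    def test_single_partner_gets_rank_one(self):
        ranked = regional_enrichment_rank([_result("GSL", "MET", 5, 0.01, 2.0)], "GSL")
        assert [r.rank for r in ranked] == [1]

    def test_score_ordering(self):
        results = [
            _result("GSL", "MET", 5, 0.001, 5.0),   # score 2e-4
            _result("GSL", "TCA", 5, 0.01, 2.0),    # score 5e-3
        ]
        ranked = regional_enrichment_rank(results, "GSL")
        assert [(r.rank, r.partner_of("GSL")) for r in ranked] == [(1, "MET"), (2, "TCA")]

    def test_zero_odds_ratio_ranks_last(self):
        results = [
            _result("GSL", "MET", 5, 0.001, 0.0),
            _result("GSL", "TCA", 5, 0.9, 1.0),
        ]
        ranked = regional_enrichment_rank(results, "GSL")
        assert ranked[-1].partner_of("GSL") == "MET"
        assert math.isinf(ranked[-1].regional_score)

    def test_undefined_odds_ratio_excluded_with_warning(self):
        results = [
            _result("GSL", "MET", 0, 1.0, math.nan),
            _result("GSL", "TCA", 5, 0.9, 1.0),
        ]
        with pytest.warns(UserWarning, match="undefined"):
            ranked = regional_enrichment_rank(results, "GSL")
        assert [r.partner_of("GSL") for r in ranked] == ["TCA"]

    def test_ties_break_by_shared_count_then_label(self):
        results = [
            _result("GSL", "MET", 3, 0.01, 2.0),
            _result("GSL", "CYS", 7, 0.01, 2.0),
            _result("GSL", "ALA", 3, 0.01, 2.0),
        ]
        ranked = regional_enrichment_rank(results, "GSL")
        assert [r.partner_of("GSL") for r in ranked] == ["CYS", "ALA", "MET"]

    def test_missing_focal_pathway_raises(self):
        with pytest.raises(KeyError):
            regional_enrichment_rank([_result("A", "B", 1, 0.5, 1.0)], "ZZZ")


class TestPlantedPairRecovery:
    def test_planted_pair_detected_single_seed(self):
        from bindnet.simulate import NetworkSimSpec, simulate_network

        spec = NetworkSimSpec(
            seed=13,
            overlap_genes=(),
            planted_pairs=(("METHIONINE_BIOSYNTHESIS", "CYSTEINE_BIOSYNTHESIS", 15.0),),
        )
        sim = simulate_network(spec)
        results = pairwise_pathway_sharing(sim.network, universe=spec.n_tfs)
        best = min(results, key=lambda r: r.enrichment.p_adj)
        assert {best.pathway_a, best.pathway_b} == {
            "METHIONINE_BIOSYNTHESIS", "CYSTEINE_BIOSYNTHESIS",
        }
        planted = _pair_result(
            results, "METHIONINE_BIOSYNTHESIS", "CYSTEINE_BIOSYNTHESIS"
        )
        assert planted.enrichment.odds_ratio > 5
        assert min(planted.n_a, planted.n_b) >= 30

    def test_outputs_round_trip_to_frame_and_graph(self, small_sim):
        results = pairwise_pathway_sharing(small_sim.network, universe=500)
        df = to_dataframe(results)
        assert len(df) == len(results)
        g = sharing_graph(results)
        assert g.number_of_edges() == len(results)
        labels = small_sim.network.pathway_labels()
        assert set(g.nodes) == labels
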