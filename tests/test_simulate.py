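"""Synthetic-data generators: determinism, calibration, round-trips."""

import math

import numpy as np
import pytest

from bindnet import read_edge_list, read_family_table, read_pathway_table
from bindnet.coexpression import edge_correlations
from bindnet.compartments import resolve_localization
from bindnet.simulate import (
    CoexprSimSpec,
    NetworkSimSpec,
    SimulationSpecError,
    default_coexpression_spec,
    simulate_coexpression,
    simulate_deg_set,
    simulate_network,
    write_network_tables,
)
from bindnet.validation import target_deg_enrichment


def _uniform_spec(seed, base, n_tfs=500, n_genes=200):
    return NetworkSimSpec(
        seed=seed,
        n_tfs=n_tfs,
        pathways=tuple((f"PW{i:02d}", n_genes // 10) for i in range(10)),
        overlap_genes=(),
        base_binding_prob=base,
        breadth_sigma=0.0,
        planted_pairs=(),
        planted_family_bias=(),
    )


class TestNetworkGenerator:
    def test_zero_base_prob_gives_no_edges(self):
        assert simulate_network(_uniform_spec(0, 0.0)).network.n_edges == 0

    def test_unit_base_prob_gives_complete_graph(self):
        sim = simulate_network(_uniform_spec(0, 1.0, n_tfs=20, n_genes=10))
        assert sim.network.n_edges == 20 * 10

    def test_density_within_binomial_bound(self):
        base, n_tfs, n_genes = 0.05, 500, 200
        sim = simulate_network(_uniform_spec(123, base, n_tfs, n_genes))
        n_trials = n_tfs * n_genes
        sd = math.sqrt(n_trials * base * (1 - base))
        assert abs(sim.network.n_edges - n_trials * base) <= 3 * sd

    def test_same_seed_reproduces_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            write_network_tables(simulate_network(NetworkSimSpec(seed=5)), tmp_path / sub)
        for name in ("edges.tsv", "pathways.tsv", "families.tsv", "localization.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        e1 = simulate_network(NetworkSimSpec(seed=1)).network.edges
        e2 = simulate_network(NetworkSimSpec(seed=2)).network.edges
        assert e1 != e2

    def test_generated_files_round_trip_through_readers(self, tmp_path):
        sim = simulate_network(NetworkSimSpec(seed=9))
        paths = write_network_tables(sim, tmp_path)
        import pandas as pd

        loc_calls = resolve_localization(pd.read_csv(paths["localization"], sep="\t"))
        net = read_edge_list(
            paths["edges"],
            pathway_table=read_pathway_table(paths["pathways"]),
            family_table=read_family_table(paths["families"]),
            localization={g: (c.enzyme_step, c.compartment, c.evidence)
                          for g, c in loc_calls.items()},
        )
        assert net.edges == sim.network.edges
        assert all(net.promoter_index[p].pathways for p in net.promoter_ids)

    def test_invalid_specs_rejected(self):
        with pytest.raises(SimulationSpecError):
            NetworkSimSpec(base_binding_prob=1.5)
        with pytest.raises(SimulationSpecError):
            NetworkSimSpec(pathways=(("A", 0),))
        with pytest.raises(SimulationSpecError):
            simulate_network(NetworkSimSpec(planted_pairs=(("NOPE", "ALSO_NOPE", 2.0),)))


class TestCoexpressionGenerator:
    def test_rho_one_copies_profile_exactly(self, small_sim):
        net = small_sim.network
        tf, tg = sorted(net.edges)[0]
        spec = CoexprSimSpec(datasets=(("d1", 10),), planted_edges=((tf, tg, "d1", 1.0),))
        (ds,) = simulate_coexpression(spec, net)
        assert np.allclose(ds.values.loc[tf], ds.values.loc[tg])

    def test_null_edges_rarely_pass_threshold(self, small_sim):
        # no planted structure: |r| >= 0.8 at n = 40 is a far-tail event
        net = small_sim.network
        n_pass = n_total = 0
        for seed in range(3):
            spec = CoexprSimSpec(datasets=(("d1", 40),), seed=seed)
            datasets = simulate_coexpression(spec, net)
            for prof in edge_correlations(net, datasets):
                n_total += 1
                n_pass += abs(prof.r_by_dataset["d1"]) >= 0.8
        assert n_total >= 500
        assert n_pass / n_total <= 0.01

    def test_planted_r09_mean_sample_r(self, small_sim):
        net = small_sim.network
        spec = default_coexpression_spec(net, seed=0, n_planted_per_dataset=40, rho=0.9,
                                         datasets=(("d1", 50),))
        datasets = simulate_coexpression(spec, net)
        planted = {(t, g) for t, g, _, _ in spec.planted_edges}
        rs = [p.r_by_dataset["d1"] for p in edge_correlations(net, datasets)
              if (p.tf_id, p.target_id) in planted]
        assert len(rs) == 40
        assert 0.85 <= float(np.mean(rs)) <= 0.93

    def test_conflicting_plantings_rejected(self, small_sim):
        tf, tg = sorted(small_sim.network.edges)[0]
        with pytest.raises(SimulationSpecError, match="conflicting"):
            CoexprSimSpec(
                datasets=(("d1", 10),),
                planted_edges=((tf, tg, "d1", 0.9), ("OTHER_TF", tg, "d1", 0.5)),
            )
        with pytest.raises(SimulationSpecError, match="unknown dataset"):
            CoexprSimSpec(datasets=(("d1", 10),), planted_edges=((tf, tg, "d9", 0.9),))

    def test_planted_edge_must_exist(self, small_sim):
        spec = CoexprSimSpec(datasets=(("d1", 10),),
                             planted_edges=(("TF9999", "NOGENE", "d1", 0.9),))
        with pytest.raises(SimulationSpecError, match="not in the network"):
            simulate_coexpression(spec, small_sim.network)


class TestDEGGenerator:
    def test_null_odds_overlap_matches_hypergeometric_moments(self):
        universe, k, n_deg = 1000, 50, 100
        overlaps = []
        for seed in range(200):
            deg, targets = simulate_deg_set(universe, k, n_deg, 1.0, seed=seed)
            overlaps.append(len(deg.genes & targets))
        mean_exp = n_deg * k / universe
        var = (n_deg * k / universe) * ((universe - k) / universe) * (universe - n_deg) / (universe - 1)
        se = math.sqrt(var / 200)
        assert abs(float(np.mean(overlaps)) - mean_exp) <= 3 * se

    def test_extreme_odds_saturates_overlap(self):
        deg, targets = simulate_deg_set(500, 50, 100, 1e6, seed=0)
        assert len(deg.genes & targets) == len(targets)

    def test_determinism_and_seed_sensitivity(self):
        a1, _ = simulate_deg_set(500, 50, 100, 4.0, seed=3)
        a2, _ = simulate_deg_set(500, 50, 100, 4.0, seed=3)
        b, _ = simulate_deg_set(500, 50, 100, 4.0, seed=4)
        assert a1.genes == a2.genes
        assert a1.genes != b.genes

    def test_planted_odds_ratio_recovered_single_seed(self):
        deg, targets = simulate_deg_set(5000, 100, 400, 4.0, seed=1)
        res = target_deg_enrichment(deg, targets)
        assert res.p_raw < 0.05
        assert 2 < res.odds_ratio < 8

    def test_infeasible_specs_rejected(self):
        with pytest.raises(SimulationSpecError):
            simulate_deg_set(100, 50, 200, 4.0)
        with pytest.raises(SimulationSpecError):
            simulate_deg_set(100, 50, 20, -1.0)
        with pytest.raises(SimulationSpecError):
            simulate_deg_set(100, 200, 20, 4.0)
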