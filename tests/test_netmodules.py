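import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prognet.dataio import ExpressionMatrix, GeneSetCollection, InteractionNetwork
from prognet.errors import InputError
from prognet.netmodules import (
    enrich_module,
    filter_modules,
    hypergeom_tail,
    map_to_network,
    mcl_cluster,
    mean_pairwise_correlation,
    select_outcome_probes,
    weight_edges,
)
from prognet.synthio import PlantedModule, SyntheticConfig, generate_cohort


def _expr(values, probes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def _clique_graph(*cliques, bridges=()):
    g = nx.Graph()
    for nodes in cliques:
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                g.add_edge(a, b, weight=1.0)
    for a, b, w in bridges:
        g.add_edge(a, b, weight=w)
    return g


class TestSelectOutcomeProbes:
    def test_planted_module_selected_poor(self):
        cfg = SyntheticConfig(
            n_genes=60, n_samples=300,
            planted_modules=[PlantedModule(12, "poor", 0.8)],
            within_module_corr=0.6, censoring_rate=0.25, seed=19,
        )
        truth, _, expr, surv = generate_cohort(cfg)
        outcome = select_outcome_probes(expr, surv)
        module = cfg.module_gene_ids[0]
        selected = outcome.table.loc[module]
        frac = (selected["selected"] & (selected["direction"] == "poor")).mean()
        assert frac >= 0.8

    def test_null_type_one_calibration(self):
        cfg = SyntheticConfig(n_genes=1000, n_samples=200, seed=31)
        truth, _, expr, surv = generate_cohort(cfg)
        outcome = select_outcome_probes(expr, surv)
        frac = outcome.table["selected"].mean()
        assert 0.03 <= frac <= 0.07

    def test_alpha_zero_selects_nothing(self, exp_survival, rng):
        probes = [f"p{i}" for i in range(5)]
        expr = _expr(rng.normal(7, 1, (5, 200)), probes, exp_survival.sample_ids)
        outcome = select_outcome_probes(expr, exp_survival, alpha=0.0)
        assert outcome.selected_probes == []

    def test_sample_mismatch_rejected(self, exp_survival, rng):
        expr = _expr(rng.normal(7, 1, (3, 4)), ["a", "b", "c"], ["x1", "x2", "x3", "x4"])
        with pytest.raises(InputError):
            select_outcome_probes(expr, exp_survival)


class TestMapToNetwork:
    def _outcome(self, probes, selected, variance=None):
        table = pd.DataFrame(
            {
                "beta": 0.5,
                "se": 0.1,
                "hazard_ratio": 1.6,
                "p_value": [0.01 if s else 0.5 for s in selected],
                "variance": variance if variance is not None else 1.0,
                "direction": "poor",
                "selected": selected,
            },
            index=probes,
        )
        from prognet.netmodules import OutcomeProbeSet

        return OutcomeProbeSet(table, 0.05)

    def test_induced_subgraph(self):
        net = InteractionNetwork(nx.Graph([("A", "B"), ("C", "D")]))
        outcome = self._outcome(["A", "B", "C"], [True, True, True])
        sub, g2p, unmapped = map_to_network(outcome, net)
        assert set(sub.nodes) == {"A", "B", "C"}
        assert list(sub.edges) == [("A", "B")]

    def test_highest_variance_probe_retained(self):
        net = InteractionNetwork(nx.Graph([("G1", "G2")]))
        outcome = self._outcome(["p_lo", "p_hi", "p2"], [True, True, True], [0.5, 2.0, 1.0])
        mapping = {"p_lo": "G1", "p_hi": "G1", "p2": "G2"}
        sub, g2p, _ = map_to_network(outcome, net, mapping)
        assert g2p["G1"] == "p_hi"

    def test_no_mapped_probe_rejected(self):
        net = InteractionNetwork(nx.Graph([("X", "Y")]))
        outcome = self._outcome(["A"], [True])
        with pytest.raises(InputError):
            map_to_network(outcome, net)


class TestWeightEdges:
    def test_identical_probes_weight_one(self):
        sub = nx.Graph([("a", "b")])
        expr = _expr([[1, 2, 3, 4], [1, 2, 3, 4]], ["a", "b"])
        wnet = weight_edges(sub, expr)
        assert wnet.graph["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_negation_weight_one(self):
        sub = nx.Graph([("a", "b")])
        expr = _expr([[1, 2, 3, 4], [-1, -2, -3, -4]], ["a", "b"])
        wnet = weight_edges(sub, expr)
        assert wnet.graph["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_independent_noise_low_weight(self, rng):
        sub = nx.Graph([("a", "b")])
        expr = _expr(rng.normal(0, 1, (2, 2000)), ["a", "b"])
        wnet = weight_edges(sub, expr)
        assert wnet.graph["a"]["b"]["weight"] < 0.1

    def test_zero_variance_weight_zero(self, caplog):
        sub = nx.Graph([("a", "b")])
        expr = _expr([[5, 5, 5, 5], [1, 2, 3, 4]], ["a", "b"])
        with caplog.at_level("WARNING"):
            wnet = weight_edges(sub, expr)
        assert wnet.graph["a"]["b"]["weight"] == 0.0

    def test_too_few_samples_rejected(self):
        sub = nx.Graph([("a", "b")])
        expr = _expr([[1, 2], [3, 4]], ["a", "b"])
        with pytest.raises(InputError):
            weight_edges(sub, expr)


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = _clique_graph(["a", "b", "c"], ["x", "y", "z"])
        res = mcl_cluster(g)
        assert sorted(map(sorted, res.clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_clique_one_cluster(self):
        g = _clique_graph(list("abcdef"))
        res = mcl_cluster(g)
        assert len(res.clusters) == 1
        assert res.clusters[0] == set("abcdef")

    def test_bridged_cliques_split_at_bridge(self):
        left = [f"l{i}" for i in range(6)]
        right = [f"r{i}" for i in range(6)]
        g = _clique_graph(left, right, bridges=[("l0", "r0", 0.1)])
        res = mcl_cluster(g, inflation=2.0)
        assert sorted(map(sorted, res.clusters)) == [sorted(left), sorted(right)]

    def test_partition_axioms_random_graphs(self, rng):
        for seed in range(10):
            g = nx.gnp_random_graph(25, 0.15, seed=seed)
            nx.set_edge_attributes(g, 1.0, "weight")
            res = mcl_cluster(g)
            union = set().union(*res.clusters) if res.clusters else set()
            assert union == set(g.nodes)
            assert sum(len(c) for c in res.clusters) == g.number_of_nodes()

    def test_components_never_merged(self, rng):
        for seed in range(5):
            g1 = nx.gnp_random_graph(12, 0.4, seed=seed)
            g2 = nx.gnp_random_graph(12, 0.4, seed=seed + 100)
            g = nx.disjoint_union(g1, g2)
            nx.set_edge_attributes(g, 1.0, "weight")
            res = mcl_cluster(g)
            for cluster in res.clusters:
                assert all(n < 12 for n in cluster) or all(n >= 12 for n in cluster)

    def test_column_stochasticity(self):
        g = _clique_graph(list("abcdef"), list("uvwxyz"), bridges=[("a", "u", 0.3)])
        res = mcl_cluster(g)
        assert res.max_colsum_deviation < 1e-10

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            mcl_cluster(nx.Graph())

    def test_determinism(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        a = mcl_cluster(g)
        b = mcl_cluster(g)
        assert a.clusters == b.clusters


class TestFilterModules:
    def _outcome_for(self, genes):
        from prognet.netmodules import OutcomeProbeSet

        table = pd.DataFrame(
            {
                "beta": 0.5, "se": 0.1, "hazard_ratio": 1.6, "p_value": 0.01,
                "variance": 1.0, "direction": "poor", "selected": True,
            },
            index=list(genes),
        )
        return OutcomeProbeSet(table, 0.05)

    def _correlated_expr(self, genes, rho, n=400, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(n)
        lam = math.sqrt(rho / (1 - rho)) if rho > 0 else 0.0
        values = 7.0 + lam * f + rng.standard_normal((len(genes), n))
        return _expr(values, list(genes))

    def test_small_cluster_rejected(self):
        genes = [f"g{i}" for i in range(7)]
        expr = self._correlated_expr(genes, 0.9)
        mods = filter_modules([set(genes)], expr, self._outcome_for(genes), min_size=8)
        assert mods == []

    def test_correlation_boundary_inclusive(self, monkeypatch):
        genes = [f"g{i}" for i in range(10)]
        expr = self._correlated_expr(genes, 0.5)
        outcome = self._outcome_for(genes)
        import prognet.netmodules as nm

        for fake_r, expected in ((0.25, 1), (0.2499, 0)):
            monkeypatch.setattr(
                nm, "mean_pairwise_correlation", lambda *a, **k: fake_r
            )
            mods = nm.filter_modules([set(genes)], expr, outcome)
            assert len(mods) == expected

    def test_numbering_by_decreasing_size(self):
        big = [f"b{i:02d}" for i in range(12)]
        small = [f"s{i:02d}" for i in range(9)]
        rng = np.random.default_rng(3)
        f1, f2 = rng.standard_normal(300), rng.standard_normal(300)
        values = np.vstack(
            [7 + 2 * f1 + rng.standard_normal((12, 300)) * 0.5,
             7 + 2 * f2 + rng.standard_normal((9, 300)) * 0.5]
        )
        expr = _expr(values, big + small)
        mods = filter_modules(
            [set(small), set(big)], expr, self._outcome_for(big + small)
        )
        assert [m.module_id for m in mods] == [0, 1]
        assert mods[0].size == 12 and mods[1].size == 9

    def test_non_disjoint_clusters_rejected(self, small_expr):
        with pytest.raises(InputError):
            filter_modules(
                [{"P0", "P1"}, {"P1", "P2"}], small_expr, self._outcome_for(["P0", "P1", "P2"])
            )

    def test_input_order_invariance(self):
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        rng = np.random.default_rng(5)
        f1, f2 = rng.standard_normal(300), rng.standard_normal(300)
        values = np.vstack(
            [7 + f1 + rng.standard_normal((10, 300)) * 0.5,
             7 + f2 + rng.standard_normal((10, 300)) * 0.5]
        )
        expr = _expr(values, a + b)
        outcome = self._outcome_for(a + b)
        m1 = filter_modules([set(a), set(b)], expr, outcome)
        m2 = filter_modules([set(b), set(a)], expr, outcome)
        assert [m.genes for m in m1] == [m.genes for m in m2]

    def test_signed_vs_absolute_mode(self):
        # anti-correlated pair: signed mean is negative, absolute is high
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        expr = _expr(np.vstack([7 + x, 7 - x]), ["a", "b"])
        signed = mean_pairwise_correlation({"a", "b"}, expr, mode="signed")
        absolute = mean_pairwise_correlation({"a", "b"}, expr, mode="absolute")
        assert signed < -0.9
        assert absolute > 0.9


def oracle_hypergeom_tail(k, M, K, n):
    """Exact combinatorial oracle: sum of pmf terms via math.comb."""
    total = math.comb(M, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= M - K:
            acc += math.comb(K, i) * math.comb(M - K, n - i)
    return acc / total


class TestEnrichment:
    def test_whole_set_overlap_matches_oracle(self):
        universe = [f"g{i}" for i in range(1000)]
        module = universe[:10]
        sets = GeneSetCollection({"target": set(module)})
        res = enrich_module(module, sets, universe)
        expected = oracle_hypergeom_tail(10, 1000, 10, 10)
        assert res.table.loc["target", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_all_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection({"s1": set(universe[20:30]), "s2": set(universe[30:40])})
        res = enrich_module(universe[:5], sets, universe)
        assert (res.table["p_value"] == 1.0).all()
        assert (res.table["fdr"] == 1.0).all()

    def test_duplicated_set_identical_p(self):
        universe = [f"g{i}" for i in range(100)]
        member = set(universe[:15])
        sets = GeneSetCollection({"a": member, "b": set(member)})
        res = enrich_module(universe[:8], sets, universe)
        assert res.table.loc["a", "p_value"] == res.table.loc["b", "p_value"]
        assert res.table.loc["a", "fdr"] == res.table.loc["b", "fdr"]

    def test_gene_outside_universe_rejected(self):
        sets = GeneSetCollection({"s": {"g1"}})
        with pytest.raises(InputError):
            enrich_module(["g1", "alien"], sets, ["g1", "g2"])

    def test_fdr_monotone_in_p(self, rng):
        universe = [f"g{i}" for i in range(200)]
        module = universe[:20]
        sets = {}
        for j in range(8):
            members = set(rng.choice(universe, size=30, replace=False))
            sets[f"s{j}"] = members
        res = enrich_module(module, GeneSetCollection(sets), universe)
        p = res.table["p_value"].to_numpy()
        fdr = res.table["fdr"].to_numpy()
        assert (np.diff(p) >= -1e-12).all()
        assert (np.diff(fdr) >= -1e-12).all()

    def test_tail_function_matches_oracle_sampled(self):
        for M in (12, 29, 47, 60):
            for K in range(0, M + 1, 7):
                for n in range(0, M + 1, 5):
                    for k in range(0, min(K, n) + 1, 3):
                        assert hypergeom_tail(k, M, K, n) == pytest.approx(
                            oracle_hypergeom_tail(k, M, K, n), rel=1e-9, abs=1e-12
                        )
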