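from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnwaves.de import ConsensusDEResult
from grnwaves.network import (
    EnrichmentUrn,
    PriorEdgeSet,
    backbone_hierarchy,
    bridging_tfs,
    build_wave_network,
    integrate_validated_edges,
    load_prior_edges,
    rank_tfs,
    tf_centrality,
    tf_enrichment,
)
from grnwaves.perturbation import ValidatedEdge
from grnwaves.waves import Wave


def make_consensus(directions: dict[str, str]) -> ConsensusDEResult:
    genes = sorted(directions)
    table = pd.DataFrame(
        {
            "wald": True,
            "lrt": True,
            "timecourse": True,
            "consensus": True,
            "direction": [directions[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return ConsensusDEResult(table, "agree_by_two", 0.05)


class TestLoadPrior:
    def test_duplicate_rows_deduplicated(self, tmp_path):
        p = tmp_path / "prior.tsv"
        p.write_text("A\tB\nA\tB\nA\tC\n")
        prior = load_prior_edges(p)
        assert prior.edges == {("A", "B"), ("A", "C")}

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "prior.tsv"
        p.write_text("")
        with pytest.warns(UserWarning):
            prior = load_prior_edges(p)
        assert prior.edges == set()

    def test_malformed_row_errors_with_line_number(self, tmp_path):
        p = tmp_path / "prior.tsv"
        p.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(ValueError, match=":2"):
            load_prior_edges(p)

    def test_sign_column_parsed(self, tmp_path):
        p = tmp_path / "prior.tsv"
        p.write_text("A\tB\tup\nA\tC\tdown\n")
        prior = load_prior_edges(p)
        assert prior.signs == {("A", "B"): "up", ("A", "C"): "down"}


class TestBuildWaveNetwork:
    def test_both_endpoints_de_gives_edge(self):
        wave = Wave("early", (1.0, 2.0), {"A", "B"})
        cons = make_consensus({"A": "up", "B": "down"})
        net = build_wave_network(wave, cons, {"A"}, PriorEdgeSet({("A", "B")}))
        assert set(net.nodes) == {"A", "B"}
        assert net.nodes["A"]["is_tf"] and not net.nodes["B"]["is_tf"]
        assert net["A"]["B"]["provenance"] == "prior"

    def test_non_de_target_excluded(self):
        wave = Wave("early", (1.0, 2.0), {"A"})
        cons = make_consensus({"A": "up"})
        net = build_wave_network(wave, cons, {"A"}, PriorEdgeSet({("A", "B")}))
        assert set(net.nodes) == {"A"} and net.number_of_edges() == 0

    def test_empty_network_warns(self):
        wave = Wave("early", (1.0, 2.0), set())
        cons = make_consensus({})
        with pytest.warns(UserWarning):
            net = build_wave_network(wave, cons, {"A"}, PriorEdgeSet(set()))
        assert net.number_of_nodes() == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_comprehension_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]
        tfs = set(genes[:12])
        de = set(rng.choice(genes, size=30, replace=False))
        edges = {
            (a, b)
            for a in tfs
            for b in genes
            if a != b and rng.random() < 0.15
        }
        wave = Wave("early", (1.0,), de)
        cons = make_consensus({g: "up" for g in de})
        net = build_wave_network(wave, cons, tfs, PriorEdgeSet(edges))
        # independent oracle straight from the construction rule
        de_tfs = de & tfs
        expected_edges = {(a, b) for (a, b) in edges if a in de_tfs and b in de and a != b}
        expected_nodes = de_tfs | {b for _, b in expected_edges}
        assert set(net.edges) == expected_edges
        assert set(net.nodes) == expected_nodes

    def test_node_and_edge_sets_invariant_to_input_order(self):
        wave = Wave("early", (1.0,), {"A", "B", "C"})
        cons = make_consensus({"A": "up", "B": "down", "C": "up"})
        e1 = PriorEdgeSet({("A", "B"), ("A", "C"), ("B", "C")})
        n1 = build_wave_network(wave, cons, {"A", "B"}, e1)
        n2 = build_wave_network(wave, cons, {"B", "A"}, e1)
        assert set(n1.edges) == set(n2.edges)


class TestIntegrateValidated:
    def _ctx(self):
        wave = Wave("early", (1.0,), {"X", "Y", "Z"})
        cons = make_consensus({"X": "up", "Y": "up", "Z": "down"})
        net = build_wave_network(wave, cons, {"X"}, PriorEdgeSet({("X", "Y")}))
        return net, wave, cons

    def _net(self):
        return self._ctx()[0]

    def test_new_edge_to_wave_de_target_adds_node_and_edge(self):
        net, wave, cons = self._ctx()
        out = integrate_validated_edges(
            net, [ValidatedEdge("X", "Z", "down", 0.01)], wave, cons, {"X"}
        )
        assert out["X"]["Z"]["provenance"] == "validated"
        assert out["X"]["Z"]["sign"] == "down"
        assert out.nodes["Z"]["de_direction"] == "down"

    def test_duplicate_of_prior_edge_becomes_both(self):
        net = integrate_validated_edges(
            self._net(), [ValidatedEdge("X", "Y", "up", 0.01)]
        )
        assert net["X"]["Y"]["provenance"] == "both"
        assert net["X"]["Y"]["sign"] == "up"

    def test_target_outside_wave_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            net = integrate_validated_edges(
                self._net(), [ValidatedEdge("X", "W", "up", 0.01)]
            )
        assert "W" not in net

    def test_sign_conflict_resolved_toward_validation_and_flagged(self):
        wave = Wave("early", (1.0,), {"X", "Y"})
        cons = make_consensus({"X": "up", "Y": "up"})
        prior = PriorEdgeSet({("X", "Y")}, {("X", "Y"): "down"})
        net = build_wave_network(wave, cons, {"X"}, prior)
        net = integrate_validated_edges(net, [ValidatedEdge("X", "Y", "up", 0.01)])
        assert net["X"]["Y"]["sign"] == "up"
        assert net["X"]["Y"]["sign_conflict"]


def hypergeom_tail_by_enumeration(N, K, n, k):
    """Exact combinatorial oracle: sum C(K,i) C(N-K,n-i) / C(N,n)."""
    denom = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
    ) / denom


class TestEnrichment:
    def test_worked_urn(self):
        # N=20, K=5, n=4, k=4: C(5,4)C(15,0)/C(20,4) = 5/4845
        p = tf_enrichment(EnrichmentUrn(20, 5, 4, 4))
        assert p == pytest.approx(5 / 4845, rel=1e-12)

    def test_k_zero_gives_one(self):
        assert tf_enrichment(EnrichmentUrn(20, 5, 4, 0)) == pytest.approx(1.0)

    def test_n_equals_N_forces_k_equals_K(self):
        assert tf_enrichment(EnrichmentUrn(10, 4, 10, 4)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            EnrichmentUrn(10, 4, 10, 3)

    def test_invalid_urns_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentUrn(10, 11, 2, 1)
        with pytest.raises(ValueError):
            EnrichmentUrn(10, 2, 3, 3)

    @given(
        st.integers(1, 30).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(0, N),
                st.integers(0, N),
            )
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_for_small_urns(self, NKn, rnd):
        N, K, n = NKn
        k_min = max(0, n - (N - K))
        k_max = min(n, K)
        k = rnd.randint(k_min, k_max)
        p = tf_enrichment(EnrichmentUrn(N, K, n, k))
        assert p == pytest.approx(
            hypergeom_tail_by_enumeration(N, K, n, k), abs=1e-12
        )


class TestCentrality:
    def test_path_centre_is_one(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        for n in g:
            g.nodes[n]["is_tf"] = True
        assert tf_centrality(g, "B") == pytest.approx(1.0)

    def test_isolated_node_is_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B", "C"])
        g.add_edge("A", "B")
        assert tf_centrality(g, "C") == 0.0

    def test_star_center_and_leaves(self):
        g = nx.DiGraph([("hub", "a"), ("hub", "b"), ("hub", "c")])
        assert tf_centrality(g, "hub") == pytest.approx(1.0)
        assert tf_centrality(g, "a") == pytest.approx(0.6)

    def test_unknown_node_errors(self):
        g = nx.DiGraph([("A", "B")])
        with pytest.raises(KeyError):
            tf_centrality(g, "Z")

    def test_harmonic_variant(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        # B: distances 1,1 -> (1+1)/2 = 1; A: 1 + 1/2 over 2 -> 0.75
        assert tf_centrality(g, "B", "harmonic") == pytest.approx(1.0)
        assert tf_centrality(g, "A", "harmonic") == pytest.approx(0.75)


def brute_force_ranking(net, prior, universe, de_genes):
    """Independent recomputation of the ranking formula."""
    from scipy.stats import hypergeom

    tfs = sorted(n for n, d in net.nodes(data=True) if d.get("is_tf"))
    und = net.to_undirected()
    rows = {}
    for tf in tfs:
        targets = {b for (a, b) in prior.edges if a == tf} & universe
        k = len(targets & de_genes)
        p = hypergeom.sf(k - 1, len(universe), len(de_genes & universe), len(targets))
        cc = nx.closeness_centrality(und, u=tf, wf_improved=True) if und.degree(tf) else 0.0
        rows[tf] = (p, cc)
    hg = {tf: -np.log10(max(p, 1e-300)) for tf, (p, _) in rows.items()}
    cent = {tf: c for tf, (_, c) in rows.items()}

    def norm(d):
        lo, hi = min(d.values()), max(d.values())
        if hi - lo < 1e-300:
            return {t: 0.5 for t in d}
        return {t: (v - lo) / (hi - lo) for t, v in d.items()}

    hg_n, cent_n = norm(hg), norm(cent)
    score = {t: (hg_n[t] + cent_n[t]) / 2 for t in tfs}
    return sorted(tfs, key=lambda t: (-score[t], rows[t][0], t))


class TestRanking:
    def _instance(self, seed, n_tfs=8, n_genes=40):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        tfs = set(genes[:n_tfs])
        de = set(rng.choice(genes, size=n_genes // 2, replace=False)) | tfs
        edges = {
            (a, b) for a in tfs for b in genes if a != b and rng.random() < 0.2
        }
        prior = PriorEdgeSet(edges)
        wave = Wave("early", (1.0,), de)
        cons = make_consensus({g: "up" for g in de})
        net = build_wave_network(wave, cons, tfs, prior)
        universe = set(genes)
        return net, prior, universe, de

    def test_strict_winner_on_both_axes_is_rank_one(self):
        genes = [f"g{i}" for i in range(20)]
        de = set(genes)
        prior = PriorEdgeSet(
            {("g0", g) for g in genes[2:]} | {("g1", "g2")}
        )
        wave = Wave("early", (1.0,), de)
        cons = make_consensus({g: "up" for g in genes})
        net = build_wave_network(wave, cons, {"g0", "g1"}, prior)
        rank = rank_tfs(net, prior, set(genes), de)
        assert rank.table.index[0] == "g0"

    def test_degenerate_spread_maps_to_half_and_lexicographic_order(self):
        genes = ["a", "b", "t1", "t2"]
        prior = PriorEdgeSet({("a", "t1"), ("b", "t2")})
        wave = Wave("early", (1.0,), set(genes))
        cons = make_consensus({g: "up" for g in genes})
        net = build_wave_network(wave, cons, {"a", "b"}, prior)
        rank = rank_tfs(net, prior, set(genes), set(genes))
        assert (rank.table["rank_score"] == 0.5).all()
        assert list(rank.table.index) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        net, prior, universe, de = self._instance(seed)
        rank = rank_tfs(net, prior, universe, de)
        assert list(rank.table.index) == brute_force_ranking(net, prior, universe, de)

    def test_rank_scores_in_unit_interval_and_total_order(self):
        net, prior, universe, de = self._instance(3)
        rank = rank_tfs(net, prior, universe, de)
        assert rank.table["rank_score"].between(0, 1).all()
        assert list(rank.table["rank"]) == list(range(1, len(rank.table) + 1))


class TestHierarchy:
    def test_directed_path_layers(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        layout = backbone_hierarchy(g, {"A", "B", "C"})
        assert layout.layers == {"A": 0, "B": 1, "C": 2}

    def test_two_cycle_with_tail(self):
        g = nx.DiGraph([("A", "B"), ("B", "A"), ("A", "C")])
        layout = backbone_hierarchy(g, {"A", "B", "C"})
        assert layout.layers["A"] == layout.layers["B"] == 0
        assert layout.layers["C"] == 1

    def test_edgeless_backbone_all_layer_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B"])
        layout = backbone_hierarchy(g, {"A", "B"})
        assert set(layout.layers.values()) == {0}

    def test_non_tf_nodes_excluded_from_backbone(self):
        g = nx.DiGraph([("A", "B"), ("A", "t")])
        layout = backbone_hierarchy(g, {"A", "B"})
        assert "t" not in layout.layers

    @pytest.mark.parametrize("seed", range(20))
    def test_condensation_edges_descend_and_sources_on_top(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        g = nx.gnp_random_graph(int(n), 0.3, seed=int(seed), directed=True)
        g = nx.relabel_nodes(g, {i: f"T{i}" for i in g.nodes})
        layout = backbone_hierarchy(g, set(g.nodes))
        cond = nx.condensation(g)
        members = {c: d["members"] for c, d in cond.nodes(data=True)}
        layer_of_scc = {
            c: layout.layers[next(iter(m))] for c, m in members.items()
        }
        for u, v in cond.edges:
            assert layer_of_scc[u] < layer_of_scc[v]
        for c in cond.nodes:
            if cond.in_degree(c) == 0:
                assert layer_of_scc[c] == 0


class TestBridging:
    def _nets(self):
        nets = {}
        for wave, tfs in (
            ("early", ["A", "B"]),
            ("intermediate", ["A"]),
            ("late", ["C"]),
        ):
            g = nx.DiGraph()
            for tf in tfs:
                g.add_node(tf, is_tf=True)
                g.add_node(f"t_{wave}_{tf}", is_tf=False)
                g.add_edge(tf, f"t_{wave}_{tf}")
            nets[wave] = g
        return nets

    def test_tf_in_two_waves_is_bridging(self):
        de = {"early": {"A", "B"}, "intermediate": {"A"}, "late": {"C"}}
        ann = bridging_tfs(self._nets(), de)
        assert ann.is_bridging("A")
        assert not ann.is_bridging("B")
        assert not ann.is_bridging("C")
        assert ann.bridging_tfs == ["A"]

    def test_tf_in_all_waves_links_three_meta_nodes(self):
        nets = self._nets()
        g = nets["late"]
        g.add_node("A", is_tf=True)
        g.add_node("t_late_A", is_tf=False)
        g.add_edge("A", "t_late_A")
        de = {"early": {"A", "B"}, "intermediate": {"A"}, "late": {"A", "C"}}
        ann = bridging_tfs(nets, de)
        assert ann.is_bridging("A")
        assert ann.combined.out_degree("A") == 3

    def test_requires_at_least_two_waves(self):
        with pytest.raises(ValueError):
            bridging_tfs({"early": nx.DiGraph()}, {"early": set()})
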