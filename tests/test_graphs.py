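"""Bipartite flux graphs, global efficiency, betweenness, power laws.

Efficiency and betweenness are checked against independent in-test
oracles: a hand-rolled BFS accumulation for efficiency and exhaustive
shortest-path enumeration (networkx all_shortest_paths) for
betweenness.
"""

from collections import deque

import networkx as nx
import numpy as np
import pytest

from minnet.errors import ContractError, ValidationError
from minnet.gpr import DeletionState
from minnet.graphs import (
    build_flux_graph,
    compare_efficiency_samples,
    cumulative_distribution,
    degree_and_betweenness,
    fit_power_law,
    gene_removal_efficiency,
    global_efficiency,
    load_gene_network,
    monte_carlo_removal,
)
from minnet.solvers import pfba


def bfs_efficiency(G):
    """Independent BFS oracle for unweighted global efficiency."""
    nodes = list(G.nodes)
    N = len(nodes)
    if N < 2:
        return 0.0
    total = 0.0
    for s in nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in G.successors(u) if G.is_directed() else G.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        total += sum(1.0 / d for v, d in dist.items() if v != s)
    return total / (N * (N - 1))


class TestGraphConstruction:
    def test_flux_mode_nodes_and_weights(self, toy1):
        state = DeletionState.from_genes(toy1, ["g1"])
        G = build_flux_graph(toy1, fluxes=pfba(toy1, state), state=state)
        assert G.number_of_nodes() == 9  # 4 metabolites + 5 active reactions
        assert "R1" not in G
        assert G.edges["T_A", "A"]["weight"] == pytest.approx(10.0, abs=1e-5)
        # the exchange imports: flux is negative, so the edge runs
        # reaction -> metabolite
        assert G.has_edge("EX_A", "A_e")

    def test_structural_mode_excludes_gpr_disabled(self, toy1):
        G = build_flux_graph(
            toy1, state=DeletionState.from_genes(toy1, ["g1", "g2"]))
        assert "R1" not in G and "R2" not in G
        assert all(d["weight"] == 1.0 for _, _, d in G.edges(data=True))

    def test_bipartite_invariant(self, toy1):
        G = build_flux_graph(toy1)
        kinds = nx.get_node_attributes(G, "kind")
        for u, v in G.edges:
            assert kinds[u] != kinds[v]

    def test_misaligned_fluxes_rejected(self, toy1):
        from minnet.solvers import FluxDistribution
        bad = FluxDistribution(np.zeros(3), 0.0, "optimal")
        with pytest.raises(ContractError):
            build_flux_graph(toy1, fluxes=bad)


class TestEfficiency:
    def test_closed_forms(self):
        assert global_efficiency(
            nx.complete_graph(6, create_using=nx.DiGraph)) == 1.0
        assert global_efficiency(
            nx.empty_graph(5, create_using=nx.DiGraph)) == 0.0
        path = nx.DiGraph([("a", "b"), ("b", "c")])
        assert global_efficiency(path) == pytest.approx(2.5 / 6)

    def test_small_graphs_convention(self):
        assert global_efficiency(nx.DiGraph()) == 0.0
        single = nx.DiGraph()
        single.add_node("x")
        assert global_efficiency(single) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bfs_oracle_on_random_digraphs(self, seed):
        G = nx.gnp_random_graph(50, 0.06, seed=seed, directed=True)
        assert global_efficiency(G) == pytest.approx(
            bfs_efficiency(G), abs=1e-12)

    def test_edge_removal_never_raises_efficiency(self):
        G = nx.gnp_random_graph(30, 0.15, seed=1, directed=True)
        base = global_efficiency(G)
        H = G.copy()
        H.remove_edges_from(list(H.edges)[:10])
        assert global_efficiency(H) <= base + 1e-12

    def test_weighted_mode_prefers_heavy_edges(self):
        G = nx.DiGraph()
        G.add_edge("a", "b", weight=10.0)
        G.add_edge("b", "c", weight=10.0)
        assert global_efficiency(G, weighted=True) > global_efficiency(G)


class TestBetweenness:
    def test_path_graph(self):
        df = degree_and_betweenness(nx.DiGraph([("a", "b"), ("b", "c")]))
        assert df.loc["b", "betweenness"] == 1
        assert df.loc["a", "betweenness"] == 0
        assert df.loc["c", "betweenness"] == 0
        assert df.loc["b", "degree"] == 2

    def test_star_degrees_and_isolated_node(self):
        G = nx.DiGraph([("h", "l1"), ("h", "l2"), ("h", "l3")])
        G.add_node("iso")
        df = degree_and_betweenness(G)
        assert df.loc["h", "degree"] == 3
        assert df.loc["iso", "degree"] == 0
        assert df.loc["iso", "betweenness"] == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_enumeration_oracle(self, seed):
        """Raw path counts match explicit all_shortest_paths enumeration
        on random digraphs with <= 8 nodes."""
        G = nx.gnp_random_graph(8, 0.3, seed=seed, directed=True)
        df = degree_and_betweenness(G)
        expected = {v: 0 for v in G}
        for s in G:
            for t in G:
                if s == t or not nx.has_path(G, s, t):
                    continue
                for p in nx.all_shortest_paths(G, s, t):
                    for v in p[1:-1]:
                        expected[v] += 1
        assert df["betweenness"].to_dict() == expected


class TestPowerLaw:
    def test_naive_closed_form(self):
        fit = fit_power_law([1, 1, 1, 2, 4], k_min=1,
                            continuity_correction=False)
        assert fit.gamma == pytest.approx(
            1 + 5 / (np.log(2) + np.log(4)), rel=1e-12)
        assert fit.n_tail == 5

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        u = rng.random(10_000)
        ks = (1 - u) ** (-1 / 1.5)  # continuous power law, gamma = 2.5
        fit = fit_power_law(ks, k_min=1.0, continuity_correction=False)
        assert fit.gamma == pytest.approx(2.5, abs=0.1)

    def test_contracts(self):
        with pytest.raises(ContractError):
            fit_power_law([3], k_min=1)
        with pytest.raises(ContractError):
            fit_power_law([1, 1, 1], k_min=1, continuity_correction=False)


class TestGeneRemoval:
    def test_empty_removal_is_baseline(self, toy1):
        baseline = global_efficiency(build_flux_graph(toy1))
        assert gene_removal_efficiency(toy1, [], mode="structural") == baseline

    def test_disconnecting_removal_lowers_efficiency(self, toy1):
        baseline = gene_removal_efficiency(toy1, [], mode="structural")
        cut = gene_removal_efficiency(toy1, ["g1", "g2"], mode="structural")
        assert cut < baseline

    def test_structural_monotone_in_removal_set(self, toy1):
        e1 = gene_removal_efficiency(toy1, ["g1"], mode="structural")
        e2 = gene_removal_efficiency(toy1, ["g1", "g3"], mode="structural")
        assert e2 <= e1 + 1e-12

    def test_flux_mode_infeasible_returns_zero(self, toy1):
        assert gene_removal_efficiency(toy1, ["gT"], mode="flux") == 0.0

    def test_unknown_gene_rejected(self, toy1):
        with pytest.raises(ContractError):
            gene_removal_efficiency(toy1, ["nope"])


class TestMonteCarlo:
    def test_k_zero_equals_baseline(self, toy1):
        baseline = gene_removal_efficiency(toy1, [], mode="structural")
        mc = monte_carlo_removal(toy1, toy1.gene_ids, k=0, n_samples=10,
                                 seed=1)
        assert np.allclose(mc["samples"], baseline)

    def test_forced_draw_is_constant(self, toy1):
        mc = monte_carlo_removal(toy1, ["g1", "g2"], k=2, n_samples=8, seed=2)
        assert len(set(mc["samples"])) == 1

    def test_seeded_reproducibility(self, toy1):
        a = monte_carlo_removal(toy1, toy1.gene_ids, k=2, n_samples=20, seed=5)
        b = monte_carlo_removal(toy1, toy1.gene_ids, k=2, n_samples=20, seed=5)
        assert np.array_equal(a["samples"], b["samples"])

    def test_pool_too_small_rejected(self, toy1):
        with pytest.raises(ContractError):
            monte_carlo_removal(toy1, ["g1"], k=2)

    def test_summary_is_boxplot_consistent(self, toy1):
        mc = monte_carlo_removal(toy1, toy1.gene_ids, k=1, n_samples=50,
                                 seed=3)
        assert mc["q1"] <= mc["median"] <= mc["q3"]
        iqr = mc["q3"] - mc["q1"]
        assert mc["whisker_low"] == pytest.approx(mc["q1"] - 1.5 * iqr)
        assert mc["whisker_high"] == pytest.approx(mc["q3"] + 1.5 * iqr)

    def test_identical_pools_rarely_significant(self, redundant_toy):
        """Under the null (both samples drawn from the same pool) the
        Mann-Whitney wrapper rejects at alpha = 0.05 about 5% of the
        time; the observed rejection rate over seeded replicates must
        stay within three binomial standard errors of that."""
        pool = [g for g in redundant_toy.gene_ids if g.startswith("L")]
        n_rep = 60
        rejections = 0
        for rep in range(n_rep):
            a = monte_carlo_removal(redundant_toy, pool, k=2, n_samples=60,
                                    seed=1000 + rep)
            b = monte_carlo_removal(redundant_toy, pool, k=2, n_samples=60,
                                    seed=5000 + rep)
            _, p = compare_efficiency_samples(a["samples"], b["samples"])
            rejections += p <= 0.05
        limit = 0.05 + 3 * (0.05 * 0.95 / n_rep) ** 0.5
        assert rejections / n_rep <= limit


class TestGeneNetwork:
    def test_triangle_efficiency(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\tc\nc\ta\n")
        G = load_gene_network(p, directed=False)
        assert global_efficiency(G) == 1.0

    def test_restriction_to_model_genes(self, toy1, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("g1\tg2\ng1\tzzz\n")
        G = load_gene_network(p, restrict_to=toy1)
        assert set(G.nodes) == {"g1", "g2"}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# only a comment\n")
        G = load_gene_network(p)
        assert G.number_of_nodes() == 0
        assert global_efficiency(G) == 0.0

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nonly_one_field\n")
        with pytest.raises(ValidationError, match="line 2"):
            load_gene_network(p)

    def test_bad_weight_reports_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\theavy\n")
        with pytest.raises(ValidationError, match="line 1"):
            load_gene_network(p)


def test_cumulative_distribution_properties():
    df = cumulative_distribution([1, 1, 2, 3])
    assert df["value"].tolist() == [1, 2, 3]
    assert df["p_ge"].tolist() == [1.0, 0.5, 0.25]
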