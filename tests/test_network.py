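import networkx as nx
import numpy as np
import pandas as pd
import pytest

from micreco.data import OtuTable
from micreco.network import (
    EcoNetwork,
    build_network,
    classify_role,
    correlation_matrix,
    detect_modules,
    network_composition,
    node_roles,
    power_law_fit_r2,
    prepare_abundance_matrix,
    random_network_baseline,
    rmt_threshold,
    topology_indices,
)


def _net_from_graph(g: nx.Graph, sign: int = 1) -> EcoNetwork:
    for u, v in g.edges():
        g[u][v].setdefault("weight", 0.9 * sign)
        g[u][v].setdefault("sign", sign)
    return EcoNetwork(graph=g, threshold=0.8)


class TestPrepare:
    def test_prevalence_filter(self):
        counts = pd.DataFrame(
            {"keep": [5, 5, 5, 5, 5, 5, 5, 5],
             "drop": [1, 2, 0, 0, 0, 0, 0, 0],
             "pad": [4, 4, 4, 4, 4, 4, 4, 4]},
            index=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame({"group": ["g"] * 8}, index=counts.index)
        table = OtuTable(counts, meta)
        prepared = prepare_abundance_matrix(table, min_prevalence=0.5)
        assert "drop" not in prepared.columns
        assert {"keep", "pad"} <= set(prepared.columns)
        prepared_all = prepare_abundance_matrix(table, min_prevalence=0.0)
        assert set(prepared_all.columns) == {"keep", "drop", "pad"}

    def test_filter_matches_brute_force_scan(self, study_bundle):
        sub = study_bundle.table.subset_group("CS")
        prepared = prepare_abundance_matrix(sub, min_prevalence=0.5)
        presence = (sub.counts > 0).mean(axis=0)
        expected = set(presence.index[presence >= 0.5])
        assert set(prepared.columns) == expected

    def test_no_survivor_is_error(self):
        counts = pd.DataFrame(
            {"a": [1, 0, 0, 0], "b": [0, 1, 0, 0], "c": [1, 1, 1, 1]},
            index=[f"s{i}" for i in range(4)],
        )
        meta = pd.DataFrame({"group": ["g"] * 4}, index=counts.index)
        with pytest.raises(ValueError):
            prepare_abundance_matrix(OtuTable(counts, meta), min_prevalence=2.0)


class TestCorrelation:
    def test_textbook_pearson(self):
        frame = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0],
             "z": [4.0, 3.0, 2.0, 1.0]}
        )
        corr = correlation_matrix(frame)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert corr.loc["x", "z"] == pytest.approx(-1.0)
        hand = np.corrcoef(frame["x"], frame["z"])[0, 1]
        assert corr.loc["x", "z"] == pytest.approx(hand)

    def test_zero_variance_dropped_with_warning(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning):
            corr = correlation_matrix(frame)
        assert "flat" not in corr.columns


class TestRmtThreshold:
    def test_block_structure_separated(self):
        """Modular blocks (within-block r ~ 0.9) riding on a dense common
        factor (between-block r ~ 0.45): the scan must reject Poisson in the
        dense noise regime and settle between the background and the blocks."""
        rng = np.random.default_rng(0)
        n_blocks, size, n_samp = 6, 15, 60
        n = n_blocks * size
        common = rng.normal(size=n_samp)
        data = np.zeros((n_samp, n))
        a, c, s = np.sqrt(0.45), np.sqrt(0.45), np.sqrt(0.10)
        for b in range(n_blocks):
            block_factor = rng.normal(size=n_samp)
            for j in range(size):
                data[:, b * size + j] = (
                    a * common + c * block_factor + s * rng.normal(size=n_samp)
                )
        corr = pd.DataFrame(np.corrcoef(data.T),
                            index=[f"o{i}" for i in range(n)],
                            columns=[f"o{i}" for i in range(n)])
        arr = corr.to_numpy().copy()
        np.fill_diagonal(arr, 0)
        block_mask = np.zeros_like(arr, dtype=bool)
        for b in range(n_blocks):
            sl = slice(b * size, (b + 1) * size)
            block_mask[sl, sl] = True
        np.fill_diagonal(block_mask, False)
        background_q90 = np.quantile(np.abs(arr[~block_mask]), 0.9)
        block_typical = np.median(np.abs(arr[block_mask]))
        st, trace = rmt_threshold(corr, start=0.30, stop=0.95, step=0.01)
        assert background_q90 < st < block_typical
        assert (trace["threshold"].diff().dropna() > 0).all()

    def test_pure_noise_is_poisson_at_scan_start(self):
        """i.i.d. data: correlations beyond 0.3 are sparse random edges, so the
        spacing is already Poisson near the start of the scan."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(60, 90))
        corr = pd.DataFrame(np.corrcoef(data.T),
                            index=[f"o{i}" for i in range(90)],
                            columns=[f"o{i}" for i in range(90)])
        st, _ = rmt_threshold(corr, start=0.30, stop=0.90, step=0.01)
        assert st <= 0.35

    def test_bad_scan_range_rejected(self):
        corr = pd.DataFrame(np.eye(5))
        with pytest.raises(ValueError):
            rmt_threshold(corr, start=0.5, stop=0.2)


class TestBuildNetwork:
    def _corr(self):
        ids = list("abcd")
        arr = np.eye(4)
        arr[0, 1] = arr[1, 0] = 0.9
        arr[2, 3] = arr[3, 2] = -0.9
        arr[0, 2] = arr[2, 0] = 0.5
        return pd.DataFrame(arr, index=ids, columns=ids)

    def test_edge_signs(self):
        net = build_network(self._corr(), st=0.8)
        assert net.graph["a"]["b"]["sign"] == 1
        assert net.graph["c"]["d"]["sign"] == -1
        assert not net.graph.has_edge("a", "c")

    def test_threshold_boundary_inclusive(self):
        net = build_network(self._corr(), st=0.5)
        assert net.graph.has_edge("a", "c")

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(-1, 1, size=(20, 20))
        arr = (raw + raw.T) / 2
        np.fill_diagonal(arr, 1.0)
        corr = pd.DataFrame(arr, index=[f"o{i}" for i in range(20)],
                            columns=[f"o{i}" for i in range(20)])
        st = 0.55
        net = build_network(corr, st)
        expected = int((np.abs(np.triu(arr, k=1)) >= st).sum())
        assert net.n_edges == expected

    def test_empty_network_is_error(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            build_network(corr, st=0.9)


class TestModules:
    def test_two_cliques_recovered(self):
        g = nx.Graph()
        for block, nodes in enumerate((list("abcde"), list("fghij"))):
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    g.add_edge(u, v)
        g.add_edge("a", "f")
        net = _net_from_graph(g)
        modules, m = detect_modules(net)
        assert len(set(modules.values())) == 2
        assert len({modules[x] for x in "abcde"}) == 1
        assert len({modules[x] for x in "fghij"}) == 1
        assert m > 0.3

    def test_complete_graph_no_structure(self):
        net = _net_from_graph(nx.complete_graph(8))
        _, m = detect_modules(net)
        assert m <= 0.05

    def test_modularity_equals_hand_formula(self):
        # two triangles joined by one edge
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        net = _net_from_graph(g)
        modules, m = detect_modules(net)
        # hand evaluation of sum(e_ii - a_i^2) for the detected partition
        m_edges = g.number_of_edges()
        comms = {}
        for node, mod in modules.items():
            comms.setdefault(mod, set()).add(node)
        e_ii, a_i = [], []
        for nodes in comms.values():
            within = sum(1 for u, v in g.edges() if u in nodes and v in nodes)
            degree_sum = sum(dict(g.degree())[n] for n in nodes)
            e_ii.append(within / m_edges)
            a_i.append(degree_sum / (2 * m_edges))
        expected = sum(e - a**2 for e, a in zip(e_ii, a_i))
        assert m == pytest.approx(expected, abs=1e-12)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            detect_modules(EcoNetwork(graph=g, threshold=0.5))


class TestTopology:
    def test_ring(self):
        net = _net_from_graph(nx.cycle_graph(10))
        topo = topology_indices(net)
        assert topo.avg_connectivity == pytest.approx(2.0)
        assert topo.avg_clustering == pytest.approx(0.0)
        assert topo.n_nodes == 10 and topo.n_edges == 10

    def test_star_closed_form_path_length(self):
        n = 9
        net = _net_from_graph(nx.star_graph(n))  # n+1 nodes
        topo = topology_indices(net)
        total = n + 1
        # leaf-leaf pairs at distance 2, center-leaf at 1
        expected = (n * 1 + (n * (n - 1) / 2) * 2) / (total * (total - 1) / 2)
        assert topo.avg_path_length == pytest.approx(expected)
        assert topo.avg_clustering == 0.0

    def test_exact_power_law_histogram(self):
        # frequencies freq(k) = C * k^-2 exactly on a log-log line
        degrees = []
        for k, freq in ((1, 16), (2, 4), (4, 1)):
            degrees.extend([k] * freq)
        assert power_law_fit_r2(degrees) == pytest.approx(1.0, abs=1e-9)

    def test_avg_connectivity_identity(self, study_bundle):
        rng = np.random.default_rng(2)
        g = nx.gnm_random_graph(30, 60, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net_from_graph(g)
        topo = topology_indices(net)
        assert topo.avg_connectivity == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes()
        )


class TestRandomBaseline:
    def test_degree_sequence_preserved(self):
        from micreco.network import _double_edge_swap

        g = nx.gnm_random_graph(25, 60, seed=4)
        rng = np.random.default_rng(0)
        for _ in range(5):
            h = _double_edge_swap(g, rng, target_swaps=600, max_tries=6000)
            assert sorted(dict(h.degree()).values()) == sorted(
                dict(g.degree()).values()
            )
            assert h.number_of_edges() == g.number_of_edges()

    def test_clique_is_rigid(self):
        net = _net_from_graph(nx.complete_graph(6))
        detect_modules(net)
        baseline = random_network_baseline(net, n_random=10, seed=0)
        assert np.allclose(baseline["random_sd"].fillna(0), 0)
        assert np.allclose(baseline["empirical"], baseline["random_mean"])

    def test_planted_modularity_exceeds_random(self):
        g = nx.planted_partition_graph(4, 12, 0.8, 0.02, seed=5)
        g = nx.Graph(g)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net_from_graph(g)
        detect_modules(net)
        baseline = random_network_baseline(net, n_random=30, seed=1)
        emp = baseline.loc["modularity", "empirical"]
        mu = baseline.loc["modularity", "random_mean"]
        sd = baseline.loc["modularity", "random_sd"]
        assert emp > mu + 2 * sd

    def test_too_sparse_rejected(self):
        g = nx.Graph([(0, 1)])
        with pytest.raises(ValueError):
            random_network_baseline(_net_from_graph(g), n_random=2, seed=0)


class TestNodeRoles:
    EPS = 1e-9

    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (2.5 - EPS, 0.6 - EPS, "peripheral"),
            (2.5 + EPS, 0.6 - EPS, "module_hub"),
            (2.5 - EPS, 0.6 + EPS, "connector"),
            (2.5 + EPS, 0.6 + EPS, "network_hub"),
            (2.5, 0.6, "peripheral"),  # exact thresholds fall to the lower tier
            (2.5, 0.7, "connector"),
            (3.0, 0.6, "module_hub"),
        ],
    )
    def test_boundary_grid(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_all_links_within_module_pi_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"),
                      ("d", "f"), ("a", "d")])
        net = _net_from_graph(g)
        detect_modules(net)
        roles = node_roles(net)
        assert roles.loc["b", "pi"] == pytest.approx(0.0)

    def test_equal_spread_over_four_modules(self):
        # hub 'h' has exactly one link into each of four 4-cliques
        g = nx.Graph()
        for i, block in enumerate(("abcd", "efgh"[:4], "ijkl", "mnop")):
            nodes = list(block) if i != 1 else list("efgq")
            for x in range(len(nodes)):
                for y in range(x + 1, len(nodes)):
                    g.add_edge(nodes[x], nodes[y])
        hub_targets = ["a", "e", "i", "m"]
        for t in hub_targets:
            g.add_edge("HUB", t)
        net = _net_from_graph(g)
        detect_modules(net)
        roles = node_roles(net)
        # HUB's module is whichever it was merged into; links spread over 4 cliques
        pi = roles.loc["HUB", "pi"]
        assert pi >= 0.625  # 1 - (2/4)^2 - 3*(1/16) at worst merge, usually 0.75
        if roles.loc["HUB", "zi"] < 2.5:
            assert roles.loc["HUB", "role"] in ("connector", "peripheral")

    def test_star_hub_is_module_hub(self):
        g = nx.star_graph(20)
        g.add_edge(50, 51)  # second trivial module
        net = _net_from_graph(g)
        detect_modules(net)
        roles = node_roles(net)
        assert roles.loc[0, "pi"] == pytest.approx(0.0)
        assert roles.loc[0, "zi"] > 2.5
        assert roles.loc[0, "role"] == "module_hub"


class TestComposition:
    def test_fractions_and_sign_tally(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9, sign=1)
        g.add_edge("b", "c", weight=-0.9, sign=-1)
        g.add_edge("c", "d", weight=-0.85, sign=-1)
        net = EcoNetwork(graph=g, threshold=0.8)
        taxonomy = pd.DataFrame(
            {"phylum": ["P1", "P1", "P2", "P2"]}, index=list("abcd")
        )
        comp = network_composition(net, taxonomy)
        assert comp["n_positive_edges"] == 1
        assert comp["n_negative_edges"] == 2
        assert comp["node_fractions"].sum() == pytest.approx(1.0)
        assert comp["node_fractions"]["P1"] == pytest.approx(0.5)

    def test_single_phylum(self):
        g = nx.Graph([("a", "b", {"weight": 0.9, "sign": 1})])
        net = EcoNetwork(graph=g, threshold=0.8)
        taxonomy = pd.DataFrame({"phylum": ["P", "P"]}, index=["a", "b"])
        comp = network_composition(net, taxonomy)
        assert comp["node_fractions"]["P"] == pytest.approx(1.0)
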