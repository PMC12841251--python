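"""Co-expression network construction, module detection and node cartography."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import savor
from savor.network import ModulePartition


def zi_pi_oracle(graph, labels):
    """Naive edge-counting recomputation of Z_i and P_i (O(V*E) loops)."""
    z, p = {}, {}
    for module in set(labels.values()):
        members = [n for n in graph.nodes() if labels[n] == module]
        within = []
        for n in members:
            k = 0
            for u, v in graph.edges():
                if (u == n and labels[v] == module) or (v == n and labels[u] == module):
                    k += 1
            within.append(k)
        mean = sum(within) / len(within)
        sd = (sum((k - mean) ** 2 for k in within) / len(within)) ** 0.5
        for n, k in zip(members, within):
            z[n] = (k - mean) / sd if sd > 0 else 0.0
    for n in graph.nodes():
        k_total = graph.degree(n)
        if k_total == 0:
            p[n] = 0.0
            continue
        frac_sq = 0.0
        for module in set(labels.values()):
            k_s = sum(1 for nb in graph.neighbors(n) if labels[nb] == module)
            frac_sq += (k_s / k_total) ** 2
        p[n] = 1.0 - frac_sq
    return z, p


class TestBuildNetwork:
    def test_duplicate_gene_yields_perfect_edge(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=10)
        expr = pd.DataFrame([row, row], index=["g1", "g2"])
        net = savor.build_network(expr)
        assert net.graph.has_edge("g1", "g2")
        assert net.graph["g1"]["g2"]["r"] == pytest.approx(1.0)

    def test_requires_four_samples(self):
        expr = pd.DataFrame(np.ones((3, 3)), index=list("abc"))
        with pytest.raises(ValueError):
            savor.build_network(expr)

    def test_zero_variance_genes_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(3, 8)), index=["a", "b", "c"])
        expr.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            net = savor.build_network(expr, r_min=0.0, q_max=1.1)
        assert net.dropped_zero_variance == ["flat"]

    def test_null_matrix_keeps_almost_no_edges(self):
        """Independent genes: the q-filter holds the edge count near zero."""
        rng = np.random.default_rng(20260117)
        expr = pd.DataFrame(
            rng.normal(size=(100, 20)), index=[f"g{i}" for i in range(100)]
        )
        net = savor.build_network(expr)
        n_pairs = 100 * 99 // 2
        assert net.n_edges <= 0.01 * n_pairs

    def test_planted_blocks_stay_within_blocks(self):
        spec = savor.ExprSimSpec(
            n_genes=60, module_sizes=(20, 20, 20), loading=0.9, noise_sd=0.3, seed=3
        )
        expr, truth = savor.gen_expression(spec)
        net = savor.build_network(expr)
        within = between = 0
        for u, v in net.graph.edges():
            if truth["module"][u] == truth["module"][v]:
                within += 1
            else:
                between += 1
        assert within > 0
        assert between < 0.05 * within

    def test_edge_set_invariant_to_gene_and_sample_order(self):
        spec = savor.ExprSimSpec(n_genes=30, module_sizes=(10, 10), seed=5)
        expr, _ = savor.gen_expression(spec)
        rng = np.random.default_rng(8)
        shuffled = expr.iloc[
            rng.permutation(expr.shape[0]), rng.permutation(expr.shape[1])
        ]
        edges = lambda net: {frozenset(e) for e in net.graph.edges()}  # noqa: E731
        assert edges(savor.build_network(expr)) == edges(savor.build_network(shuffled))


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        g = nx.union(
            nx.relabel_nodes(nx.complete_graph(5), lambda n: f"a{n}"),
            nx.relabel_nodes(nx.complete_graph(4), lambda n: f"b{n}"),
        )
        part = savor.detect_modules(g)
        assert len(part.module_sizes) == 2
        assert len({part.labels[f"a{i}"] for i in range(5)}) == 1
        assert len({part.labels[f"b{i}"] for i in range(4)}) == 1

    def test_single_clique_is_one_module(self):
        part = savor.detect_modules(nx.complete_graph(6))
        assert len(part.module_sizes) == 1

    def test_singleton_components_become_singleton_modules(self):
        g = nx.complete_graph(4)
        g.add_node("lonely")
        part = savor.detect_modules(g)
        assert part.module_sizes[part.labels["lonely"]] == 1

    def test_planted_module_recovery(self):
        """Five planted 40-gene factors at loading 0.9: near-perfect recovery."""
        spec = savor.ExprSimSpec(
            n_genes=200, module_sizes=(40,) * 5, loading=0.9, noise_sd=0.3, seed=20260117
        )
        expr, truth = savor.gen_expression(spec)
        net = savor.build_network(expr)
        part = savor.detect_modules(net, seed=1)
        genes = list(part.labels)
        ari = adjusted_rand_score(
            [truth["module"][g] for g in genes], [part.labels[g] for g in genes]
        )
        assert ari >= 0.9


class TestCartography:
    def test_equal_within_degrees_give_zero_z(self):
        g = nx.cycle_graph(6)
        part = ModulePartition(labels={n: 0 for n in g.nodes()}, modularity=0.0)
        z = savor.within_module_degree_z(g, part)
        assert all(v == 0.0 for v in z.values())

    def test_star_center_matches_hand_calculation(self):
        g = nx.star_graph(6)  # center 0 plus 6 leaves, one 7-node module
        part = ModulePartition(labels={n: 0 for n in g.nodes()}, modularity=0.0)
        z = savor.within_module_degree_z(g, part)
        # within-degrees: [6, 1x6]; mean 12/7, population sd sqrt(150/49)
        mean, sd = 12 / 7, (sum((k - 12 / 7) ** 2 for k in [6] + [1] * 6) / 7) ** 0.5
        assert z[0] == pytest.approx((6 - mean) / sd)
        assert z[1] == pytest.approx((1 - mean) / sd)

    def test_z_sums_to_zero_within_module(self):
        g = nx.gnp_random_graph(20, 0.3, seed=4)
        part = savor.detect_modules(g)
        z = savor.within_module_degree_z(g, part)
        for module in set(part.labels.values()):
            members = part.members(module)
            zs = [z[n] for n in members]
            if any(v != 0 for v in zs):
                assert sum(zs) == pytest.approx(0.0, abs=1e-9)

    def test_participation_trivial_values(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("x", "y")])
        labels = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1}
        part = ModulePartition(labels=labels, modularity=0.0)
        p = savor.participation_coefficient(g, part)
        assert p["a"] == 0.0  # all edges inside its own module
        # degree-2 node with one edge into each of two modules
        g2 = nx.Graph([("m", "in"), ("m", "out")])
        part2 = ModulePartition(labels={"m": 0, "in": 0, "out": 1}, modularity=0.0)
        assert savor.participation_coefficient(g2, part2)["m"] == pytest.approx(0.5)

    def test_matches_oracle_on_random_three_module_graph(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(30, 0.2, seed=6)
        labels = {n: int(rng.integers(0, 3)) for n in g.nodes()}
        part = ModulePartition(labels=labels, modularity=0.0)
        z_ref, p_ref = zi_pi_oracle(g, labels)
        z = savor.within_module_degree_z(g, part)
        p = savor.participation_coefficient(g, part)
        for n in g.nodes():
            assert z[n] == pytest.approx(z_ref[n])
            assert p[n] == pytest.approx(p_ref[n])

    def test_participation_invariant_under_module_relabeling(self):
        g = nx.gnp_random_graph(15, 0.3, seed=7)
        labels = {n: n % 3 for n in g.nodes()}
        relabeled = {n: (m + 7) * 13 for n, m in labels.items()}
        p1 = savor.participation_coefficient(g, ModulePartition(labels, 0.0))
        p2 = savor.participation_coefficient(g, ModulePartition(relabeled, 0.0))
        assert p1 == p2

    def test_participation_bounded_by_module_count(self):
        g = nx.gnp_random_graph(25, 0.25, seed=12)
        labels = {n: n % 4 for n in g.nodes()}
        p = savor.participation_coefficient(g, ModulePartition(labels, 0.0))
        for n in g.nodes():
            m = len({labels[nb] for nb in g.neighbors(n)})
            if m:
                assert p[n] <= 1 - 1 / m + 1e-12


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "z, p, role",
        [
            (3.0, 0.1, "module_hub"),
            (0.0, 0.8, "connector"),
            (3.0, 0.8, "network_hub"),
            (0.0, 0.1, "peripheral"),
            (2.5, 0.62, "peripheral"),  # thresholds are strict
            (2.5000001, 0.62, "module_hub"),
            (2.5, 0.6200001, "connector"),
        ],
    )
    def test_threshold_semantics(self, z, p, role):
        topo = pd.DataFrame({"gene": ["n"], "module": [0], "degree": [1], "Z": [z], "P": [p]})
        out = savor.classify_roles(topo)
        assert out.loc[0, "role"] == role
        assert bool(out.loc[0, "is_key"]) == (role != "peripheral")

    def test_bridge_genes_between_planted_cliques_are_connectors(self):
        """A gene with one edge into each of three modules has P = 2/3 > 0.62."""
        g = nx.Graph()
        for prefix in ("a", "b", "c"):
            clique = nx.relabel_nodes(nx.complete_graph(8), lambda n: f"{prefix}{n}")
            g = nx.union(g, clique)
        g.add_node("bridge")
        g.add_edges_from([("bridge", "a0"), ("bridge", "b0"), ("bridge", "c0")])
        part = savor.detect_modules(g)
        roles = savor.classify_roles(savor.node_topology(g, part)).set_index("gene")
        assert roles.loc["bridge", "role"] == "connector"


class TestFilterModules:
    @staticmethod
    def partition_of(sizes):
        labels, i = {}, 0
        for m, size in enumerate(sizes):
            for _ in range(size):
                labels[f"g{i}"] = m
                i += 1
        return ModulePartition(labels=labels, modularity=0.0)

    def test_passing_module(self):
        part = self.partition_of([20])
        annotation = {f"g{i}": {f"f{i % 4}"} for i in range(12)}
        annotation.update({f"g{i}": {"f0"} for i in range(3)})
        report = savor.filter_modules(part, annotation)
        row = report.iloc[0]
        assert row["n_annotated"] == 12 and row["n_distinct_functions"] == 4
        assert row["top_function_gene_count"] >= 3 and bool(row["passes"])

    def test_too_few_annotated_fails(self):
        part = self.partition_of([9])
        annotation = {f"g{i}": {"f1", "f2", "f3"} for i in range(9)}
        assert not savor.filter_modules(part, annotation)["passes"].iloc[0]

    def test_top_function_tie_broken_lexicographically(self):
        part = self.partition_of([2])
        report = savor.filter_modules(part, {"g0": {"zeta"}, "g1": {"alpha"}})
        assert report["top_function"].iloc[0] == "alpha"

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(20260117)
        part = self.partition_of(rng.integers(5, 30, size=6).tolist())
        functions = [f"fn{i}" for i in range(8)]
        annotation = {
            g: set(rng.choice(functions, size=rng.integers(1, 4), replace=False))
            for g in part.labels
            if rng.uniform() < 0.7
        }
        report = savor.filter_modules(part, annotation).set_index("module")
        for module in set(part.labels.values()):
            members = [g for g, m in part.labels.items() if m == module]
            annotated = [g for g in members if g in annotation]
            counts = {}
            for g in annotated:
                for f in annotation[g]:
                    counts[f] = counts.get(f, 0) + 1
            top = max(counts.values()) if counts else 0
            expected_pass = (
                len(annotated) >= 10
                and len(annotated) / len(members) >= 0.5
                and len(counts) >= 3
                and top >= 3
            )
            assert report.loc[module, "n_annotated"] == len(annotated)
            assert bool(report.loc[module, "passes"]) == expected_pass
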