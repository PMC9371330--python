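"""CLR transform, network inference, modules, Zi-Pi roles, comparisons."""

import numpy as np
import pandas as pd
import pytest

from phyllotraj import (
    class_edge_proportions,
    clr_transform,
    compare_networks,
    detect_modules,
    guild_summary,
    infer_network,
    zi_pi,
)
from phyllotraj.networks import NetworkModel
from phyllotraj.table import AbundanceMatrix, TableError

from conftest import toy_table


def clr_of(values, ids=None):
    df = pd.DataFrame(np.asarray(values, float))
    df.columns = ids or [f"o{j + 1}" for j in range(df.shape[1])]
    return AbundanceMatrix(df, "clr")


def net_from_edges(edges, nodes):
    rows = [(a, b, w, "+" if w >= 0 else "-", 1.0) for a, b, w in edges]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                     "stability"])
    return NetworkModel(df, nodes)


class TestClr:
    def test_constant_row_maps_to_zero(self):
        out = clr_transform(toy_table([[5, 5, 5]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_hand_example_and_zero_sum(self):
        out = clr_transform(toy_table([[1, 1, 8]]), pseudocount=1).values
        logs = np.log([2.0, 2.0, 9.0])
        np.testing.assert_allclose(out.to_numpy()[0], logs - logs.mean(),
                                   rtol=1e-12)
        assert out.to_numpy().sum() == pytest.approx(0.0, abs=1e-12)

    def test_near_scale_invariance(self):
        counts = np.array([[10, 40, 200, 1000]])
        a = clr_transform(toy_table(counts)).values.to_numpy()
        b = clr_transform(toy_table(counts * 2)).values.to_numpy()
        # with a pseudocount, doubling all counts shifts CLR only slightly
        assert np.abs(a - b).max() < 0.1


class TestInferNetwork:
    def test_perfect_correlation_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        mat = np.column_stack([x, x, rng.normal(size=50)])
        net = infer_network(clr_of(mat), seed=1)
        edge = net.edges[(net.edges["source"] == "o1")
                         & (net.edges["target"] == "o2")]
        assert len(edge) == 1
        assert edge.iloc[0]["stability"] == 1.0
        assert edge.iloc[0]["sign"] == "+"

    def test_false_edge_rate_on_independent_data(self):
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(20):
            mat = rng.normal(size=(200, 25))
            net = infer_network(clr_of(mat), seed=int(rng.integers(1 << 30)))
            n_pairs = 25 * 24 / 2
            rates.append(net.n_edges / n_pairs)
        assert np.mean(rates) < 0.01

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(2)
        n = 150
        blocks = []
        for b in range(3):
            shared = rng.normal(size=n)
            blocks.append(shared[:, None] + 0.4 * rng.normal(size=(n, 5)))
        mat = np.hstack(blocks)
        net = infer_network(clr_of(mat), seed=3)
        same_block = 0
        for _, r in net.edges.iterrows():
            ia = int(r["source"][1:]) - 1
            ib = int(r["target"][1:]) - 1
            same_block += ia // 5 == ib // 5
        assert net.n_edges > 0
        assert same_block / net.n_edges >= 0.9

    def test_too_few_samples(self):
        with pytest.raises(TableError):
            infer_network(clr_of(np.zeros((5, 3))))

    def test_seed_reproducible_and_sample_order_invariant(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(60, 10))
        mat[:, 1] = mat[:, 0] + 0.1 * rng.normal(size=60)
        a = infer_network(clr_of(mat), seed=9)
        b = infer_network(clr_of(mat), seed=9)
        pd.testing.assert_frame_equal(a.edges, b.edges)


class TestModules:
    def clique_graph(self, sizes, bridges=()):
        edges, nodes, start = [], [], 0
        for s in sizes:
            members = [f"n{start + i}" for i in range(s)]
            nodes += members
            for i in range(s):
                for j in range(i + 1, s):
                    edges.append((members[i], members[j], 1.0))
            start += s
        edges += [(a, b, 1.0) for a, b in bridges]
        return net_from_edges(edges, nodes)

    def test_two_disconnected_cliques(self):
        net = self.clique_graph([4, 4])
        mods = detect_modules(net)
        assert len(set(mods.values())) == 2
        assert len({mods[f"n{i}"] for i in range(4)}) == 1

    def test_ring_of_four_cliques(self):
        net = self.clique_graph(
            [5, 5, 5, 5],
            bridges=[("n0", "n5"), ("n6", "n10"), ("n11", "n15"),
                     ("n16", "n1")])
        mods = detect_modules(net)
        assert len(set(mods.values())) == 4
        # modularity oracle: the clique partition maximizes modularity
        import networkx as nx

        g = net.graph()
        cliques = [[f"n{5 * b + i}" for i in range(5)] for b in range(4)]
        q_clique = nx.algorithms.community.modularity(g, cliques)
        assert net.modularity == pytest.approx(q_clique, abs=1e-12)

    def test_singletons_get_own_modules(self):
        net = net_from_edges([("a", "b", 1.0)], ["a", "b", "c", "d"])
        mods = detect_modules(net)
        assert mods["c"] != mods["d"]
        assert mods["c"] != mods["a"]


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)],
                             ["a", "b", "c"])
        roles = zi_pi(net, {"a": 0, "b": 0, "c": 0})
        assert (roles.table["pi"] == 0).all()

    def test_even_split_pi_half(self):
        edges = [("x", "a", 1), ("x", "b", 1), ("x", "c", 1), ("x", "d", 1)]
        net = net_from_edges(edges, ["x", "a", "b", "c", "d"])
        modules = {"x": 0, "a": 0, "b": 0, "c": 1, "d": 1}
        roles = zi_pi(net, modules)
        assert roles.table.loc["x", "pi"] == pytest.approx(0.5)

    def test_constructed_module_hub(self):
        # hub wired to all 20 members of its module; members sparsely wired
        nodes = ["hub"] + [f"m{i}" for i in range(20)] + ["z1", "z2"]
        edges = [("hub", f"m{i}", 1.0) for i in range(20)]
        edges += [(f"m{2 * i}", f"m{2 * i + 1}", 1.0) for i in range(5)]
        edges += [("z1", "z2", 1.0)]
        net = net_from_edges(edges, nodes)
        modules = {n: 0 for n in nodes}
        modules["z1"] = modules["z2"] = 1
        roles = zi_pi(net, modules)
        hub = roles.table.loc["hub"]
        assert hub["zi"] >= 2.5
        assert hub["role"] == "module hub"

    def test_degree_zero_excluded(self):
        net = net_from_edges([("a", "b", 1.0)], ["a", "b", "c"])
        roles = zi_pi(net, {"a": 0, "b": 0, "c": 1})
        assert roles.excluded == ["c"]


class TestGuildSummary:
    def test_star_center_has_max_betweenness(self):
        edges = [("c", f"l{i}", 1.0) for i in range(5)]
        net = net_from_edges(edges, ["c"] + [f"l{i}" for i in range(5)])
        guilds = pd.Series({"c": "A", **{f"l{i}": "B" for i in range(5)}})
        gs = guild_summary(net, guilds)
        assert gs.table.loc["A", "betweenness_mean"] > \
            gs.table.loc["B", "betweenness_mean"]

    def test_single_guild_equals_graph_stats(self):
        import networkx as nx

        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        net = net_from_edges(edges, list("abcd"))
        guilds = pd.Series({n: "only" for n in "abcd"})
        gs = guild_summary(net, guilds)
        btw = nx.betweenness_centrality(net.graph())
        assert gs.table.loc["only", "betweenness_mean"] == pytest.approx(
            np.mean(list(btw.values())))
        assert gs.table.loc["only", "degree_mean"] == pytest.approx(
            np.mean([net.graph().degree(n) for n in "abcd"]))

    def test_toy_matches_path_enumeration_oracle(self):
        # 6-node graph; brute-force all-pairs shortest-path betweenness
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0),
                 ("b", "e", 1.0), ("e", "f", 1.0), ("c", "f", 1.0)]
        nodes = list("abcdef")
        net = net_from_edges(edges, nodes)
        import itertools

        import networkx as nx

        g = net.graph()

        def brute_betweenness(node):
            total = 0.0
            for s, t in itertools.combinations(set(nodes) - {node}, 2):
                paths = list(nx.all_shortest_paths(g, s, t))
                through = sum(node in p[1:-1] for p in paths)
                total += through / len(paths)
            return total / ((len(nodes) - 1) * (len(nodes) - 2) / 2)

        guilds = pd.Series({n: n for n in nodes})  # one guild per node
        gs = guild_summary(net, guilds)
        for n in nodes:
            assert gs.table.loc[n, "betweenness_mean"] == pytest.approx(
                brute_betweenness(n), abs=1e-12)


def test_pathogen_guild_is_most_central():
    """At the full default design the planted pathogen-load coupling and
    the driver-borne host-genetic displacement make the pathogen guild the
    most central: highest mean betweenness averaged across the per-date
    networks."""
    import phyllotraj as pt

    table, _, _ = pt.simulate(pt.SimulationConfig(seed=1))
    clean = pt.flag_contaminants(table).pruned(table).real_samples()
    meta = clean.sample_meta
    btw, deg = {}, {}
    for t in sorted(meta["timepoint"].unique()):
        sub = clean.subset_samples(
            meta.index[(meta["timepoint"] == t)
                       & ~meta["infected"]].tolist())
        net = infer_network(clr_transform(sub), seed=1)
        detect_modules(net)
        gs = guild_summary(net, clean.otu_meta)
        for g in gs.table.index:
            btw.setdefault(g, []).append(gs.table.loc[g, "betweenness_mean"])
            deg.setdefault(g, []).append(gs.table.loc[g, "degree_mean"])
    assert max(btw, key=lambda g: np.mean(btw[g])) == "pathogen"


class TestCompare:
    def make_tables(self, invert=False, seed=0, n=60, k=12):
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=(n, 1))
        block1 = shared + 0.3 * rng.normal(size=(n, k // 2))
        sign = -1.0 if invert else 1.0
        shared2 = rng.normal(size=(n, 1))
        block2 = sign * shared2 + 0.3 * rng.normal(size=(n, k // 2))
        t1 = np.hstack([block1, rng.normal(size=(n, k // 2))])
        t2 = np.hstack([sign * block2[:, : k // 2], rng.normal(size=(n, k // 2))])
        return clr_of(t1), clr_of(t2)

    def test_identical_tables_similar(self):
        rng = np.random.default_rng(1)
        n, k = 60, 10
        shared = rng.normal(size=(n, 1))
        mat = np.hstack([shared + 0.3 * rng.normal(size=(n, 5)),
                         rng.normal(size=(n, 5))])
        c = clr_of(mat)
        res = compare_networks(c, c, n_boot=10, n_perm=50, seed=2)
        assert res.distance == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_inverted_structure_detected(self):
        rng = np.random.default_rng(3)
        n, k = 80, 10
        shared = rng.normal(size=(n, 1))
        base = shared + 0.3 * rng.normal(size=(n, 5))
        t1 = np.hstack([base, rng.normal(size=(n, 5))])
        # invert half the block so planted correlations flip sign
        flipped = base.copy()
        flipped[:, ::2] *= -1
        t2 = np.hstack([flipped, rng.normal(size=(n, 5))])
        res = compare_networks(clr_of(t1), clr_of(t2), n_boot=5, n_perm=50,
                               seed=4)
        assert res.p_value <= 0.05

    def test_symmetry(self):
        a, b = self.make_tables(seed=5)
        d1 = compare_networks(a, b, n_boot=2, n_perm=5, seed=6).distance
        d2 = compare_networks(b, a, n_boot=2, n_perm=5, seed=6).distance
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestClassEdges:
    def test_single_class(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", -1.0)], list("abc"))
        tax = pd.Series({"a": "X", "b": "X", "c": "X"})
        out = class_edge_proportions(net, tax)
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (out["class_a"] == "X").all()

    def test_bipartite_between_only(self):
        net = net_from_edges([("a", "x", 1.0), ("b", "y", 1.0)], list("abxy"))
        tax = pd.Series({"a": "P", "b": "P", "x": "Q", "y": "Q"})
        out = class_edge_proportions(net, tax)
        assert len(out) == 1
        assert out.iloc[0]["class_a"] == "P" and out.iloc[0]["class_b"] == "Q"
        assert out.iloc[0]["proportion"] == 1.0

    def test_five_edge_toy_by_hand(self):
        edges = [("a", "b", 1.0), ("a", "c", -1.0), ("b", "c", 1.0),
                 ("c", "d", 1.0), ("d", "e", -1.0)]
        net = net_from_edges(edges, list("abcde"))
        tax = pd.Series({"a": "X", "b": "X", "c": "Y", "d": "Y"})  # e unknown
        out = class_edge_proportions(net, tax).set_index(
            ["class_a", "class_b", "sign"])["proportion"]
        assert out[("X", "X", "+")] == pytest.approx(0.2)
        assert out[("X", "Y", "-")] == pytest.approx(0.2)
        assert out[("X", "Y", "+")] == pytest.approx(0.2)
        assert out[("Y", "Y", "+")] == pytest.approx(0.2)
        assert out[("Unknown", "Y", "-")] == pytest.approx(0.2)

    def test_proportions_sum_to_one_on_inferred_network(self, clean_table):
        sub = clean_table.subset_samples(
            clean_table.sample_meta.index[
                clean_table.sample_meta["timepoint"] == 3].tolist())
        net = infer_network(clr_transform(sub), seed=0)
        out = class_edge_proportions(net, clean_table.otu_meta)
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
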