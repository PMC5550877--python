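import numpy as np
import pandas as pd
import pytest
from scipy import stats

from difnet import (
    CoexpressionNetwork,
    Edge,
    ExpressionMatrix,
    build_network,
    degree_centrality,
    dif_degree,
    k_core_decomposition,
    select_hubs,
)
from difnet.errors import InputError, StatisticsError

from _oracles import kcore_bruteforce, pearson_r


def matrix_from_rows(rows: dict, label="cond") -> ExpressionMatrix:
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, {c: label for c in values.columns})


def net_from_edges(nodes, pairs, label="x") -> CoexpressionNetwork:
    edges = tuple(
        Edge(*sorted(p), r=0.9, p_value=1e-6, q_value=1e-5, sign="positive")
        for p in pairs
    )
    return CoexpressionNetwork(label, tuple(sorted(nodes)), edges, n_samples=10)


class TestBuildNetwork:
    def test_identical_vectors_perfect_edge(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = matrix_from_rows({"a": v, "b": v, "c": [5, 1, 4, 2, 3]})
        net = build_network(m, ["a", "b", "c"], "cond")
        ab = [e for e in net.edges if (e.gene_a, e.gene_b) == ("a", "b")]
        assert len(ab) == 1
        assert ab[0].r == 1.0
        assert ab[0].p_value == 0.0
        assert ab[0].sign == "positive"

    def test_orthogonal_pair_no_edge(self):
        # y's centered deviations are orthogonal to x's: r is exactly 0
        m = matrix_from_rows({"x": [1, 2, 3, 4, 5], "y": [1, 2, 3, 2, 1]})
        net = build_network(m, ["x", "y"], "cond", log_transform=False)
        assert net.edges == ()

    def test_textbook_correlation_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 5.0, 4.0, 5.0]
        m = matrix_from_rows({"x": x, "y": y})
        net = build_network(
            m, ["x", "y"], "cond", edge_fdr_alpha=1.0, log_transform=False
        )
        (e,) = net.edges
        r = pearson_r(x, y)
        t = r * np.sqrt((5 - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), 5 - 2)
        assert e.r == pytest.approx(r, rel=1e-12)
        assert e.p_value == pytest.approx(p, rel=1e-12)

    def test_negative_correlation_sign(self):
        m = matrix_from_rows({"x": [1, 2, 3, 4, 5], "y": [10, 8, 6, 4, 2]})
        net = build_network(m, ["x", "y"], "cond", log_transform=False)
        (e,) = net.edges
        assert e.sign == "negative"
        assert e.r == pytest.approx(-1.0)

    def test_default_log_transform_matches_log_correlation(self):
        rng = np.random.default_rng(13)
        rows = {f"g{i}": np.exp2(rng.normal(5, 1, 12)) for i in range(4)}
        m = matrix_from_rows(rows)
        net = build_network(m, list(rows), "cond", edge_fdr_alpha=1.0)
        X = m.values.to_numpy()
        pc = 1e-6 * X.mean()
        logx = np.log2(X + pc)
        idx = {g: i for i, g in enumerate(m.gene_ids)}
        for e in net.edges:
            expected = np.corrcoef(logx[idx[e.gene_a]], logx[idx[e.gene_b]])[0, 1]
            assert e.r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_gene_isolated_with_warning(self):
        m = matrix_from_rows(
            {"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10], "flat": [3, 3, 3, 3, 3]}
        )
        with pytest.warns(UserWarning, match="flat"):
            net = build_network(m, ["a", "b", "flat"], "cond")
        assert "flat" in net.nodes
        assert degree_centrality(net)["flat"] == 0

    def test_too_few_samples_raises(self):
        m = matrix_from_rows({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(StatisticsError, match="4 samples"):
            build_network(m, ["a", "b"], "cond")

    def test_single_gene_rejected(self):
        m = matrix_from_rows({"a": [1, 2, 3, 4, 5]})
        with pytest.raises(InputError, match="2 genes"):
            build_network(m, ["a"], "cond")

    def test_missing_gene_rejected(self):
        m = matrix_from_rows({"a": [1, 2, 3, 4, 5], "b": [1, 3, 2, 4, 5]})
        with pytest.raises(InputError, match="ghost"):
            build_network(m, ["a", "ghost"], "cond")

    def test_edges_fdr_filtered_and_canonical(self, hub_config):
        from difnet import generate_expression

        control, _, _ = generate_expression(hub_config)
        net = build_network(control, control.gene_ids, "control", edge_fdr_alpha=0.05)
        for e in net.edges:
            assert e.q_value < 0.05
            assert e.gene_a < e.gene_b
            assert e.sign == ("positive" if e.r >= 0 else "negative")
        # handshake identity
        assert sum(degree_centrality(net).values()) == 2 * len(net.edges)


class TestDegreeCentrality:
    def test_empty_graph(self):
        net = net_from_edges(["a", "b", "c"], [])
        assert degree_centrality(net) == {"a": 0, "b": 0, "c": 0}

    def test_triangle(self):
        net = net_from_edges("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        assert degree_centrality(net) == {"a": 2, "b": 2, "c": 2}

    def test_handshake_identity_random_graphs(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(12)]
        for _ in range(20):
            pairs = {
                tuple(sorted(map(str, rng.choice(nodes, 2, replace=False))))
                for _ in range(15)
            }
            net = net_from_edges(nodes, pairs)
            assert sum(degree_centrality(net).values()) == 2 * len(net.edges)


class TestKCore:
    def test_triangle_plus_pendant(self):
        net = net_from_edges(
            "abcd", [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        )
        assert k_core_decomposition(net) == {"a": 2, "b": 2, "c": 2, "d": 1}

    def test_edgeless_graph(self):
        net = net_from_edges("abc", [])
        assert k_core_decomposition(net) == {"a": 0, "b": 0, "c": 0}

    def test_clique_property(self):
        nodes = list("abcde")
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        net = net_from_edges(nodes, pairs)
        assert set(k_core_decomposition(net).values()) == {4}

    def test_core_number_bounded_by_degree(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(10)]
        pairs = {
            tuple(sorted(map(str, rng.choice(nodes, 2, replace=False))))
            for _ in range(18)
        }
        net = net_from_edges(nodes, pairs)
        deg = degree_centrality(net)
        for g, c in k_core_decomposition(net).items():
            assert c <= deg[g]

    def test_matches_bruteforce_small_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            nodes = [f"n{i}" for i in range(n)]
            pairs = {
                tuple(sorted(map(str, rng.choice(nodes, 2, replace=False))))
                for _ in range(int(rng.integers(0, n * 2)))
            }
            net = net_from_edges(nodes, pairs)
            assert k_core_decomposition(net) == kcore_bruteforce(nodes, pairs)


class TestDifDegree:
    def test_identical_networks_zero(self):
        net = net_from_edges("abc", [("a", "b")])
        table = dif_degree(net, net)
        assert (table["dif_degree"] == 0).all()

    def test_arithmetic(self):
        ctrl = net_from_edges(
            ["h"] + [f"p{i}" for i in range(12)],
            [("h", f"p{i}") for i in range(12)],
        )
        pert = net_from_edges(
            ["h"] + [f"p{i}" for i in range(12)],
            [("h", "p0"), ("h", "p1")],
        )
        table = dif_degree(ctrl, pert)
        assert table.loc["h", "dif_degree"] == 10
        assert table.loc["h", "signed_dif"] == 10

    def test_gene_absent_from_perturbed(self):
        ctrl = net_from_edges("abc", [("a", "b"), ("a", "c")])
        pert = net_from_edges("bc", [("b", "c")])
        table = dif_degree(ctrl, pert)
        assert table.loc["a", "degree_perturbed"] == 0
        assert table.loc["a", "dif_degree"] == 2

    def test_absolute_value(self):
        ctrl = net_from_edges("ab", [])
        pert = net_from_edges("ab", [("a", "b")])
        table = dif_degree(ctrl, pert)
        assert table.loc["a", "dif_degree"] == 1
        assert table.loc["a", "signed_dif"] == -1


class TestSelectHubs:
    @staticmethod
    def table_for(dif: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree_control": [v for v in dif.values()],
                "degree_perturbed": [0] * len(dif),
                "dif_degree": list(dif.values()),
                "signed_dif": list(dif.values()),
            },
            index=pd.Index(list(dif), name="gene_id"),
        )

    def test_printed_hub_lists_intersection(self):
        zbtb18 = {"Olig1": 12, "Zic5": 11, "Erbb2": 10, "Numbl": 9, "Olig2": 9}
        foxj3 = {
            "Olig1": 14, "Shank1": 12, "Erbb2": 12, "Zic5": 11,
            "Smarcd3": 10, "Ina": 10, "Chd7": 9, "Olig2": 9,
        }
        filler = {f"x{i}": 3 for i in range(5)}
        sel = select_hubs(
            {
                "zbtb18": self.table_for({**zbtb18, **filler}),
                "foxj3": self.table_for({**foxj3, **filler}),
            },
            threshold=8,
        )
        assert set(sel.selected["zbtb18"]) == set(zbtb18)
        assert set(sel.selected["foxj3"]) == set(foxj3)
        assert sel.core_regulators == ("Erbb2", "Olig1", "Olig2", "Zic5")

    def test_boundary_value_excluded(self):
        sel = select_hubs({"p": self.table_for({"g1": 8, "g2": 9})}, threshold=8)
        assert sel.selected["p"] == ("g2",)

    def test_single_table_identity(self):
        sel = select_hubs({"p": self.table_for({"g1": 10, "g2": 2})}, threshold=8)
        assert sel.core_regulators == sel.selected["p"] == ("g1",)

    def test_no_tables_rejected(self):
        with pytest.raises(InputError):
            select_hubs({}, threshold=8)
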