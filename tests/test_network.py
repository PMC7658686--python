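import numpy as np
import pandas as pd
import pytest

from metafunc import (
    CategoryMap,
    active_index,
    build_network,
    correlation_matrix,
    interaction_complexity,
    internal_complexity,
    normalize_relative,
)
from metafunc.network import CooccurrenceNetwork, write_edge_list, write_graphml
import networkx as nx

from conftest import make_profile


# -------------------------------------------------------- correlations


def _profile_from_columns(cols: dict):
    x = np.column_stack(list(cols.values()))
    return make_profile(x, ["G"] * x.shape[0], fids=list(cols))


def test_spearman_identity_and_reversal():
    x = np.arange(1.0, 9.0)
    prof = _profile_from_columns({"a": x, "b": x[::-1], "c": x**2})
    r, p, q = correlation_matrix(prof, n_perm=99, seed=0)
    assert r.at["a", "a"] == pytest.approx(1.0)
    assert r.at["a", "b"] == pytest.approx(-1.0)
    assert r.at["a", "c"] == pytest.approx(1.0)  # monotone transform


def test_spearman_average_ranks_for_ties():
    prof = _profile_from_columns(
        {"x": np.array([1.0, 2.0, 2.0, 4.0]), "y": np.array([10.0, 20.0, 30.0, 40.0])}
    )
    r, _, _ = correlation_matrix(prof, n_perm=99, seed=0)
    assert r.at["x", "y"] == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-9)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    a = rng.random(20)
    b = rng.random(20)
    r1, _, _ = correlation_matrix(_profile_from_columns({"a": a, "b": b}),
                                  n_perm=99, seed=0)
    r2, _, _ = correlation_matrix(
        _profile_from_columns({"a": np.exp(3 * a), "b": b**3}), n_perm=99, seed=0
    )
    assert r1.at["a", "b"] == pytest.approx(r2.at["a", "b"], abs=1e-12)


def test_permutation_p_super_uniform_for_independent_pairs():
    rng = np.random.default_rng(17)
    prof = make_profile(rng.random((30, 12)), ["G"] * 30)
    _, p, _ = correlation_matrix(prof, n_perm=199, seed=3)
    iu = np.triu_indices(12, 1)
    pv = p.to_numpy()[iu]
    for alpha in (0.05, 0.2):
        assert (pv <= alpha).mean() <= alpha + 2.58 * np.sqrt(
            alpha * (1 - alpha) / len(pv)
        ) + 0.01


def test_correlation_rejects_tiny_samples_and_warns_on_constants():
    prof = make_profile(np.random.default_rng(0).random((3, 4)), ["G"] * 3)
    with pytest.raises(ValueError, match="4 samples"):
        correlation_matrix(prof)
    x = np.random.default_rng(1).random((10, 3))
    x[:, 1] = 0.5
    with pytest.warns(UserWarning, match="constant"):
        r, _, _ = correlation_matrix(make_profile(x, ["G"] * 10), n_perm=99)
    assert "F2" not in r.columns


# ------------------------------------------------------------ edge rule


def _three_node_matrices():
    nodes = ["a", "b", "c"]
    r = pd.DataFrame(
        [[1.0, 0.9, -0.85], [0.9, 1.0, 0.5], [-0.85, 0.5, 1.0]],
        index=nodes, columns=nodes,
    )
    q = pd.DataFrame(0.01, index=nodes, columns=nodes)
    return r, q


def test_three_node_edge_rule_exact():
    r, q = _three_node_matrices()
    net = build_network(r, q, group="HC")
    assert net.graph.number_of_edges() == 2
    assert net.graph["a"]["b"]["sign"] == "+"
    assert net.graph["a"]["c"]["sign"] == "-"
    assert not net.graph.has_edge("b", "c")
    assert net.n_positive == 1 and net.n_negative == 1


def test_edge_rule_empty_below_threshold():
    nodes = ["a", "b"]
    r = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=nodes, columns=nodes)
    q = pd.DataFrame(0.001, index=nodes, columns=nodes)
    assert build_network(r, q).graph.number_of_edges() == 0


def test_edge_rule_respects_q_threshold():
    r, q = _three_node_matrices()
    q.loc["a", "b"] = q.loc["b", "a"] = 0.2
    net = build_network(r, q)
    assert not net.graph.has_edge("a", "b")
    assert net.graph.has_edge("a", "c")


def test_asymmetric_r_rejected():
    r, q = _three_node_matrices()
    r.iat[0, 1] = 0.0
    with pytest.raises(ValueError, match="symmetric"):
        build_network(r, q)


def test_planted_block_denser_than_background():
    from metafunc.synthetic import SimulationConfig, generate_dataset
    from metafunc import cooccurrence_network

    fids = [f"COG{i+1:04d}" for i in range(30)]
    cfg = SimulationConfig(
        group_sizes=(60,), group_labels=("G",), n_functions=30,
        blocks=[(fids[:10], 0.95)], seed=19,
    )
    ds = generate_dataset(cfg)
    rel = normalize_relative(ds.profile)
    net = cooccurrence_network(rel, "G", n_perm=199, seed=1)
    block = set(fids[:10])
    inside = outside = 0
    for u, v in net.graph.edges:
        if u in block and v in block:
            inside += 1
        else:
            outside += 1
    density_in = inside / (10 * 9 / 2)
    density_out = outside / (30 * 29 / 2 - 45)
    assert density_in > density_out


# ------------------------------------------------- complexity indices


def _net_from_edges(nodes, edges, group="HC"):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, r=0.9, q=0.01, sign="+")
    return CooccurrenceNetwork(group, g)


def _cmap_for(nodes_by_cat):
    rows = []
    for cat, nodes in nodes_by_cat.items():
        for n in nodes:
            rows.append((n, cat, "metabolism"))
    frame = pd.DataFrame(rows, columns=["function", "category", "class"])
    return CategoryMap(frame.set_index("function"))


def test_active_index_star_isolated_and_path():
    net = _net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
    idx = active_index(net)
    assert idx["a"] == pytest.approx(0.5)
    assert idx["b"] == pytest.approx(1.0)
    assert idx["c"] == pytest.approx(0.5)
    iso = _net_from_edges(["a", "b", "c"], [("a", "b")])
    assert active_index(iso)["c"] == 0.0
    single = _net_from_edges(["a"], [])
    assert (active_index(single) == 0).all()


def test_internal_complexity_pair_counting():
    cmap = _cmap_for({"A": ["a1", "a2", "a3"], "B": ["b1"]})
    net = _net_from_edges(["a1", "a2", "a3", "b1"], [("a1", "a2"), ("a2", "a3")])
    ic = internal_complexity(net, cmap)
    assert ic["A"] == pytest.approx(2 / 3)
    assert ic["B"] == 0.0  # fewer than 2 members


def test_internal_complexity_complete_subgraph_is_one():
    cmap = _cmap_for({"A": ["a1", "a2", "a3"]})
    net = _net_from_edges(
        ["a1", "a2", "a3"], [("a1", "a2"), ("a2", "a3"), ("a1", "a3")]
    )
    assert internal_complexity(net, cmap)["A"] == pytest.approx(1.0)


def test_internal_complexity_empty_network_all_zero():
    cmap = _cmap_for({"A": ["a1", "a2"], "B": ["b1", "b2"]})
    net = _net_from_edges(["a1", "a2", "b1", "b2"], [])
    assert (internal_complexity(net, cmap) == 0).all()


def test_interaction_complexity_cross_pair_counting_and_symmetry():
    cmap = _cmap_for({"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]})
    net = _net_from_edges(["a1", "a2", "b1", "b2", "b3"], [("a1", "b2")])
    m = interaction_complexity(net, cmap)
    assert m.at["A", "B"] == pytest.approx(1 / 6)
    assert m.equals(m.T)
    # diagonal carries internal complexity
    assert m.at["A", "A"] == internal_complexity(net, cmap)["A"]


def test_complexity_invariant_to_node_relabeling():
    cmap1 = _cmap_for({"A": ["x", "y"], "B": ["z"]})
    net1 = _net_from_edges(["x", "y", "z"], [("x", "y"), ("y", "z")])
    cmap2 = _cmap_for({"A": ["p", "q"], "B": ["r"]})
    net2 = _net_from_edges(["p", "q", "r"], [("p", "q"), ("q", "r")])
    assert internal_complexity(net1, cmap1).equals(internal_complexity(net2, cmap2))
    v1 = interaction_complexity(net1, cmap1).to_numpy()
    v2 = interaction_complexity(net2, cmap2).to_numpy()
    np.testing.assert_allclose(v1, v2)
    assert ((v1 >= 0) & (v1 <= 1)).all()


def test_unmapped_node_rejected():
    cmap = _cmap_for({"A": ["a1"]})
    net = _net_from_edges(["a1", "zz"], [])
    with pytest.raises(KeyError, match="zz"):
        internal_complexity(net, cmap)


def test_exports_roundtrip(tmp_path):
    net = _net_from_edges(["a", "b", "c"], [("a", "b")])
    write_edge_list(net, tmp_path / "edges.tsv")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert list(edges.columns) == ["node1", "node2", "r", "q", "sign"]
    assert len(edges) == 1
    write_graphml(net, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert set(back.nodes) == {"a", "b", "c"}
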