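"""Signed functional co-occurrence networks and category complexity indices.

One network per study group: nodes are functions, and an edge joins two
functions whose Spearman correlation across that group's samples passes a
magnitude threshold (default |r| >= 0.8) at a permutation-FDR threshold
(default q < 0.05); the edge sign records the correlation direction.
Category-level structure is summarized by pair-normalized edge densities —
internal complexity (within-category edges over possible within-category
pairs) and interaction complexity (cross-category edges over possible cross
pairs) — and per-node connectivity by the active index, degree scaled to
[0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .difftest import bh_fdr
from .io_core import CategoryMap, FunctionalProfile


def correlation_matrix(
    profile: FunctionalProfile,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman r with permutation p and BH-FDR q matrices.

    Ranks use average ties. The permutation null shuffles the sample order
    of one member of each pair (one shared shuffle per randomization across
    all pairs), and p = (b+1)/(B+1) counts null |r| reaching the observed
    |r|. BH runs over the strict upper triangle; diagonals of p and q are
    NaN. Constant functions are dropped with a warning.
    """
    if method != "spearman":
        raise ValueError(f"unsupported correlation method: {method!r}")
    x = profile.data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation null", stacklevel=2)

    keep = np.ptp(x, axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant function(s) excluded from the network",
            stacklevel=2,
        )
    cols = profile.data.columns[keep]
    x = x[:, keep]
    m = x.shape[1]

    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    centered = ranks - ranks.mean(axis=0)
    normed = centered / np.linalg.norm(centered, axis=0)
    r_obs = normed.T @ normed
    np.fill_diagonal(r_obs, 1.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros((m, m))
    abs_obs = np.abs(r_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_null = normed.T @ normed[perm]
        exceed += np.abs(r_null) >= abs_obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    iu = np.triu_indices(m, k=1)
    # symmetrize: the permuted variable is arbitrary, so use the upper-triangle draw
    p_sym = np.full((m, m), np.nan)
    p_sym[iu] = p[iu]
    p_sym[(iu[1], iu[0])] = p[iu]

    q = np.full((m, m), np.nan)
    if iu[0].size:
        q_flat = bh_fdr(p[iu])
        q[iu] = q_flat
        q[(iu[1], iu[0])] = q_flat

    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return mk(r_obs), mk(p_sym), mk(q)


@dataclass
class CooccurrenceNetwork:
    """Per-group signed graph over functions."""

    group: str
    graph: nx.Graph  # nodes: function IDs; edge attrs: r, q, sign
    r_threshold: float = 0.8
    q_threshold: float = 0.05

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_positive(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "+")

    @property
    def n_negative(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "-")

    def summary(self) -> dict:
        return {
            "group": self.group,
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def build_network(
    r: pd.DataFrame,
    q: pd.DataFrame,
    r_threshold: float = 0.8,
    q_threshold: float = 0.05,
    group: str = "",
    prune: bool = False,
) -> CooccurrenceNetwork:
    """Apply the signed edge rule to r/q matrices.

    A positive edge requires r >= r_threshold and q < q_threshold; a
    negative edge requires r <= -r_threshold and q < q_threshold. All
    functions stay in the node list unless ``prune`` drops isolated ones.
    """
    if not r.index.equals(r.columns) or not q.index.equals(q.columns):
        raise ValueError("r and q must be square with matching labels")
    if not r.index.equals(q.index):
        raise ValueError("r and q labels disagree")
    rv = r.to_numpy(dtype=float)
    if not np.allclose(rv, rv.T, atol=1e-12):
        raise ValueError("r matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(r.index)
    for i, j in combinations(range(len(r.index)), 2):
        qv = q.iat[i, j]
        if np.isnan(qv) or qv >= q_threshold:
            continue
        rij = rv[i, j]
        if rij >= r_threshold:
            sign = "+"
        elif rij <= -r_threshold:
            sign = "-"
        else:
            continue
        g.add_edge(r.index[i], r.index[j], r=float(rij), q=float(qv), sign=sign)
    if prune:
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CooccurrenceNetwork(group, g, r_threshold, q_threshold)


def cooccurrence_network(
    profile: FunctionalProfile,
    group: str,
    r_threshold: float = 0.8,
    q_threshold: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    prune: bool = False,
) -> CooccurrenceNetwork:
    """Correlation matrix + edge rule for one study group's samples."""
    sub = profile.subset_group(group)
    r, _, q = correlation_matrix(sub, n_perm=n_perm, seed=seed)
    return build_network(r, q, r_threshold, q_threshold, group, prune)


def active_index(net: CooccurrenceNetwork) -> pd.Series:
    """Per-node degree scaled by the maximum possible degree (|nodes| - 1)."""
    g = net.graph
    n = g.number_of_nodes()
    denom = max(n - 1, 1)
    return pd.Series(
        {node: g.degree(node) / denom for node in g.nodes}, name="active_index"
    )


def _category_members(net: CooccurrenceNetwork, cmap: CategoryMap) -> dict[str, list]:
    members: dict[str, list] = {}
    for node in net.graph.nodes:
        members.setdefault(cmap.category_of(node), []).append(node)
    return members


def internal_complexity(net: CooccurrenceNetwork, cmap: CategoryMap) -> pd.Series:
    """Within-category edge density: edges inside c over C(n_c, 2); 0 if n_c < 2."""
    members = _category_members(net, cmap)
    cat_of = {n: cmap.category_of(n) for n in net.graph.nodes}
    within = {c: 0 for c in members}
    for u, v in net.graph.edges:
        cu, cv = cat_of[u], cat_of[v]
        if cu == cv:
            within[cu] += 1
    out = {}
    for c, nodes in members.items():
        n_c = len(nodes)
        pairs = n_c * (n_c - 1) // 2
        out[c] = within[c] / pairs if pairs else 0.0
    return pd.Series(out, name="internal_complexity").sort_index()


def interaction_complexity(net: CooccurrenceNetwork, cmap: CategoryMap) -> pd.DataFrame:
    """Cross-category edge density: edges between c1,c2 over n_c1*n_c2.

    The returned matrix is symmetric; its diagonal carries the internal
    complexity of each category.
    """
    members = _category_members(net, cmap)
    cats = sorted(members)
    sizes = {c: len(members[c]) for c in cats}
    cat_of = {n: cmap.category_of(n) for n in net.graph.nodes}
    cross = pd.DataFrame(0.0, index=cats, columns=cats)
    for u, v in net.graph.edges:
        cu, cv = cat_of[u], cat_of[v]
        if cu != cv:
            cross.at[cu, cv] += 1
            cross.at[cv, cu] += 1
    for c1 in cats:
        for c2 in cats:
            if c1 != c2:
                cross.at[c1, c2] /= sizes[c1] * sizes[c2]
    internal = internal_complexity(net, cmap)
    for c in cats:
        cross.at[c, c] = internal[c]
    return cross


def write_edge_list(net: CooccurrenceNetwork, path) -> None:
    rows = [
        (u, v, d["r"], d["q"], d["sign"])
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "r", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
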