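"""Cross-species matching: homolog reduction, HVGs, correlation adjustment,
match-graph construction and star pruning."""

import numpy as np
import pandas as pd
import pytest

import hypoatlas as ha
from hypoatlas import ValidationError
from hypoatlas.crossspecies import MatchConfig


def test_reduce_homologs_keeps_highest_similarity():
    table = pd.DataFrame(
        {
            "gene_a": ["gA", "gA", "gC"],
            "gene_b": ["gB1", "gB2", "gB1"],
            "similarity": [80.0, 95.0, 70.0],
        }
    )
    out = ha.reduce_homologs(table)
    pairs = set(zip(out.gene_a, out.gene_b))
    assert ("gA", "gB2") in pairs
    assert ("gA", "gB1") not in pairs
    # the map is injective in both directions
    assert out.gene_a.is_unique and out.gene_b.is_unique


def test_reduce_homologs_single_pair_and_ties():
    single = pd.DataFrame({"gene_a": ["x"], "gene_b": ["y"], "similarity": [50.0]})
    assert len(ha.reduce_homologs(single)) == 1
    tie = pd.DataFrame(
        {"gene_a": ["g", "g"], "gene_b": ["b2", "b1"], "similarity": [90.0, 90.0]}
    )
    out = ha.reduce_homologs(tie)
    assert out.gene_b.tolist() == ["b1"]  # lexicographically smaller partner
    dup = pd.DataFrame(
        {"gene_a": ["g", "g"], "gene_b": ["b", "b"], "similarity": [90.0, 80.0]}
    )
    with pytest.raises(ValidationError):
        ha.reduce_homologs(dup)


def test_shared_hvgs_intersection_and_tie_break():
    genes = [f"g{i}" for i in range(6)]
    flags_a = pd.DataFrame(
        [[1, 1, 1], [1, 1, 0], [1, 1, 0], [1, 0, 0], [0, 0, 0], [1, 1, 1]],
        index=genes, dtype=bool,
    )
    flags_b = pd.DataFrame(
        [[1, 1], [1, 1], [0, 0], [1, 1], [1, 1], [0, 0]], index=genes, dtype=bool
    )
    cfg = MatchConfig(hvg_per_species=3)
    var_a = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5], index=genes)
    shared = ha.select_shared_hvgs(flags_a, flags_b, cfg, variances_a=var_a)
    # species A top-3 by occurrence (ties at 2 broken by variance): g0, g5, g1
    # species B top-3: g0, g1, g3/g4 (occurrence ties broken by gene id)
    assert "g0" in shared and "g5" not in shared  # g5 flagged only rarely in B
    brute_a = {"g0", "g5", "g1"}
    brute_b = {"g0", "g1", "g3"}
    assert set(shared) == brute_a & brute_b
    with pytest.raises(ValidationError, match="stringency|shared"):
        ha.select_shared_hvgs(flags_a.iloc[:2], flags_b.iloc[4:], cfg)


def test_correlate_centroids_limits():
    rng = np.random.default_rng(0)
    cent = rng.normal(size=(2, 10))
    emb = np.vstack([cent[0]] * 3 + [cent[1]] * 3 + [cent[0]] * 2 + [-(cent[0] - cent[0].mean())] * 2)
    la = pd.Series(["a0"] * 3 + ["a1"] * 3, index=range(6))
    lb = pd.Series(["b0"] * 2 + ["b1"] * 2, index=range(6, 10))
    corr = ha.correlate_centroids(emb, la, lb)
    assert corr.loc["a0", "b0"] == pytest.approx(1.0)
    assert corr.loc["a0", "b1"] == pytest.approx(-1.0)
    with pytest.raises(ValidationError):
        ha.correlate_centroids(emb[:, :2], la, lb)


def test_random_centroids_rarely_correlate():
    rng = np.random.default_rng(1)
    emb = rng.normal(size=(60, 80))
    la = pd.Series(np.repeat([f"a{i}" for i in range(6)], 5), index=range(30))
    lb = pd.Series(np.repeat([f"b{i}" for i in range(6)], 5), index=range(30, 60))
    corr = ha.correlate_centroids(emb, la, lb)
    assert (corr.abs().to_numpy() < 0.5).mean() >= 0.99


def test_adjustment_arithmetic():
    # row (0.9, 0.8) where 0.8 is also its column max -> adjusted 0.7
    corr = pd.DataFrame([[0.9, 0.8], [0.5, 0.2]], index=["a0", "a1"], columns=["b0", "b1"])
    adj = ha.adjust_correlations(corr)
    assert adj.loc["a0", "b1"] == pytest.approx(min(2 * 0.8 - 0.9, 0.8))
    # an entry that is both its row and column maximum is unchanged
    assert adj.loc["a0", "b0"] == pytest.approx(0.9)


def test_adjustment_matches_brute_force_3x3():
    rng = np.random.default_rng(2)
    vals = rng.uniform(-1, 1, size=(3, 3))
    corr = pd.DataFrame(vals, index=list("xyz"), columns=list("uvw"))
    adj = ha.adjust_correlations(corr).to_numpy()
    for i in range(3):
        for j in range(3):
            row_m = vals[i].max()
            col_m = vals[:, j].max()
            expected = min(vals[i, j] - (row_m - vals[i, j]), vals[i, j] - (col_m - vals[i, j]))
            assert adj[i, j] == pytest.approx(expected)
    # one-sided modes
    row_only = ha.adjust_correlations(corr, mode="row").to_numpy()
    assert row_only[0, 0] == pytest.approx(2 * vals[0, 0] - vals[0].max())


def test_match_graph_threshold_is_strict_and_monotone():
    adj = pd.DataFrame([[0.7, 0.9], [0.2, 0.75]], index=["a0", "a1"], columns=["b0", "b1"])
    g = ha.build_match_graph(adj)
    assert not g.has_edge(("A", "a0"), ("B", "b0"))  # exactly 0.7 is excluded
    assert g.has_edge(("A", "a0"), ("B", "b1"))
    counts = [
        ha.build_match_graph(adj, MatchConfig(adjusted_threshold=t)).number_of_edges()
        for t in (0.1, 0.5, 0.8, 0.95)
    ]
    assert counts == sorted(counts, reverse=True)
    empty = ha.build_match_graph(adj, MatchConfig(adjusted_threshold=0.95))
    assert empty.number_of_edges() == 0
    assert empty.number_of_nodes() == 4  # unmatched clusters remain as nodes


def _graph(edges):
    adj = pd.DataFrame(
        0.0,
        index=sorted({a for a, _, _ in edges}),
        columns=sorted({b for _, b, _ in edges}),
    )
    for a, b, w in edges:
        adj.loc[a, b] = w
    return ha.build_match_graph(adj)


def test_prune_trace_from_documented_rule():
    """h1-m1 (0.9), h1-m2 (0.8), m1-h2 (0.85): h1 trims to its best edge,
    after which m1's neighbours are exclusive, leaving an M:1 star on m1."""
    g = _graph([("h1", "m1", 0.9), ("h1", "m2", 0.8), ("h2", "m1", 0.85)])
    out = ha.prune_match_graph(g)
    edges = {(u[1], v[1]) if u[0] == "A" else (v[1], u[1]) for u, v in out.edges}
    assert edges == {("h1", "m1"), ("h2", "m1")}
    assert all(out.edges[e]["relation"] == "M:1" for e in out.edges)


def test_isolated_edge_and_exclusive_star_are_kept():
    g = _graph([("h1", "m1", 0.8)])
    out = ha.prune_match_graph(g)
    assert out.number_of_edges() == 1
    assert list(out.edges(data="relation"))[0][2] == "1:1"
    star = _graph([("h1", "m1", 0.9), ("h1", "m2", 0.8), ("h1", "m3", 0.75)])
    out = ha.prune_match_graph(star)
    assert out.number_of_edges() == 3
    assert all(d == "1:N" for _, _, d in out.edges(data="relation"))


def brute_force_prune(edges):
    """Independent re-implementation of the pruning rule on plain dicts."""
    edges = dict(edges)
    nodes = sorted({n for e in edges for n in e})
    while True:
        changed = False
        for node in nodes:
            nbrs = [e for e in edges if node in e]
            if not nbrs:
                continue
            others = [e[0] if e[1] == node else e[1] for e in nbrs]
            deg = lambda v: sum(v in e for e in edges)
            if not any(deg(v) >= 2 for v in others):
                continue
            best = min(
                nbrs,
                key=lambda e: (-edges[e], (set(e) - {node}).pop()),
            )
            for e in nbrs:
                if e != best:
                    del edges[e]
                    changed = True
        if not changed:
            return set(edges)


def test_star_property_on_random_graphs_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(200):
        na, nb = rng.integers(2, 7), rng.integers(2, 7)
        adj = pd.DataFrame(
            rng.uniform(0, 1, size=(na, nb)),
            index=[f"a{i}" for i in range(na)],
            columns=[f"b{j}" for j in range(nb)],
        )
        g = ha.build_match_graph(adj, MatchConfig(adjusted_threshold=0.5))
        out = ha.prune_match_graph(g)
        # star property: no edge with both endpoints of degree >= 2
        for u, v in out.edges:
            assert out.degree(u) == 1 or out.degree(v) == 1
        ref = brute_force_prune(
            {
                (u, v): g.edges[u, v]["adjusted"]
                for u, v in ((min(e), max(e)) for e in g.edges)
            }
        )
        got = {(min(e), max(e)) for e in out.edges}
        assert got == ref


def test_match_summary_ordering_and_unmatched():
    g = _graph([("h1", "m1", 0.9), ("h1", "m2", 0.8), ("h1", "m3", 0.85)])
    out = ha.prune_match_graph(g)
    summ = ha.match_summary(out, clusters_a=["h1", "h9"], clusters_b=["m1", "m2", "m3"])
    assert (summ.cluster == "h9").sum() == 1
    assert summ.loc[summ.cluster == "h9", "unmatched"].item()
    partners = summ.loc[summ.cluster == "h1", "partners"].item().split(";")
    assert partners == ["m1", "m3", "m2"]  # descending correlation
    empty = ha.match_summary(ha.build_match_graph(pd.DataFrame(0.0, index=["a"], columns=["b"])))
    assert empty.unmatched.all()
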