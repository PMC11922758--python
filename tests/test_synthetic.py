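"""Contracts of the synthetic-data generators (determinism, planted truth)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import hypoatlas as ha
from hypoatlas import ValidationError


def test_hierarchy_determinism():
    spec = ha.HierarchySpec(levels=(2, 3), cells_per_leaf=30, seed=5)
    e1, c1, t1 = ha.simulate_hierarchy(spec)
    e2, c2, t2 = ha.simulate_hierarchy(spec)
    assert np.array_equal(e1, e2)
    pd.testing.assert_frame_equal(c1, c2)
    assert t1.to_dict() == t2.to_dict()


def test_sibling_leaf_centroids_at_planted_separation(small_hierarchy):
    """Empirical sibling-leaf centroid distances match the planted separation."""
    spec, embedding, cells, truth = small_hierarchy
    leaves = truth.nodes_at_level(1)
    # standard error of the distance between two empirical centroids
    se = spec.noise_sd * np.sqrt(2 * spec.embedding_dim / spec.cells_per_leaf)
    checked = 0
    for a, b in itertools.combinations(leaves, 2):
        if a.parent != b.parent:
            continue
        emp_a = embedding[a.cells].mean(axis=0)
        emp_b = embedding[b.cells].mean(axis=0)
        assert abs(np.linalg.norm(emp_a - emp_b) - spec.separation) < 3 * se
        checked += 1
    assert checked == 2


def test_zero_separation_gives_chance_recovery():
    spec = ha.HierarchySpec(levels=(4,), cells_per_leaf=60, separation=0.0, seed=1)
    embedding, cells, truth = ha.simulate_hierarchy(spec)
    ens = ha.run_leiden_ensemble(embedding, 1.0, n_runs=3, base_seed=0)
    labels = ha.consensus_partition(ens, seed=0)
    assert adjusted_rand_score(cells["true_C0"], labels) < 0.05


def test_hierarchy_validation_errors():
    with pytest.raises(ValidationError):
        ha.HierarchySpec(levels=(), cells_per_leaf=10)
    with pytest.raises(ValidationError):
        ha.HierarchySpec(levels=(2,), cells_per_leaf=0)
    with pytest.raises(ValidationError):
        ha.HierarchySpec(levels=(2,), embedding_dim=-1)


def test_cell_assignments_are_complete(small_hierarchy):
    spec, embedding, cells, truth = small_hierarchy
    assert len(cells) == spec.n_leaves * spec.cells_per_leaf
    assert cells["cell_id"].is_unique
    for col in ("donor_id", "batch_id"):
        assert cells[col].notna().all()
    truth.validate_nested()


def test_counts_contracts(small_hierarchy, small_counts):
    _, _, cells, truth = small_hierarchy
    counts, markers = small_counts
    totals = np.asarray(counts.matrix.sum(axis=1)).ravel()
    assert (totals > 0).all()
    assert set(markers) == {n.id for n in truth.nodes_at_level(1)}
    assert all(len(v) == 4 for v in markers.values())
    # determinism
    again, _ = ha.simulate_counts(
        truth, cells, n_genes=120, markers_per_leaf=4, batch_effect_sd=0.3, seed=7
    )
    assert (counts.matrix != again.matrix).nnz == 0


def test_counts_marker_budget_validated(small_hierarchy):
    _, _, cells, truth = small_hierarchy
    with pytest.raises(ValidationError):
        ha.simulate_counts(truth, cells, n_genes=10, markers_per_leaf=5)


def test_planted_marker_detected_and_null_markers_absent(small_hierarchy):
    """A 10x planted marker reaches Bonferroni significance; without planted
    markers no gene exceeds the nominal false-positive rate by much."""
    _, _, cells, truth = small_hierarchy
    counts, markers = ha.simulate_counts(
        truth, cells, n_genes=200, markers_per_leaf=2, marker_fold=10.0, seed=3
    )
    labels = truth.labels_at_level(1)
    batch = cells["batch_id"].to_numpy()
    leaf = truth.nodes_at_level(1)[0].id
    table = ha.find_markers(counts, labels, batch, leaf).set_index("gene")
    assert (table.loc[markers[leaf], "padj"] < 0.05).all()

    null_counts, _ = ha.simulate_counts(
        truth, cells, n_genes=500, markers_per_leaf=0, seed=4
    )
    null_table = ha.find_markers(null_counts, labels, batch, leaf)
    assert (null_table["pval"] < 0.05).mean() < 0.10


def test_species_pair_bookkeeping_and_zero_divergence():
    spec = ha.SpeciesPairSpec(
        shared_leaves=6, a_only_leaves=5, b_only_leaves=2,
        divergence_sd=0.0, noise_sd=1e-9, cells_per_leaf=10, seed=2,
    )
    emb, species, labels, truth = ha.simulate_species_pair(spec)
    assert len(truth) == 6
    a_clusters = {l for l in labels[species == "A"]}
    assert len(a_clusters - set(truth["cluster_a"])) == 5  # exactly 5 unmatched A clusters
    idx = np.arange(len(labels))
    corr = ha.correlate_centroids(
        emb,
        pd.Series(labels[species == "A"], index=idx[species == "A"]),
        pd.Series(labels[species == "B"], index=idx[species == "B"]),
    )
    for i in range(6):
        assert corr.loc[f"A{i}", f"B{i}"] == pytest.approx(1.0, abs=1e-6)


def test_species_pair_validates_homolog_fraction():
    with pytest.raises(ValidationError):
        ha.SpeciesPairSpec(homolog_fraction=1.5)


def test_spatial_generator_contracts():
    aff = ha.planted_affinity(4, 3, 2, signal=10, baseline=1)
    # one flat row plus a constant-affinity row behave identically: NA truth
    spec = ha.SpatialSpec(4, 10, 5, tuple(map(tuple, aff)), noise_sd=0.5, seed=0)
    abundance, regions, truth = ha.simulate_spatial(spec)
    assert (abundance.to_numpy() >= 0).all()
    assert truth["K0"] == "R0" and truth["K1"] == "R1"
    assert truth["K3"] is None and truth["K4"] is None
    assert regions.notna().all() and len(regions) == 40
    # determinism
    abundance2, _, _ = ha.simulate_spatial(spec)
    pd.testing.assert_frame_equal(abundance, abundance2)


def test_gwas_tables_contracts():
    spec_df, rank_df = ha.simulate_gwas_tables(2000, 8, 30, seed=1)
    ranks = np.sort(rank_df["rank"].to_numpy())
    assert np.array_equal(ranks, np.arange(1, 2001))
    assert spec_df.to_numpy().min() >= 0 and spec_df.to_numpy().max() <= 1
    # no planted effectors -> selection returns nothing
    spec0, rank0 = ha.simulate_gwas_tables(2000, 8, 0, seed=1)
    assert len(ha.select_effector_genes(spec0, rank0)) == 0
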