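"""Embedding, Leiden compartments, profile matching, markers, DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from issgraph import (MARKER_PANEL, cluster, cluster_profiles,
                      differential_expression, embed, match_clusters,
                      normalize_matrix, subset_panel)
from issgraph.compart import (CompartmentMap, EmbeddingResult,
                              linkage_to_newick)
from issgraph.exprmat import filter_matrix
from issgraph.simdata import simulate_tissue_expression


@pytest.fixture(scope="module")
def tissue():
    expr, labels = simulate_tissue_expression(seed=0)
    return expr, labels


@pytest.fixture(scope="module")
def normalized_tissue(tissue):
    expr, labels = tissue
    filt = filter_matrix(expr, min_gene_total=100, min_patch_reads=10)
    kept = expr.patches["patch_id"].isin(filt.patches["patch_id"])
    return filt, normalize_matrix(filt), labels[kept.to_numpy()]


class TestEmbed:
    def test_rgb_embedding_in_unit_cube(self, normalized_tissue):
        _, norm, _ = normalized_tissue
        emb = embed(norm, dims=3, seed=0)
        assert emb.coordinates.shape[1] == 3
        assert emb.coordinates.min() >= 0.0
        assert emb.coordinates.max() <= 1.0

    def test_programs_separate(self, normalized_tissue):
        _, norm, labels = normalized_tissue
        emb = embed(norm, dims=3, seed=0)
        X = emb.coordinates
        intra, inter = [], []
        rng = np.random.default_rng(0)
        for _ in range(500):
            i, j = rng.integers(len(X), size=2)
            d = np.linalg.norm(X[i] - X[j])
            (intra if labels[i] == labels[j] else inter).append(d)
        assert np.mean(inter) > 2 * np.mean(intra)

    def test_deterministic_given_seed(self, normalized_tissue):
        _, norm, _ = normalized_tissue
        e1 = embed(norm, dims=3, seed=5)
        e2 = embed(norm, dims=3, seed=5)
        assert np.array_equal(e1.coordinates, e2.coordinates)

    def test_panel_mismatch_rejected(self, normalized_tissue):
        _, norm, _ = normalized_tissue
        other, _ = simulate_tissue_expression(n_noise_genes=2, seed=1)
        other = normalize_matrix(other)
        with pytest.raises(ValueError, match="panel"):
            embed([norm, other], dims=3, seed=0)

    def test_raw_matrix_rejected(self, tissue):
        expr, _ = tissue
        with pytest.raises(ValueError, match="normalized"):
            embed(expr, dims=3, seed=0)


class TestCluster:
    def test_planted_regions_recovered(self, normalized_tissue):
        _, norm, labels = normalized_tissue
        emb = embed(norm, dims=50, seed=0)
        cmap = cluster(emb, resolution=1.0, seed=0)
        assert adjusted_rand_score(labels, cmap.labels) >= 0.9

    def test_identical_patches_single_cluster(self):
        emb = EmbeddingResult(coordinates=np.zeros((40, 5)),
                              sample_ids=np.zeros(40, dtype=int), dims=5,
                              seed=0)
        cmap = cluster(emb, resolution=1.0, seed=0)
        assert cmap.n_clusters == 1

    def test_deterministic_given_seed(self, normalized_tissue):
        _, norm, _ = normalized_tissue
        emb = embed(norm, dims=50, seed=1)
        c1 = cluster(emb, seed=2)
        c2 = cluster(emb, seed=2)
        assert np.array_equal(c1.labels, c2.labels)

    def test_too_few_patches_rejected(self):
        emb = EmbeddingResult(coordinates=np.zeros((10, 5)),
                              sample_ids=np.zeros(10, dtype=int), dims=5,
                              seed=0)
        with pytest.raises(ValueError):
            cluster(emb, k_neighbors=15)


def _map_for(expr, labels):
    return CompartmentMap(labels=np.asarray(labels),
                          sample_ids=np.zeros(len(labels), dtype=int),
                          n_clusters=int(np.max(labels)) + 1,
                          resolution=1.0, seed=0)


class TestClusterProfiles:
    def test_profiles_sum_to_one(self, tissue):
        expr, labels = tissue
        profiles = cluster_profiles(expr, _map_for(expr, labels))
        assert np.allclose(profiles.sum(axis=1), 1.0, atol=1e-12)

    def test_duplicate_patches_match_single(self, tissue):
        expr, _ = tissue
        from dataclasses import replace

        two = replace(expr, counts=np.vstack([expr.counts[:1]] * 2),
                      patches=expr.patches.iloc[[0, 0]].reset_index(
                          drop=True))
        profiles = cluster_profiles(two, _map_for(two, [0, 0]))
        single = expr.counts[0] / expr.counts[0].sum()
        assert np.allclose(profiles.iloc[0].to_numpy(), single)

    def test_region_profile_concentrates_on_program(self, tissue):
        expr, labels = tissue
        profiles = cluster_profiles(expr, _map_for(expr, labels))
        prof0 = profiles.loc[(0, 0)]
        program = list(range(0, 6)) + list(range(18, 21))
        assert prof0.iloc[program].sum() > 0.9


class TestMatchClusters:
    def _two_sample_profiles(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = np.eye(4) * 0.8 + 0.05
        rows, idx = [], []
        for s in range(2):
            for c in range(4):
                p = base[c] + rng.uniform(0, noise, 4)
                rows.append(p / p.sum())
                idx.append((s, c))
        return pd.DataFrame(rows, columns=list("wxyz"),
                            index=pd.MultiIndex.from_tuples(
                                idx, names=["sample", "cluster"]))

    def test_identical_profiles_pair_first(self):
        profiles = self._two_sample_profiles(noise=0.0)
        link, groups = match_clusters(profiles, n_groups=4)
        for c in range(4):
            assert groups.loc[(0, c)] == groups.loc[(1, c)]
        assert groups.nunique() == 4

    def test_shared_regions_pair_across_samples(self):
        profiles = self._two_sample_profiles(noise=0.05, seed=3)
        _, groups = match_clusters(profiles, n_groups=4)
        for c in range(4):
            assert groups.loc[(0, c)] == groups.loc[(1, c)]

    def test_constant_profile_rejected(self):
        profiles = self._two_sample_profiles()
        profiles.iloc[0] = 0.25
        with pytest.raises(ValueError, match="constant"):
            match_clusters(profiles)

    def test_single_sample_rejected(self, tissue):
        expr, labels = tissue
        profiles = cluster_profiles(expr, _map_for(expr, labels))
        with pytest.raises(ValueError):
            match_clusters(profiles)

    def test_newick_serialization(self):
        profiles = self._two_sample_profiles(noise=0.02, seed=1)
        link, _ = match_clusters(profiles, n_groups=4)
        nwk = linkage_to_newick(link, [f"{s}_{c}" for s, c in profiles.index])
        assert nwk.endswith(";")
        assert nwk.count(",") == len(profiles) - 1


class TestSubsetPanel:
    def test_default_panel_is_18_genes(self, tissue):
        expr, _ = tissue
        sub = subset_panel(expr)
        assert len(sub.genes) == 18
        assert sub.genes == list(MARKER_PANEL)

    def test_column_subset(self, tissue):
        expr, _ = tissue
        sub = subset_panel(expr, ["Pvalb", "Rorb"])
        assert sub.counts.shape == (len(expr.patches), 2)
        assert np.array_equal(sub.counts[:, 0],
                              expr.counts[:, expr.genes.index("Pvalb")])

    def test_full_panel_identity(self, tissue):
        expr, _ = tissue
        sub = subset_panel(expr, expr.genes)
        assert np.array_equal(sub.counts, expr.counts)

    def test_unknown_marker_listed(self, tissue):
        expr, _ = tissue
        with pytest.raises(ValueError, match="Nope"):
            subset_panel(expr, ["Pvalb", "Nope"])


class TestDifferentialExpression:
    def test_program_gene_tops_its_region(self, tissue):
        expr, labels = tissue
        table = differential_expression(expr, _map_for(expr, labels),
                                        exclude_genes=MARKER_PANEL)
        for reg in range(3):
            sub = table[table["compartment"] == reg]
            top = sub.iloc[0]
            assert top["q"] < 0.05
            expected = {f"prog_extra{reg * 3 + i}" for i in range(3)}
            assert sub.head(3)["gene"].isin(expected).all()

    @staticmethod
    def _flat_expr(counts):
        from issgraph.exprmat import PatchExpression, PatchGrid

        grid = PatchGrid(extent=(counts.shape[0] * 128, 128))
        table = grid.patch_table().iloc[:counts.shape[0]].reset_index(
            drop=True)
        return PatchExpression(
            counts=counts, genes=[f"flat{i}"
                                  for i in range(counts.shape[1])],
            patches=table)

    def test_label_permutation_uniform_p(self):
        """Permuted labels give uniform p-values over many flat genes."""
        rng = np.random.default_rng(5)
        expr = self._flat_expr(rng.poisson(5.0, size=(60, 1000)))
        labels = rng.integers(0, 2, size=60)
        table = differential_expression(expr, _map_for(expr, labels))
        pvals = table[table["compartment"] == 0]["p"].to_numpy()
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_distributions_zero_lfc(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(8.0, size=(30, 20))
        expr = self._flat_expr(np.vstack([base, base]))
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        table = differential_expression(expr, _map_for(expr, labels))
        assert np.allclose(table["log_fold_change"], 0.0, atol=1e-12)
        assert (table["q"] > 0.9).all()

    def test_small_compartment_skipped(self, tissue):
        expr, labels = tissue
        labels = labels.copy()
        labels[:2] = 7  # a 2-patch pseudo-compartment
        with pytest.warns(UserWarning, match="skipped"):
            table = differential_expression(expr, _map_for(expr, labels))
        assert 7 not in set(table["compartment"])
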