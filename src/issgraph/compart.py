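"""Spatial compartments from patch expression profiles.

Normalized patch profiles from one or more tissue sections are embedded
jointly with UMAP — into 3 dimensions for RGB visualization of spatial
expression variation, or into 50 dimensions for clustering.  Compartments
are Leiden communities of the k-nearest-neighbor graph on the embedding;
their expression profiles (normalized by cluster area and total counts) are
matched across sections by correlation-based hierarchical clustering.  A
reduced 18-marker-gene workflow and per-compartment differential expression
(rank-sum versus rest, Benjamini-Hochberg corrected) round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.neighbors import kneighbors_graph

# Reduced marker panel: 6 inhibitory, 6 pan-excitatory, 2 neocortical-layer
# (Rorb L4, Penk L6), and 4 shared excitatory/inhibitory markers.
MARKER_PANEL = (
    "Pvalb", "Vip", "Cck", "Fam19a1", "Calb1", "Calb2",
    "Rprm", "Crym", "Wfs1", "Pcp4", "Plcxd2", "3110035E14Rik",
    "Rorb", "Penk",
    "Slc24a2", "Bcl11b", "Gda", "Rgs4",
)


@dataclass
class EmbeddingResult:
    """Joint UMAP embedding over concatenated samples."""

    coordinates: np.ndarray         # (n_patches_total, dims)
    sample_ids: np.ndarray          # sample index per row
    dims: int
    seed: int
    params: dict = field(default_factory=dict)

    def per_sample(self):
        return [self.coordinates[self.sample_ids == s]
                for s in np.unique(self.sample_ids)]


@dataclass
class CompartmentMap:
    """Leiden labels per patch, grouped per sample."""

    labels: np.ndarray              # global label per row of the embedding
    sample_ids: np.ndarray
    n_clusters: int
    resolution: float
    seed: int

    def labels_for(self, sample: int) -> np.ndarray:
        return self.labels[self.sample_ids == sample]


def _as_list(expr):
    return list(expr) if isinstance(expr, (list, tuple)) else [expr]


def embed(expr, dims: int = 50, seed: int = 0, n_neighbors: int = 15,
          min_dist: float = 0.1) -> EmbeddingResult:
    """UMAP-embed one or more normalized expression matrices jointly.

    All matrices must share the gene panel and be normalized.  For
    ``dims=3`` each axis is min-max normalized to [0, 1] so coordinates read
    directly as RGB colors.
    """
    import umap

    mats = _as_list(expr)
    panel = mats[0].genes
    for m in mats:
        if m.genes != panel:
            raise ValueError("gene panels differ between samples")
        if m.state != "normalized":
            raise ValueError("embed expects normalized matrices")
    X = np.vstack([m.counts for m in mats])
    sample_ids = np.concatenate([np.full(len(m.counts), i)
                                 for i, m in enumerate(mats)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns on forced determinism
        reducer = umap.UMAP(n_components=dims, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    if dims == 3:
        span = coords.max(axis=0) - coords.min(axis=0)
        span[span == 0] = 1.0
        coords = (coords - coords.min(axis=0)) / span
    return EmbeddingResult(coordinates=coords, sample_ids=sample_ids,
                           dims=dims, seed=seed,
                           params={"n_neighbors": n_neighbors,
                                   "min_dist": min_dist})


def cluster(embedding: EmbeddingResult, resolution: float = 1.0,
            seed: int = 0, k_neighbors: int = 15) -> CompartmentMap:
    """Leiden communities of the kNN graph on the embedding coordinates."""
    X = embedding.coordinates
    n = len(X)
    if n <= k_neighbors:
        raise ValueError(f"need more than {k_neighbors} patches, got {n}")
    adj = kneighbors_graph(X, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership, dtype=int)
    return CompartmentMap(labels=labels, sample_ids=embedding.sample_ids,
                          n_clusters=int(labels.max()) + 1,
                          resolution=resolution, seed=seed)


def cluster_profiles(expr, cmap: CompartmentMap) -> pd.DataFrame:
    """Cluster expression profiles from *raw* counts.

    Per cluster: sum raw gene counts over member patches, divide by cluster
    area (number of patches), then scale to unit total over genes.  Rows are
    ``(sample, cluster)``.
    """
    mats = _as_list(expr)
    rows, index = [], []
    for s, m in enumerate(mats):
        if m.state != "raw":
            raise ValueError("cluster_profiles expects raw counts")
        labels = cmap.labels_for(s)
        if len(labels) != len(m.counts):
            raise ValueError("labels do not cover the matrix patches")
        for lab in np.unique(labels):
            member = m.counts[labels == lab]
            if member.shape[0] == 0:
                raise ValueError(f"empty cluster {lab} in sample {s}")
            profile = member.sum(axis=0) / member.shape[0]
            total = profile.sum()
            if total == 0:
                raise ValueError(
                    f"cluster {lab} in sample {s} has zero counts")
            rows.append(profile / total)
            index.append((s, int(lab)))
    return pd.DataFrame(rows, columns=mats[0].genes,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["sample", "cluster"]))


def match_clusters(profiles: pd.DataFrame, n_groups: int | None = None):
    """Match compartments across samples by profile correlation.

    Average-linkage hierarchical clustering on ``1 - Pearson r`` between all
    cluster profiles.  Returns ``(linkage, groups)`` where ``groups`` maps
    each ``(sample, cluster)`` to a flat correspondence group; ``n_groups``
    (e.g. 20 for a top-20 compartment view) controls the tree cut and
    defaults to the number of profiles in the largest sample.
    """
    if profiles.index.get_level_values("sample").nunique() < 2:
        raise ValueError("need clusters from at least 2 samples")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [str(profiles.index[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError("constant profile(s), correlation undefined: "
                         + ", ".join(bad))
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False),
                             method="average")
    if n_groups is None:
        n_groups = int(profiles.groupby(level="sample").size().max())
    flat = hierarchy.fcluster(link, t=min(n_groups, len(X)),
                              criterion="maxclust")
    groups = pd.Series(flat, index=profiles.index, name="group")
    return link, groups


def linkage_to_newick(link, labels) -> str:
    """Serialize a SciPy linkage as a Newick string."""
    tree = hierarchy.to_tree(link)

    def walk(node):
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def subset_panel(expr, marker_genes=MARKER_PANEL):
    """Column-subset raw counts to a marker panel (18 genes by default)."""
    markers = list(marker_genes)
    if expr.state != "raw":
        raise ValueError("subset_panel operates on raw counts")
    unknown = [g for g in markers if g not in expr.genes]
    if unknown:
        raise ValueError("markers absent from the panel: " + ", ".join(unknown))
    cols = [expr.genes.index(g) for g in markers]
    from dataclasses import replace

    return replace(expr, counts=expr.counts[:, cols], genes=markers,
                   gene_read_totals={g: expr.gene_read_totals.get(g, 0)
                                     for g in markers})


def differential_expression(expr, cmap: CompartmentMap,
                            exclude_genes=(), min_patches: int = 3,
                            ) -> pd.DataFrame:
    """Rank-sum DE of each compartment versus the rest.

    Per compartment and gene: two-sided Wilcoxon rank-sum test (Mann-Whitney
    U with tie correction; counts are heavily tied) and p,
    Benjamini-Hochberg q (within compartment), and the log fold-change of
    mean raw counts (+1 pseudocount).  Compartments with fewer than
    ``min_patches`` members are skipped with a warning.  Rows are sorted by
    q within each compartment.
    """
    mats = _as_list(expr)
    counts = np.vstack([m.counts for m in mats]).astype(float)
    genes = [g for g in mats[0].genes if g not in set(exclude_genes)]
    cols = [mats[0].genes.index(g) for g in genes]
    counts = counts[:, cols]
    labels = cmap.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("differential expression needs >= 2 compartments")
    out = []
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() < min_patches:
            warnings.warn(f"compartment {lab} has < {min_patches} patches; "
                          "skipped")
            continue
        inside, outside = counts[mask], counts[~mask]
        res = stats.mannwhitneyu(inside, outside, axis=0,
                                 alternative="two-sided",
                                 method="asymptotic")
        stat, p = res.statistic, res.pvalue
        q = _benjamini_hochberg(p)
        lfc = np.log((inside.mean(axis=0) + 1.0) /
                     (outside.mean(axis=0) + 1.0))
        df = pd.DataFrame({"compartment": lab, "gene": genes,
                           "statistic": stat, "p": p, "q": q,
                           "log_fold_change": lfc})
        out.append(df.sort_values("q", kind="stable"))
    return pd.concat(out, ignore_index=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0.0, 1.0)
    return q
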