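"""Patch-level gene expression matrix: counting, filtering, normalization.

Quality-filtered reads are aggregated over overlapping square patches laid
on a regular grid: tiles of ``tile_size`` pixels (the grid stride) with an
``overlap`` margin on each side, so each patch counts reads from a window of
``tile_size + 2 * overlap`` pixels.  With the defaults (128 px tiles,
128 px overlap) each patch covers a 384 x 384 px region and every read
contributes to up to nine patches.  Matrices are normalized by Anscombe
variance stabilization, regression of per-patch log totals, and per-gene
standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def patch_footprint(tile_size: int, overlap: int) -> int:
    """Window side covered by one patch: ``tile_size + 2 * overlap``."""
    if tile_size < 0 or overlap < 0:
        raise ValueError("tile_size and overlap must be >= 0")
    return tile_size + 2 * overlap


@dataclass
class PatchGrid:
    """Regular grid of overlapping square patches.

    Patches are strided by ``tile_size``; each extends ``overlap`` pixels
    beyond its tile on every side.  Membership intervals are half-open
    ``[x0, x0 + window)``.
    """

    extent: tuple               # (width, height) in pixels
    tile_size: int = 128
    overlap: int = 128

    @property
    def window_size(self) -> int:
        return patch_footprint(self.tile_size, self.overlap)

    def patch_table(self) -> pd.DataFrame:
        """One row per patch: id, tile origin, window origin, center."""
        w, h = self.extent
        rows = []
        pid = 0
        for ty in range(0, h, self.tile_size):
            for tx in range(0, w, self.tile_size):
                x0, y0 = tx - self.overlap, ty - self.overlap
                rows.append({"patch_id": pid, "tile_x": tx, "tile_y": ty,
                             "x0": x0, "y0": y0,
                             "cx": tx + self.tile_size / 2,
                             "cy": ty + self.tile_size / 2})
                pid += 1
        return pd.DataFrame(rows)


@dataclass
class PatchExpression:
    """Patches x genes matrix with coordinates and normalization state."""

    counts: np.ndarray                  # float after normalization
    genes: list
    patches: pd.DataFrame               # from PatchGrid.patch_table()
    state: str = "raw"                  # raw | normalized
    gene_read_totals: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.patches), len(self.genes)):
            raise ValueError("counts shape does not match patches x genes")

    @property
    def total_reads_per_patch(self) -> np.ndarray:
        if self.state != "raw":
            return np.asarray(self.meta["raw_totals"])
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.genes,
                            index=self.patches["patch_id"].to_numpy())

    def to_anndata(self):
        """Bridge to an AnnData with patch coordinates in ``obsm``."""
        import anndata

        ad = anndata.AnnData(X=self.counts.astype(float),
                             obs=self.patches.set_index(
                                 self.patches["patch_id"].astype(str)),
                             var=pd.DataFrame(index=self.genes))
        ad.obsm["spatial"] = self.patches[["cx", "cy"]].to_numpy()
        return ad

    def write_mtx(self, prefix) -> None:
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        sio.mmwrite(f"{prefix}.mtx", csr_matrix(self.counts))
        pd.Series(self.genes).to_csv(f"{prefix}_genes.tsv", sep="\t",
                                     index=False, header=False)
        self.patches.to_csv(f"{prefix}_patches.tsv", sep="\t", index=False)


def count_matrix(reads, grid: PatchGrid, gene_panel) -> PatchExpression:
    """Count quality-filtered reads per (patch window, gene).

    A read falls in every patch whose half-open window contains it, so with
    overlapping windows one read contributes to several entries.  Reads
    outside all patch windows or with genes outside the panel are dropped
    (count logged).
    """
    genes = list(gene_panel)
    if not genes:
        raise ValueError("gene panel is empty")
    gidx = {g: i for i, g in enumerate(genes)}
    table = grid.patch_table()
    counts = np.zeros((len(table), len(genes)), dtype=int)
    x0 = table["x0"].to_numpy()
    y0 = table["y0"].to_numpy()
    win = grid.window_size
    totals: dict = {g: 0 for g in genes}
    dropped = 0
    for r in reads:
        gi = gidx.get(r.gene)
        if gi is None:
            dropped += 1
            continue
        inside = ((x0 <= r.x) & (r.x < x0 + win) &
                  (y0 <= r.y) & (r.y < y0 + win))
        if not inside.any():
            dropped += 1
            continue
        totals[r.gene] += 1
        counts[np.flatnonzero(inside), gi] += 1
    if dropped:
        logger.info("count_matrix: %d reads outside panel/grid ignored",
                    dropped)
    return PatchExpression(counts=counts, genes=genes, patches=table,
                           gene_read_totals=totals,
                           meta={"dropped_reads": dropped,
                                 "window_size": win})


def filter_matrix(expr: PatchExpression, min_gene_total: int = 500,
                  min_patch_reads: int = 10) -> PatchExpression:
    """Drop low-expressed genes, then sparsely covered patches.

    Gene totals are the per-sample read totals recorded at counting time
    (pre-patch, so overlap multiplicity does not inflate them); genes with
    total < ``min_gene_total`` go first, then patches with fewer than
    ``min_patch_reads`` reads (window counts over the kept genes).
    """
    if expr.state != "raw":
        raise ValueError("filter_matrix expects raw counts")
    totals = expr.gene_read_totals or {
        g: int(t) for g, t in zip(expr.genes, expr.counts.sum(axis=0))}
    keep_genes = [g for g in expr.genes if totals.get(g, 0) >= min_gene_total]
    dropped_genes = [g for g in expr.genes if g not in keep_genes]
    gcols = [expr.genes.index(g) for g in keep_genes]
    counts = expr.counts[:, gcols]
    patch_reads = counts.sum(axis=1)
    keep_patches = patch_reads >= min_patch_reads
    dropped_patches = expr.patches.loc[~keep_patches, "patch_id"].tolist()
    counts = counts[keep_patches]
    if counts.size == 0:
        raise ValueError(
            f"filtering removed everything (dropped {len(dropped_genes)} "
            f"genes, {int((~keep_patches).sum())} patches)")
    return PatchExpression(
        counts=counts, genes=keep_genes,
        patches=expr.patches.loc[keep_patches].reset_index(drop=True),
        gene_read_totals={g: totals[g] for g in keep_genes},
        meta={**expr.meta, "dropped_genes": dropped_genes,
              "dropped_patches": dropped_patches, "filtered": True})


def anscombe(x):
    """Variance-stabilizing transform for counts: ``2 sqrt(x + 3/8)``."""
    return 2.0 * np.sqrt(np.asarray(x, dtype=float) + 0.375)


def normalize_matrix(expr: PatchExpression) -> PatchExpression:
    """Anscombe -> regress out log totals -> per-gene standardization.

    Per gene, an ordinary least-squares fit of the Anscombe-transformed
    values on ``log(total raw reads per patch + 1)`` is replaced by its
    residuals (removing variation driven by local cell density), then each
    gene column is scaled to zero mean and unit variance.  Re-normalizing an
    already normalized matrix is rejected.
    """
    if expr.state != "raw":
        raise ValueError(f"matrix already in state {expr.state!r}")
    raw_totals = expr.counts.sum(axis=1).astype(float)
    X = anscombe(expr.counts)
    logt = np.log(raw_totals + 1.0)
    design = np.column_stack([np.ones_like(logt), logt])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0)
    zero_var = sd <= 1e-10 * max(1.0, float(np.abs(X).max()))
    if zero_var.any():
        warnings.warn("zero-variance gene(s) after regression set to 0: "
                      + ", ".join(np.array(expr.genes)[zero_var]))
        sd = np.where(zero_var, 1.0, sd)
    scaled = (resid - resid.mean(axis=0)) / sd
    scaled[:, zero_var] = 0.0
    return replace(expr, counts=scaled, state="normalized",
                   meta={**expr.meta, "raw_totals": raw_totals})
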