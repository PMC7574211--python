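"""Comparison of decoded spatial gene patterns with reference grids.

Per-gene read positions are turned into probability density functions on a
coarse voxel-style grid (Gaussian kernel density estimate, covariance factor
0.05) and compared against reference expression grids — e.g. one coronal
level of an in situ hybridization atlas — by Kullback-Leibler divergence.
The "covariance factor" is the KDE bandwidth scaling applied to the data
covariance (SciPy's ``gaussian_kde`` factor); see the methods note for the
alternative readings of that term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

KL_EPS = 1e-12  # floor on the reference density inside the log


@dataclass
class SpatialPattern:
    """Normalized 2-D expression density for one gene."""

    density: np.ndarray
    gene: str
    provenance: str = "ISS"         # ISS | reference
    grid_spacing: float = 1.0

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if (self.density < 0).any():
            raise ValueError("density must be non-negative")

    @property
    def normalized(self) -> bool:
        return bool(np.isclose(self.density.sum(), 1.0, atol=1e-9))

    def normalize(self) -> "SpatialPattern":
        total = self.density.sum()
        if total <= 0:
            raise ValueError(f"pattern for {self.gene} has zero mass")
        return SpatialPattern(self.density / total, self.gene,
                              self.provenance, self.grid_spacing)


def pattern_from_reads(reads, target_grid_shape,
                       extent=None, kde_covariance_factor: float = 0.05,
                       gene: str | None = None) -> SpatialPattern:
    """KDE density of one gene's read positions on a target grid.

    Read coordinates are rescaled from the image ``extent`` (``(width,
    height)``; defaults to the reads' bounding box) onto the
    ``target_grid_shape = (n_rows, n_cols)`` grid, a Gaussian KDE with the
    given covariance factor is evaluated at the grid cell centers, and the
    result is normalized to total mass 1.  At least two reads are required.
    """
    pts = np.array([[r.x, r.y] for r in reads], dtype=float)
    if len(pts) < 2:
        raise ValueError("KDE needs at least 2 reads")
    n_rows, n_cols = target_grid_shape
    if extent is None:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
    else:
        lo = np.zeros(2)
        span = np.asarray(extent, dtype=float)
    # scale image coordinates onto the voxel grid
    scaled = (pts - lo) / span * np.array([n_cols, n_rows])
    try:
        kde = stats.gaussian_kde(scaled.T, bw_method=kde_covariance_factor)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate read geometry for KDE") from err
    cols, rows = np.meshgrid(np.arange(n_cols) + 0.5,
                             np.arange(n_rows) + 0.5)
    density = kde(np.vstack([cols.ravel(), rows.ravel()])).reshape(
        n_rows, n_cols)
    name = gene if gene is not None else getattr(reads[0], "gene", "?")
    return SpatialPattern(density, gene=name, provenance="ISS").normalize()


def pattern_from_grid(grid, gene: str) -> SpatialPattern:
    """Wrap a reference expression grid (already voxelized) as a pattern."""
    return SpatialPattern(np.asarray(grid, dtype=float), gene=gene,
                          provenance="reference").normalize()


def kl_divergence(p: SpatialPattern, q: SpatialPattern) -> float:
    """KL(p || q) between normalized patterns on the same grid.

    The reference density ``q`` is floored at ``1e-12`` inside the log so the
    divergence stays finite on sparse grids.  Non-negative; zero iff the
    patterns coincide (up to floor effects).
    """
    if p.density.shape != q.density.shape:
        raise ValueError(f"grid shapes differ: {p.density.shape} vs "
                         f"{q.density.shape}")
    pd_, qd = p.density, np.maximum(q.density, KL_EPS)
    mask = pd_ > 0
    return float(np.sum(pd_[mask] * np.log(pd_[mask] / qd[mask])))


def match_table(iss_patterns, ref_patterns) -> pd.DataFrame:
    """Gene x gene KL matrix sorted so the best self-matches come first.

    Both inputs map gene name -> :class:`SpatialPattern` over a shared gene
    set.  Entry (i, j) is ``KL(ISS_i || ref_j)``.  Each gene's score is
    ``KL(self pair) - min KL(off pairs)``; rows and columns are sorted
    ascending by score, so genes whose decoded pattern matches their own
    reference pattern better than any other gene's appear in the top-left.
    """
    iss = dict(iss_patterns)
    ref = dict(ref_patterns)
    missing = sorted(set(iss) ^ set(ref))
    if missing:
        raise ValueError("genes not present in both sets: "
                         + ", ".join(missing))
    genes = sorted(iss)
    kl = np.array([[kl_divergence(iss[gi], ref[gj]) for gj in genes]
                   for gi in genes])
    diag = np.diag(kl)
    off = kl + np.diag(np.full(len(genes), np.inf))
    score = diag - off.min(axis=1)
    order = np.argsort(score, kind="stable")
    sorted_genes = [genes[i] for i in order]
    out = pd.DataFrame(kl[np.ix_(order, order)], index=sorted_genes,
                       columns=sorted_genes)
    out.attrs["score"] = pd.Series(score[order], index=sorted_genes)
    return out


def top_matches(table: pd.DataFrame, k: int = 10):
    """First/last k genes of a sorted match table (best and worst matches)."""
    genes = list(table.index)
    return genes[:k], genes[-k:]
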