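"""Nearest-centroid intrinsic molecular subtype assignment.

Each sample's gene-level expression vector is correlated (Spearman)
against every subtype centroid over the shared panel genes; the label is
the centroid with the highest correlation. The panel covers the five
intrinsic subtypes (Basal, LumA, LumB, HER2-E, Normal-like) plus
claudin-low handled as an additional centroid in the same pass — a
deliberate single-stage simplification of the published two-stage
claudin-low predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SUBTYPES", "CentroidSet", "load_centroids", "classify_subtype"]

log = logging.getLogger(__name__)

SUBTYPES = ("Basal", "LumA", "LumB", "HER2-E", "Normal-like", "Claudin-low")


class CentroidError(ValueError):
    pass


@dataclass
class CentroidSet:
    """Gene-by-subtype centroid matrix.

    Column order is the deterministic tie-break order for classification.
    """

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise CentroidError("need at least 2 subtype centroids")
        if self.centroids.index.has_duplicates:
            raise CentroidError("duplicate panel genes in centroid table")
        self.centroids = self.centroids.astype(float)

    @property
    def panel_genes(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


def load_centroids(path: str | Path) -> CentroidSet:
    """Read a centroid TSV: rows = genes, columns = subtypes."""
    return CentroidSet(pd.read_csv(path, sep="\t", index_col=0))


def classify_subtype(gene_matrix: pd.DataFrame, centroids: CentroidSet,
                     min_coverage: float = 0.5
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample the subtype of its best-correlated centroid.

    Parameters
    ----------
    gene_matrix
        Gene-by-sample expression (gene symbols on the index).
    centroids
        Centroid set; correlations are computed over the panel genes
        present in ``gene_matrix``, which must cover at least
        ``min_coverage`` of the panel.

    Returns
    -------
    labels, correlations
        Per-sample label Series and the full sample-by-subtype Spearman
        correlation matrix for audit. Ties are broken by centroid column
        order with a logged warning.
    """
    shared = [g for g in centroids.panel_genes if g in gene_matrix.index]
    coverage = len(shared) / len(centroids.panel_genes)
    if coverage < min_coverage:
        raise CentroidError(
            f"only {len(shared)}/{len(centroids.panel_genes)} panel genes present "
            f"({coverage:.0%} < {min_coverage:.0%})")

    x = gene_matrix.loc[shared].to_numpy()
    c = centroids.centroids.loc[shared].to_numpy()
    # Spearman = Pearson on ranks; rank once per sample / centroid
    xr = stats.rankdata(x, axis=0)
    cr = stats.rankdata(c, axis=0)
    xr = (xr - xr.mean(axis=0)) / xr.std(axis=0)
    cr = (cr - cr.mean(axis=0)) / cr.std(axis=0)
    corr = (xr.T @ cr) / len(shared)  # samples x subtypes

    names = centroids.subtypes
    best = corr.argmax(axis=1)
    ties = (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.warning("classify_subtype: %d tie(s) broken by centroid order", int(ties.sum()))
    labels = pd.Series([names[i] for i in best], index=gene_matrix.columns, name="subtype")
    corr_df = pd.DataFrame(corr, index=gene_matrix.columns, columns=names)
    return labels, corr_df
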