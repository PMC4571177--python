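"""Leading-edge metagene analysis.

Builds a binary genes x gene-sets occurrence matrix from the leading edges
of significantly enriched sets, clusters genes by the Pearson correlation
of their occurrence profiles (agglomerative, average linkage on
1 - correlation), and annotates each cluster by hypergeometric
over-representation against a user-supplied term->genes collection with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .gsea import GseaResult
from .io_formats import GeneSetCollection

__all__ = [
    "MetageneClusters",
    "occurrence_matrix",
    "cluster_metagenes",
    "overrepresentation",
]

log = logging.getLogger(__name__)


@dataclass
class MetageneClusters:
    """Disjoint gene clusters partitioning the occurrence-matrix rows.

    Clusters are ordered by size (largest first), ties by first gene;
    genes within a cluster are sorted lexicographically.
    """

    clusters: list[list[str]]
    linkage: str
    cut: float | int

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("empty cluster")

    def assignment(self) -> dict[str, int]:
        return {g: i for i, cluster in enumerate(self.clusters) for g in cluster}


def occurrence_matrix(results: list[GseaResult], q_max: float = 0.01) -> pd.DataFrame:
    """Binary genes x sets matrix over significantly enriched sets.

    Columns are the sets with fdr_q < q_max (strict); rows are the union of
    their leading-edge genes. Row and column order are lexicographic, so the
    matrix is independent of input order.
    """
    sig = [r for r in results if r.fdr_q < q_max]
    if not sig:
        raise ValueError("nothing to analyze: no set passes the FDR threshold")
    cols = sorted(r.set_name for r in sig)
    edges = {r.set_name: set(r.leading_edge) for r in sig}
    rows = sorted(set().union(*edges.values()))
    data = np.zeros((len(rows), len(cols)), dtype=int)
    row_idx = {g: i for i, g in enumerate(rows)}
    for j, name in enumerate(cols):
        for g in edges[name]:
            data[row_idx[g], j] = 1
    return pd.DataFrame(data, index=pd.Index(rows, name="gene"), columns=cols)


def _occurrence_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows; rows with zero variance
    (constant occurrence profiles) sit at distance 1 from every other row."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def cluster_metagenes(
    occurrence: pd.DataFrame,
    linkage: str = "average",
    k: int | None = 2,
    height: float | None = None,
) -> MetageneClusters:
    """Agglomerative clustering of genes by occurrence-profile correlation.

    Cut the dendrogram into ``k`` clusters (default 2) or at ``height``
    (takes precedence when given). A single-gene matrix yields one trivial
    cluster with a warning.
    """
    genes = list(occurrence.index)
    if len(genes) == 0:
        raise ValueError("empty occurrence matrix")
    if len(genes) == 1:
        warnings.warn("single gene: returning one trivial cluster")
        return MetageneClusters([list(genes)], linkage, k if height is None else height)
    condensed = _occurrence_distance(occurrence.to_numpy(dtype=float))
    tree = hierarchy.linkage(condensed, method=linkage)
    if height is not None:
        labels = hierarchy.fcluster(tree, t=height, criterion="distance")
        cut: float | int = height
    else:
        if k is None or not 1 <= k <= len(genes):
            raise ValueError(f"k must lie in 1..{len(genes)}")
        labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
        cut = k
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        groups.setdefault(int(lab), []).append(g)
    clusters = sorted(
        (sorted(c) for c in groups.values()), key=lambda c: (-len(c), c[0])
    )
    return MetageneClusters(clusters, linkage, cut)


def overrepresentation(
    cluster: list[str],
    annotation: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a cluster.

    For each term, p = P(X >= k) where X counts cluster genes falling in
    the term when ``n`` genes are drawn from a universe of ``N`` containing
    ``K`` term genes (term membership intersected with the universe first).
    Benjamini-Hochberg q across the tested terms. Terms with no gene in the
    universe are skipped with a log entry.

    Returns a DataFrame (term, k, K, n, N, p, q) sorted by ascending p,
    ties by term name.
    """
    universe_set = set(universe)
    if len(universe_set) != len(universe):
        raise ValueError("universe contains duplicates")
    cluster_set = set(cluster)
    if not cluster_set <= universe_set:
        raise ValueError("cluster must be a subset of the universe")
    n_univ = len(universe_set)
    n_clust = len(cluster_set)
    rows = []
    for term in annotation.names():
        members = set(annotation.genes(term)) & universe_set
        if not members:
            log.info("term %s has no gene in the universe; skipped", term)
            continue
        k = len(cluster_set & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_clust))
        rows.append((term, k, len(members), n_clust, n_univ, min(p, 1.0)))
    if not rows:
        raise ValueError("no annotation term overlaps the universe")
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p", "term"], ignore_index=True)
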