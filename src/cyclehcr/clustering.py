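"""Cell and gene clustering on spot-count matrices.

Cells: depth normalization -> log1p -> PCA -> kNN graph -> Leiden community
detection, with a UMAP embedding for visualization and kNN imputation.
Genes: hierarchical ordering of per-cluster min-max-scaled mean expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .assignment import CountMatrix


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Per-cell labels (1..K, 0 = unallocated), embedding, and summaries."""

    labels: np.ndarray
    embedding: np.ndarray | None
    sizes: dict[int, int]
    params: dict = field(default_factory=dict)
    silhouette: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def normalize_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Depth-scale each cell to the median total, then log(1 + x).

    Input is genes x cells; output is cells x genes (analysis orientation)
    plus a boolean flag of zero-depth cells (left as zero vectors).
    """
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=0)
    zero = depth == 0
    target = np.median(depth[~zero]) if (~zero).any() else 1.0
    scale = np.divide(target, depth, out=np.zeros_like(depth), where=~zero)
    return np.log1p(counts * scale).T, zero


def cluster_cells(normalized: np.ndarray, k_neighbors: int = 15,
                  resolution: float = 1.0, seed: int = 0,
                  n_pcs: int = 30, min_size: int = 20,
                  embed: bool = True) -> ClusterResult:
    """Leiden clustering of cells on a kNN graph in PCA space.

    ``normalized`` is cells x genes (from :func:`normalize_counts`). Labels
    are renumbered 1..K by decreasing size; members of clusters smaller than
    ``min_size``, and cells with negative silhouette in PCA space, are marked
    unallocated (label 0) while cluster identity and count are decided before
    unallocation.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(normalized, dtype=float)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ClusteringError(f"need >= {k_neighbors + 1} cells, got {n}")
    if np.allclose(X, X[0]):
        warnings.warn("all cells identical; returning a single cluster")
        return ClusterResult(labels=np.ones(n, dtype=int), embedding=None,
                             sizes={1: n}, params={"degenerate": True})

    n_comp = min(n_pcs, X.shape[1], n - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    raw = np.asarray(part.membership)

    # renumber by decreasing size, 1-based
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw])

    keep = {lab for lab, size in zip(*np.unique(labels, return_counts=True))
            if size >= min_size}
    labels = np.where(np.isin(labels, list(keep)), labels, 0)
    # re-compact to 1..K
    final_ids = sorted(set(labels) - {0})
    compact = {old: i + 1 for i, old in enumerate(final_ids)}
    labels = np.array([compact.get(l, 0) for l in labels])

    sil = None
    if len(set(labels) - {0}) > 1:
        from sklearn.metrics import silhouette_samples

        alloc = labels > 0
        sil = np.full(n, np.nan)
        sil[alloc] = silhouette_samples(pcs[alloc], labels[alloc])
        labels = np.where(np.nan_to_num(sil, nan=1.0) < 0, 0, labels)

    embedding = None
    if embed:
        import umap

        embedding = umap.UMAP(n_neighbors=k_neighbors, n_components=2,
                              random_state=seed).fit_transform(pcs)

    sizes = {int(l): int(s) for l, s in zip(*np.unique(labels[labels > 0],
                                                       return_counts=True))}
    return ClusterResult(labels=labels, embedding=embedding, sizes=sizes,
                         silhouette=sil,
                         params={"k_neighbors": k_neighbors, "resolution": resolution,
                                 "seed": seed, "n_pcs": n_comp, "min_size": min_size})


def cluster_genes(matrix: np.ndarray, genes, cell_labels: np.ndarray
                  ) -> tuple[list, pd.DataFrame]:
    """Order genes by hierarchical clustering of min-max-scaled cluster means.

    ``matrix`` is genes x cells. Returns (ordered gene list, scaled means
    genes x clusters in [0, 1]); constant genes are scaled to 0 and flagged
    in the frame's ``attrs['constant_genes']``.
    """
    matrix = np.asarray(matrix, dtype=float)
    genes = list(genes)
    cell_labels = np.asarray(cell_labels)
    clusters = sorted(set(cell_labels) - {0})
    if not clusters:
        raise ClusteringError("no allocated clusters")
    means = np.stack([matrix[:, cell_labels == c].mean(axis=1) for c in clusters], axis=1)
    lo = means.min(axis=1, keepdims=True)
    span = means.max(axis=1, keepdims=True) - lo
    constant = span[:, 0] == 0
    scaled = np.zeros_like(means)
    nz = ~constant
    scaled[nz] = (means[nz] - lo[nz]) / span[nz]
    frame = pd.DataFrame(scaled, index=pd.Index(genes, name="gene"), columns=clusters)
    frame.attrs["constant_genes"] = [g for g, c in zip(genes, constant) if c]

    if len(genes) > 2:
        with np.errstate(invalid="ignore"):
            dist = pdist(np.where(constant[:, None], 0.0, scaled), metric="correlation")
        dist = np.nan_to_num(dist, nan=1.0)
        order = leaves_list(linkage(dist, method="average"))
    else:
        order = np.arange(len(genes))
    ordered = [genes[i] for i in order]
    return ordered, frame


def impute_on_embedding(values: np.ndarray, embedding: np.ndarray,
                        k: int = 15) -> np.ndarray:
    """Smooth per-cell values by averaging the k nearest embedding neighbors.

    The neighborhood includes the cell itself, so k=1 is the identity.
    ``values`` may be a vector (one gene) or cells x genes.
    """
    from sklearn.neighbors import NearestNeighbors

    values = np.asarray(values, dtype=float)
    embedding = np.asarray(embedding)
    if k < 1:
        raise ClusteringError("k must be >= 1")
    k = min(k, embedding.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    if values.ndim == 1:
        return values[idx].mean(axis=1)
    return values[idx].mean(axis=1)


def score_markers(scaled_means: pd.DataFrame,
                  panel: dict[str, list[str]]) -> pd.DataFrame:
    """Annotate each cluster with the hypothesis whose markers score highest.

    ``scaled_means`` is genes x clusters in [0, 1]; the score of a hypothesis
    in a cluster is the mean scaled expression of its marker genes. Reports
    the winning hypothesis and its margin over the runner-up.
    """
    if not panel:
        raise ClusteringError("empty marker panel")
    scores = {}
    for hyp, markers in panel.items():
        present = [g for g in markers if g in scaled_means.index]
        if not present:
            raise ClusteringError(f"no markers of {hyp!r} present in matrix")
        scores[hyp] = scaled_means.loc[present].mean(axis=0)
    score_df = pd.DataFrame(scores)  # clusters x hypotheses
    best = score_df.idxmax(axis=1)
    top = score_df.max(axis=1)
    margin = top - score_df.apply(
        lambda r: r.drop(best[r.name]).max() if len(r) > 1 else 0.0, axis=1)
    return pd.DataFrame({"hypothesis": best, "score": top, "margin": margin})
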