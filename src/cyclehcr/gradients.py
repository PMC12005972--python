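"""Spatial expression gradients, slope ranking, co-expression, and midline
segment classification.

All gradient slopes are reported on normalized units: per-cell (or
per-segment) expression is min-max scaled over the fitting window and the
coordinate is scaled to [0, 1], so a monotone bounded profile has a slope in
[-1, 1] and a fixed |k| threshold is comparable across genes. This scaling
changes threshold semantics relative to raw-count slopes — see the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


class GradientError(ValueError):
    pass


@dataclass
class GradientFit:
    gene: str
    cluster: object
    axis: str
    slope_k: float
    intercept: float
    r2: float
    n_cells: int
    degenerate: bool = False


@dataclass
class CoexpressionMatrix:
    cluster: object
    genes: list
    rho: np.ndarray            # symmetric, diag 1, entries in [-1, 1]
    undefined: np.ndarray      # mask of pairs involving a constant gene
    order: list                # display order from hierarchical clustering


def _minmax(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x), True
    return (x - x.min()) / span, False


def _scaled_ols(y_scaled: np.ndarray, x_scaled: np.ndarray) -> tuple[float, float, float]:
    slope, intercept, r, _, _ = stats.linregress(x_scaled, y_scaled)
    return float(slope), float(intercept), float(r ** 2)


def fit_gradient(counts: np.ndarray, genes, axes: pd.DataFrame,
                 cluster_labels: np.ndarray, cluster, axis: str, gene: str,
                 min_cells: int = 20) -> GradientFit:
    """OLS of min-max-scaled expression against the [0, 1]-scaled axis
    coordinate, over one cluster's cells."""
    if axis not in ("dp", "ap", "radial"):
        raise GradientError(f"axis must be dp/ap/radial, got {axis!r}")
    genes = pd.Index(list(genes))
    cluster_labels = np.asarray(cluster_labels)
    cells = cluster_labels == cluster
    n = int(cells.sum())
    if n < min_cells:
        raise GradientError(f"cluster {cluster!r} has {n} cells < min_cells={min_cells}")
    y = np.asarray(counts, dtype=float)[genes.get_loc(gene), cells]
    x = axes.loc[np.asarray(cells), f"{axis}_{'deg' if axis == 'ap' else 'um'}"].to_numpy()
    y_s, y_const = _minmax(y)
    x_s, x_const = _minmax(x)
    if y_const or x_const:
        return GradientFit(gene, cluster, axis, 0.0, float(y_s.mean()), 0.0, n,
                           degenerate=True)
    slope, intercept, r2 = _scaled_ols(y_s, x_s)
    return GradientFit(gene, cluster, axis, slope, intercept, r2, n)


def fit_gradients(counts, genes, axes, cluster_labels, clusters=None,
                  axes_names=("dp", "ap", "radial"), min_cells: int = 20
                  ) -> pd.DataFrame:
    """All (gene, cluster, axis) fits with enough cells, as one table."""
    cluster_labels = np.asarray(cluster_labels)
    if clusters is None:
        clusters = sorted(set(cluster_labels) - {0})
    rows = []
    for cl in clusters:
        if (cluster_labels == cl).sum() < min_cells:
            continue
        for ax in axes_names:
            for g in genes:
                fit = fit_gradient(counts, genes, axes, cluster_labels, cl, ax, g,
                                   min_cells=min_cells)
                rows.append(vars(fit))
    return pd.DataFrame(rows)


def rank_genes_by_slope(fits: pd.DataFrame) -> pd.DataFrame:
    """Stable sort from positive-ascending to negative-descending slopes,
    ties broken by gene name."""
    return fits.sort_values(["slope_k", "gene"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)


def coexpression_matrix(counts: np.ndarray, genes, cluster_labels: np.ndarray,
                        cluster) -> CoexpressionMatrix:
    """Pairwise Spearman rho over one cluster's cells (average-rank ties).

    Constant genes yield undefined correlations, stored as 0 with the
    ``undefined`` mask set. The matrix is exactly symmetric with unit
    diagonal; ``order`` is the average-linkage ordering of 1 - rho.
    """
    genes = list(genes)
    cluster_labels = np.asarray(cluster_labels)
    cells = cluster_labels == cluster
    if cells.sum() < 3:
        raise GradientError("need >= 3 cells for co-expression")
    X = np.asarray(counts, dtype=float)[:, cells]
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    constant = X.std(axis=1) == 0
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    undefined = constant[:, None] | constant[None, :]
    rho = np.where(undefined, 0.0, rho)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)

    if len(genes) > 2:
        d = 1.0 - rho
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        order_idx = leaves_list(linkage(squareform(d, checks=False), method="average"))
    else:
        order_idx = np.arange(len(genes))
    return CoexpressionMatrix(cluster=cluster, genes=genes, rho=rho,
                              undefined=undefined,
                              order=[genes[i] for i in order_idx])


def classify_segments(counts: np.ndarray, genes, arc_positions: np.ndarray,
                      cluster_labels: np.ndarray | None = None,
                      clusters_in_band=None, n_segments: int = 9,
                      n_fit: int = 8, k_threshold: float = 0.15) -> pd.DataFrame:
    """Bin cells into equal-arc-length segments and classify per-gene slopes.

    Cells (optionally restricted to ``clusters_in_band``) are split into
    ``n_segments`` equal-arc-length bins; the per-segment mean transcript
    count per cell is computed per gene; the first ``n_fit`` segment means
    are min-max scaled and regressed against the segment index scaled to
    [0, 1]. Classes: descending (k <= -threshold), ascending
    (k >= +threshold), else flat. Empty segments are skipped; fits on fewer
    than 4 segments are flagged ``low_support``.
    """
    if n_fit > n_segments:
        raise GradientError("n_fit must be <= n_segments")
    counts = np.asarray(counts, dtype=float)
    arc = np.asarray(arc_positions, dtype=float)
    keep = np.ones(len(arc), dtype=bool)
    if clusters_in_band is not None:
        if cluster_labels is None:
            raise GradientError("clusters_in_band requires cluster_labels")
        keep = np.isin(np.asarray(cluster_labels), list(clusters_in_band))
    counts = counts[:, keep]
    arc = arc[keep]

    edges = np.linspace(arc.min(), arc.max(), n_segments + 1)
    seg = np.clip(np.digitize(arc, edges[1:-1]), 0, n_segments - 1)
    seg_means = np.full((counts.shape[0], n_segments), np.nan)
    for s in range(n_segments):
        in_seg = seg == s
        if in_seg.any():
            seg_means[:, s] = counts[:, in_seg].mean(axis=1)

    x_full = np.linspace(0.0, 1.0, n_fit)
    rows = []
    for gi, gene in enumerate(genes):
        y = seg_means[gi, :n_fit]
        ok = ~np.isnan(y)
        low_support = ok.sum() < 4
        y_ok, x_ok = y[ok], x_full[ok]
        if ok.sum() < 2:
            slope, degenerate = 0.0, True
        else:
            y_s, degenerate = _minmax(y_ok)
            slope = 0.0 if degenerate else _scaled_ols(y_s, x_ok)[0]
        if slope <= -k_threshold:
            cls = "descending"
        elif slope >= k_threshold:
            cls = "ascending"
        else:
            cls = "flat"
        row = {"gene": gene, "slope_k": slope, "class": cls,
               "low_support": low_support, "degenerate": degenerate}
        row.update({f"segment_{s + 1}": seg_means[gi, s] for s in range(n_segments)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
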