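"""Embryo-intrinsic coordinate axes and left-right symmetry.

Cartesian centroids are re-expressed on three axes: distal-proximal (dp,
distance along the midline, distal end at 0), anterior-posterior (ap, the
signed angle in degrees between a cell's perpendicular offset from the
midline and the posterior reference direction, posterior = 0), and radial
(perpendicular distance to the midline).  Cells are called left or right
from the sign of ap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class AxesError(ValueError):
    pass


@dataclass(frozen=True)
class Midline:
    """Oriented line: a point on it and a unit direction (proximal positive)."""

    point: np.ndarray
    direction: np.ndarray


def fit_midline(centroids: np.ndarray, cluster_labels=None,
                anchor_clusters=None, proximal_anchor=None) -> Midline:
    """First principal axis of (anchor-cluster) centroids.

    ``anchor_clusters`` restricts the fit to interior/embryonic clusters;
    ``proximal_anchor`` names a cluster whose centroid fixes the positive
    (proximal) end of the axis, e.g. the extraembryonic cap.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 3:
        raise AxesError("centroids must be (n, 3)")
    if cluster_labels is not None:
        cluster_labels = np.asarray(cluster_labels)
    pts = centroids
    if anchor_clusters is not None:
        if cluster_labels is None:
            raise AxesError("anchor_clusters requires cluster_labels")
        pts = centroids[np.isin(cluster_labels, list(anchor_clusters))]
    if len(pts) < 3:
        raise AxesError("need >= 3 cells to fit a midline")
    mean = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - mean, full_matrices=False)
    if s[0] <= s[1] * (1 + 1e-9):
        raise AxesError("isotropic centroid cloud: midline orientation ambiguous")
    direction = vt[0]
    if proximal_anchor is not None:
        if cluster_labels is None:
            raise AxesError("proximal_anchor requires cluster_labels")
        anchor = centroids[cluster_labels == proximal_anchor].mean(axis=0)
        if np.dot(anchor - mean, direction) < 0:
            direction = -direction
    return Midline(point=mean, direction=direction / np.linalg.norm(direction))


def transform_coordinates(centroids: np.ndarray, midline: Midline,
                          posterior_reference: np.ndarray) -> pd.DataFrame:
    """Project centroids onto (dp, ap, radial) coordinates.

    ``posterior_reference`` is a direction (not necessarily unit or
    orthogonal to the midline); its component perpendicular to the midline
    defines ap = 0. The ap sign follows the right-hand rule about the
    midline direction, so mirroring cells across the midline-posterior plane
    negates ap and leaves dp and radial unchanged. Cells exactly on the
    midline get ap = 0 and are flagged.
    """
    centroids = np.asarray(centroids, dtype=float)
    u = midline.direction / np.linalg.norm(midline.direction)
    ref = np.asarray(posterior_reference, dtype=float)
    ref_perp = ref - np.dot(ref, u) * u
    nref = np.linalg.norm(ref_perp)
    if nref < 1e-12:
        raise AxesError("posterior_reference is parallel to the midline")
    r_hat = ref_perp / nref

    rel = centroids - midline.point
    proj = rel @ u
    dp = proj - proj.min()
    v = rel - proj[:, None] * u[None, :]
    radial = np.linalg.norm(v, axis=1)
    on_midline = radial < 1e-12

    cosang = v @ r_hat
    sinang = v @ np.cross(u, r_hat)
    ap = np.degrees(np.arctan2(sinang, cosang))
    ap = np.where(ap <= -180.0, 180.0, ap)  # convention: ap in (-180, 180]
    ap = np.where(on_midline, 0.0, ap)

    return pd.DataFrame({
        "dp_um": dp,
        "ap_deg": ap,
        "radial_um": radial,
        "side": np.where(ap > 0, "right", "left"),
        "on_midline": on_midline,
    })


def left_right_correlation(counts: np.ndarray, genes, axes: pd.DataFrame
                           ) -> tuple[pd.DataFrame, float]:
    """Per-gene mean expression on each side plus one global Pearson r.

    ``counts`` is genes x cells aligned with ``axes`` rows. With a single
    gene (or zero variance) r is undefined and returned as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    side = axes["side"].to_numpy()
    left = side == "left"
    right = side == "right"
    if not left.any() or not right.any():
        raise AxesError("both sides must contain cells")
    table = pd.DataFrame({
        "mean_left": counts[:, left].mean(axis=1),
        "mean_right": counts[:, right].mean(axis=1),
    }, index=pd.Index(list(genes), name="gene"))
    if len(table) < 2 or table["mean_left"].std() == 0 or table["mean_right"].std() == 0:
        return table, float("nan")
    r = float(np.corrcoef(table["mean_left"], table["mean_right"])[0, 1])
    return table, r
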