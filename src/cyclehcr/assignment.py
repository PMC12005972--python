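"""3D spot-to-cell assignment via dilated nucleus label masks.

The conservative assignment strategy: each decoded single-molecule spot is
attributed to the segmented nucleus whose (slightly dilated) mask contains
the spot's voxel, or left unassigned if it falls in background.  Dilation is
Euclidean in physical units and anisotropy-aware; contested background
voxels go to the label with the nearest pre-dilation labeled voxel, ties
broken deterministically by smaller label id.

Coordinate convention (used package-wide): volumes are indexed (z, y, x),
0-based; spot coordinates are physical micrometres; the voxel of a spot is
``floor(coordinate / voxel_size)`` per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class AssignmentError(ValueError):
    pass


@dataclass
class LabelVolume:
    """3D integer-labeled nucleus masks with physical voxel size.

    ``labels`` is (z, y, x) with 0 = background; labels need not be
    consecutive (e.g. after filtering). ``voxel_size_um`` is (z, y, x) in µm.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise AssignmentError("label volume must be 3D (z, y, x)")
        if np.issubdtype(self.labels.dtype, np.signedinteger) and self.labels.min() < 0:
            raise AssignmentError("labels must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise AssignmentError("voxel_size_um must be 3 positive values (z, y, x)")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    # -- I/O ------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write multi-page TIFF plus a JSON sidecar holding the voxel size."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.labels.astype(np.uint32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"voxel_size_um": list(self.voxel_size_um),
                                       "axes": "zyx"}))

    @classmethod
    def read(cls, path: str | Path) -> "LabelVolume":
        import tifffile

        path = Path(path)
        labels = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(labels=labels, voxel_size_um=tuple(meta["voxel_size_um"]))


@dataclass
class CountMatrix:
    """Genes x cells transcript counts plus per-cell and per-gene metadata.

    Cells removed by QC keep their column with ``excluded=True`` so spot
    conservation (matrix sum == assigned spots) always holds.
    """

    counts: np.ndarray                       # (n_genes, n_cells) ints
    genes: pd.Index
    cells: np.ndarray                        # label ids, aligned to columns
    cell_meta: pd.DataFrame                  # index = cells
    gene_meta: pd.DataFrame = field(default=None)  # index = genes

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = pd.Index(self.genes)
        self.cells = np.asarray(self.cells)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise AssignmentError("counts shape must be (n_genes, n_cells)")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.genes)
        if "is_control" not in self.gene_meta:
            self.gene_meta["is_control"] = False
        if "excluded" not in self.cell_meta:
            self.cell_meta["excluded"] = False

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_counts(self, gene: str) -> np.ndarray:
        return self.counts[self.genes.get_loc(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)

    def write(self, outdir: str | Path) -> None:
        """Write MTX counts plus TSV gene/cell metadata."""
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(outdir / "counts.mtx", csr_matrix(self.counts))
        pd.Series(self.genes, name="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
        pd.Series(self.cells, name="cell").to_csv(outdir / "cells.tsv", sep="\t", index=False)
        self.gene_meta.to_csv(outdir / "gene_meta.tsv", sep="\t")
        self.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")

    @classmethod
    def read(cls, outdir: str | Path) -> "CountMatrix":
        from scipy import io as sio

        outdir = Path(outdir)
        counts = np.asarray(sio.mmread(outdir / "counts.mtx").todense())
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t")["gene"]
        cells = pd.read_csv(outdir / "cells.tsv", sep="\t")["cell"].to_numpy()
        gene_meta = pd.read_csv(outdir / "gene_meta.tsv", sep="\t", index_col=0)
        cell_meta = pd.read_csv(outdir / "cell_meta.tsv", sep="\t", index_col=0)
        return cls(counts=counts, genes=pd.Index(genes), cells=cells,
                   cell_meta=cell_meta, gene_meta=gene_meta)


# ---------------------------------------------------------------------------
# dilation
# ---------------------------------------------------------------------------

def _offset_groups(radius_um: float, sampling: Sequence[float]):
    """Nonzero integer voxel offsets within the radius, grouped by distance.

    Offsets whose scaled Euclidean norm is equal form one tie group; groups
    are returned in increasing distance order.
    """
    reach = [int(np.floor(radius_um / s + 1e-9)) for s in sampling]
    groups: dict[float, list[tuple[int, int, int]]] = {}
    for dz in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dx in range(-reach[2], reach[2] + 1):
                if dz == dy == dx == 0:
                    continue
                d2 = (dz * sampling[0]) ** 2 + (dy * sampling[1]) ** 2 + (dx * sampling[2]) ** 2
                if d2 <= radius_um ** 2 + 1e-9:
                    groups.setdefault(round(d2, 9), []).append((dz, dy, dx))
    return [groups[k] for k in sorted(groups)]


def _shifted(arr: np.ndarray, offset, fill):
    """``out[v] = arr[v + offset]`` with out-of-bounds reads giving ``fill``."""
    out = np.full_like(arr, fill)
    src_sl, dst_sl = [], []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            src_sl.append(slice(o, n))
            dst_sl.append(slice(0, n - o))
        else:
            src_sl.append(slice(0, n + o))
            dst_sl.append(slice(-o, n))
    out[tuple(dst_sl)] = arr[tuple(src_sl)]
    return out


def dilate_labels(volume: LabelVolume, radius_um: float) -> LabelVolume:
    """Grow every label into background by up to ``radius_um`` (Euclidean, µm).

    Labeled voxels never change identity; a background voxel within radius
    of at least one labeled voxel takes the label of the nearest labeled
    voxel (anisotropy-aware, measured on the voxel index lattice), ties
    broken by the smaller label id.  Implemented as a sweep over integer
    voxel offsets in increasing-distance tie groups, which reproduces the
    per-voxel brute-force nearest-labeled-voxel search exactly.
    """
    if radius_um < 0:
        raise AssignmentError(f"radius_um must be >= 0, got {radius_um}")
    labels = volume.labels
    if radius_um == 0 or not labels.any():
        return LabelVolume(labels.copy(), volume.voxel_size_um)

    sentinel = np.iinfo(np.int64).max
    work = labels.astype(np.int64)
    work[work == 0] = sentinel
    out = work.copy()
    unclaimed = out == sentinel
    for group in _offset_groups(radius_um, volume.voxel_size_um):
        cand = _shifted(work, group[0], sentinel)
        for off in group[1:]:
            np.minimum(cand, _shifted(work, off, sentinel), out=cand)
        np.copyto(out, cand, where=unclaimed & (cand < sentinel))
        unclaimed &= out == sentinel
    out[out == sentinel] = 0
    return LabelVolume(out.astype(labels.dtype), volume.voxel_size_um)


# ---------------------------------------------------------------------------
# assignment + counting
# ---------------------------------------------------------------------------

def spot_voxels(spots: pd.DataFrame, volume: LabelVolume) -> np.ndarray:
    """(n, 3) integer voxel indices (z, y, x) via the floor convention."""
    vz, vy, vx = volume.voxel_size_um
    coords = np.stack([
        np.floor(spots["z_um"].to_numpy() / vz),
        np.floor(spots["y_um"].to_numpy() / vy),
        np.floor(spots["x_um"].to_numpy() / vx),
    ], axis=1)
    if not np.isfinite(coords).all():
        raise AssignmentError("spot coordinates must be finite")
    return coords.astype(np.int64)


def assign_spots(spots: pd.DataFrame, volume: LabelVolume) -> np.ndarray:
    """Per-spot cell id (0 = unassigned, including out-of-bounds spots)."""
    vox = spot_voxels(spots, volume)
    shape = np.asarray(volume.labels.shape)
    in_bounds = np.all((vox >= 0) & (vox < shape), axis=1)
    cell_ids = np.zeros(len(spots), dtype=np.int64)
    vb = vox[in_bounds]
    cell_ids[in_bounds] = volume.labels[vb[:, 0], vb[:, 1], vb[:, 2]].astype(np.int64)
    return cell_ids


def cell_geometry(volume: LabelVolume) -> pd.DataFrame:
    """Centroid (µm) and volume (µm³) per label from the undilated masks."""
    labels = volume.labels
    ids = volume.label_ids
    if ids.size == 0:
        return pd.DataFrame(columns=["centroid_z_um", "centroid_y_um", "centroid_x_um", "volume_um3"])
    flat = labels.ravel()
    nvox = np.bincount(flat, minlength=int(ids.max()) + 1)[ids]
    zz, yy, xx = np.indices(labels.shape, sparse=True)
    cz = np.bincount(flat, weights=np.broadcast_to(zz, labels.shape).ravel(),
                     minlength=int(ids.max()) + 1)[ids] / nvox
    cy = np.bincount(flat, weights=np.broadcast_to(yy, labels.shape).ravel(),
                     minlength=int(ids.max()) + 1)[ids] / nvox
    cx = np.bincount(flat, weights=np.broadcast_to(xx, labels.shape).ravel(),
                     minlength=int(ids.max()) + 1)[ids] / nvox
    vz, vy, vx = volume.voxel_size_um
    return pd.DataFrame({
        "centroid_z_um": (cz + 0.5) * vz,
        "centroid_y_um": (cy + 0.5) * vy,
        "centroid_x_um": (cx + 0.5) * vx,
        "volume_um3": nvox * volume.voxel_volume_um3,
    }, index=pd.Index(ids, name="cell"))


def build_count_matrix(assignment: np.ndarray, spots: pd.DataFrame,
                       volume: LabelVolume, codebook=None) -> CountMatrix:
    """Tally assigned spots into a genes x cells matrix.

    ``codebook`` (optional) fixes the gene universe and control flags;
    otherwise genes are the sorted unique names in the spot table. Cell
    centroids and volumes come from the *undilated* ``volume``.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(spots):
        raise AssignmentError("assignment length must match spot table")
    if codebook is not None:
        genes = pd.Index(list(codebook.entries), name="gene")
        is_control = np.array([g in codebook.non_targeting for g in genes])
    else:
        genes = pd.Index(sorted(spots["gene"].unique()), name="gene")
        is_control = np.zeros(len(genes), dtype=bool)

    cell_meta = cell_geometry(volume)
    cells = cell_meta.index.to_numpy()
    cell_pos = {c: i for i, c in enumerate(cells)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    counts = np.zeros((len(genes), len(cells)), dtype=np.int64)
    assigned = assignment > 0
    for g, c in zip(spots["gene"].to_numpy()[assigned], assignment[assigned]):
        counts[gene_pos[g], cell_pos[c]] += 1

    gene_meta = pd.DataFrame({"is_control": is_control}, index=genes)
    return CountMatrix(counts=counts, genes=genes, cells=cells,
                       cell_meta=cell_meta, gene_meta=gene_meta)


def intensity_count_correlation(cm: CountMatrix, spots: pd.DataFrame,
                                assignment: np.ndarray) -> pd.DataFrame:
    """Per-gene Pearson r between per-cell spot count and summed intensity.

    Cells with no spots of the gene contribute (0, 0). Genes with fewer than
    3 expressing cells, or constant vectors, are flagged undefined (r = NaN)
    rather than raising.
    """
    assignment = np.asarray(assignment)
    cell_pos = {c: i for i, c in enumerate(cm.cells)}
    rows = []
    for gi, gene in enumerate(cm.genes):
        counts = cm.counts[gi].astype(float)
        intensity = np.zeros(cm.n_cells)
        sel = (spots["gene"].to_numpy() == gene) & (assignment > 0)
        for c, inten in zip(assignment[sel], spots["intensity"].to_numpy()[sel]):
            intensity[cell_pos[c]] += inten
        n_expressing = int((counts > 0).sum())
        if n_expressing < 3 or counts.std() == 0 or intensity.std() == 0:
            rows.append({"gene": gene, "r": np.nan, "n_expressing": n_expressing, "undefined": True})
            continue
        r = float(np.corrcoef(counts, intensity)[0, 1])
        rows.append({"gene": gene, "r": r, "n_expressing": n_expressing, "undefined": False})
    return pd.DataFrame(rows).set_index("gene")
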