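"""Synthetic spatial-transcriptomics data with known ground truth.

Two generators emulate the structure the downstream analysis assumes:

* ``generate_embryo`` — an egg-cylinder arrangement of ~1,500 nuclei in nine
  spatially segregated expression clusters (interior columns mirrored across
  a midplane, a demarcation band, an extraembryonic cap, enclosing endoderm
  shells and an outer ring), with axial expression gradients, shared latent
  co-expression factors, and left-right symmetry.
* ``generate_hippocampus`` — a curved band of nuclei layered into three
  clusters, with designated genes carrying monotone gradients along the
  band's midline arc length, plus per-nucleus protein intensities against a
  fixed inactive-chromatin reference antigen.

Per-cell transcript counts are negative binomial with mean
``base_rate * exp(gradient_effect * axis_coordinate) * exp(loadings . latent
factors)``; spots are placed uniformly inside each nucleus's slightly
dilated ellipsoid; background spots (the only source of non-targeting
counts) are homogeneous Poisson over the tissue bounding volume.  Everything
is reproducible from the config seed.

The default geometry is schematic, not biological: shell radii and cell
densities are chosen so the nine regions are distinct and nuclei are
placeable without collision, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import LabelVolume
from .codebook import Codebook, build_codebook

#: HCR amplification fold per fluorescence channel (488 / 561 / 640 nm).
DEFAULT_AMPLIFICATION = {488: 103.7, 561: 88.3, 640: 121.3}


class PlacementError(RuntimeError):
    """Nuclei could not be placed without collision after bounded retries."""


@dataclass
class ClusterSpec:
    """One expression cluster: where its cells live and what they express.

    ``region`` is a list of sampling boxes; their interpretation depends on
    the geometry kind (cylindrical (z, r) fraction windows for the embryo,
    band-normal offset windows for the hippocampus). ``gradients`` maps gene
    -> log-linear slope along the dataset's axis coordinate (normalized to
    [0, 1]).
    """

    name: str
    n_cells: int
    region: list[dict]
    base_rates: dict[str, float]
    gradients: dict[str, float] = field(default_factory=dict)


@dataclass
class CoexpressionFactor:
    """A shared latent factor: each cell draws z ~ N(0, 1) and every loaded
    gene's rate is multiplied by exp(loading * z)."""

    loadings: dict[str, float]
    clusters: list[str] | None = None  # None = all clusters


@dataclass
class FateMapConfig:
    """Full recipe for one synthetic dataset."""

    kind: str                       # "egg_cylinder" or "band"
    geometry: dict
    clusters: list[ClusterSpec]
    genes: list[str]
    n_controls: int = 6
    background_rate_per_cell: float = 0.05
    nb_size: float = 5.0            # NB dispersion (inf -> Poisson); var = mu + mu^2/size
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nucleus_radius_um: float = 3.0   # ~6 um nuclear diameter, typical embryonic
    radius_jitter: float = 0.10
    min_gap_um: float = 1.2
    spot_dilation_um: float = 0.2
    intensity_sigma: float = 0.4
    amplification: dict = field(default_factory=lambda: dict(DEFAULT_AMPLIFICATION))
    coexpression: list[CoexpressionFactor] = field(default_factory=list)
    gene_designations: dict[str, str] = field(default_factory=dict)
    # protein channels (hippocampus): antigen -> {cluster -> fold vs reference}
    antigen_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_antigen: str = "H3K27me3"
    reference_intensity: float = 1000.0
    protein_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if any(c.n_cells < 1 for c in self.clusters):
            raise ValueError("every cluster needs n_cells >= 1")
        if self.background_rate_per_cell < 0:
            raise ValueError("background_rate_per_cell must be >= 0")
        for c in self.clusters:
            if any(v < 0 for v in c.base_rates.values()):
                raise ValueError(f"negative base rate in cluster {c.name}")

    @property
    def n_cells(self) -> int:
        return sum(c.n_cells for c in self.clusters)


@dataclass
class GroundTruth:
    """Per-cell and per-spot generative truth for benchmarking recovery."""

    cells: pd.DataFrame          # index cell id: cluster, centroid, side, axis_t
    true_counts: pd.DataFrame    # genes x cells, realized nuclear counts
    expected_rates: pd.DataFrame  # genes x cells, NB means
    spots: pd.DataFrame          # per spot: gene, cell (0 = background)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _sample_region_embryo(rng, box: dict, geom: dict) -> np.ndarray:
    """Uniform point in a cylindrical-shell window; returns (z, y, x) in µm."""
    R, H, m = geom["radius_um"], geom["height_um"], geom["margin_um"]
    z0, z1 = box["z"]
    r0, r1 = box["r"]
    z = m + rng.uniform(z0, z1) * H
    r = R * np.sqrt(rng.uniform(r0 ** 2, r1 ** 2))
    theta = rng.uniform(0, 2 * np.pi)
    cy = geom["center_yx_um"][0]
    cx = geom["center_yx_um"][1]
    return np.array([z, cy + r * np.sin(theta), cx + r * np.cos(theta)])


def _band_curve(geom: dict):
    """Quadratic planar midline y(x), its arc length, and the band normal."""
    x_mid = 0.5 * (geom["x_min_um"] + geom["x_max_um"])

    def y_of(x):
        return geom["y_apex_um"] + geom["curvature"] * (np.asarray(x) - x_mid) ** 2

    def dy_of(x):
        return 2.0 * geom["curvature"] * (np.asarray(x) - x_mid)

    xs = np.linspace(geom["x_min_um"], geom["x_max_um"], 2001)
    seg = np.hypot(np.diff(xs), np.diff(y_of(xs)))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return y_of, dy_of, xs, arc


def _sample_region_band(rng, box: dict, geom: dict) -> tuple[np.ndarray, float]:
    """Uniform point in a band layer; returns ((z, y, x), normalized arc s)."""
    y_of, dy_of, xs, arc = geom["_curve"]
    x = rng.uniform(geom["x_min_um"], geom["x_max_um"])
    d = rng.uniform(*box["offset"])
    z = geom["z_margin_um"] + rng.uniform(0, 1) * geom["thickness_um"]
    dy = float(dy_of(x))
    norm = np.hypot(dy, 1.0)
    # in-plane unit normal to the tangent (1, dy)
    ny, nx = 1.0 / norm, -dy / norm
    pos = np.array([z, float(y_of(x)) + ny * d, x + nx * d])
    s = float(np.interp(x, xs, arc) / arc[-1])
    return pos, s


def _place_cells(rng, config: FateMapConfig, geom: dict):
    """Random sequential placement with a hard minimum center distance."""
    rmax = config.nucleus_radius_um * (1 + config.radius_jitter)
    dmin = 2 * rmax + config.min_gap_um
    cell_size = dmin
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def ok(p: np.ndarray) -> bool:
        key = tuple((p // cell_size).astype(int))
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        if np.sum((p - q) ** 2) < dmin ** 2:
                            return False
        return True

    centers, cluster_of, axis_t = [], [], []
    for spec in config.clusters:
        weights = np.array([_box_weight(b, config.kind) for b in spec.region], dtype=float)
        weights /= weights.sum()
        placed, attempts = 0, 0
        budget = 400 * spec.n_cells
        while placed < spec.n_cells:
            if attempts > budget:
                raise PlacementError(
                    f"could not place {spec.n_cells} cells in cluster {spec.name} "
                    f"after {budget} attempts; region too dense")
            attempts += 1
            box = spec.region[rng.choice(len(spec.region), p=weights)]
            if config.kind == "egg_cylinder":
                p = _sample_region_embryo(rng, box, geom)
                t = (p[0] - geom["margin_um"]) / geom["height_um"]
            else:
                p, t = _sample_region_band(rng, box, geom)
            if not ok(p):
                continue
            grid.setdefault(tuple((p // cell_size).astype(int)), []).append(p)
            centers.append(p)
            cluster_of.append(spec.name)
            axis_t.append(t)
            placed += 1
    return np.array(centers), np.array(cluster_of), np.array(axis_t)


def _box_weight(box: dict, kind: str) -> float:
    if kind == "egg_cylinder":
        z0, z1 = box["z"]
        r0, r1 = box["r"]
        return max(z1 - z0, 0) * max(r1 ** 2 - r0 ** 2, 0)
    d0, d1 = box["offset"]
    return max(d1 - d0, 0)


def _paint_nuclei(shape, centers, semi_axes, voxel_size) -> np.ndarray:
    """Rasterize non-overlapping ellipsoids; label = placement order (1-based)."""
    labels = np.zeros(shape, dtype=np.uint32)
    vs = np.asarray(voxel_size)
    for i, (c, a) in enumerate(zip(centers, semi_axes), start=1):
        lo = np.maximum(np.floor((c - a) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((c + a) / vs).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        cz = (zz + 0.5) * vs[0]
        cy = (yy + 0.5) * vs[1]
        cx = (xx + 0.5) * vs[2]
        inside = (((cz - c[0]) / a[0]) ** 2 + ((cy - c[1]) / a[1]) ** 2
                  + ((cx - c[2]) / a[2]) ** 2) <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = i
    return labels


# ---------------------------------------------------------------------------
# expression + spots
# ---------------------------------------------------------------------------

def _draw_counts(rng, config: FateMapConfig, cluster_of, axis_t):
    """Expected rates and realized NB counts, genes x cells."""
    genes = list(config.genes)
    n_cells = len(cluster_of)
    mu = np.zeros((len(genes), n_cells))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for spec in config.clusters:
        cols = np.flatnonzero(cluster_of == spec.name)
        for g, rate in spec.base_rates.items():
            mu[gene_pos[g], cols] = rate
        for g, beta in spec.gradients.items():
            mu[gene_pos[g], cols] *= np.exp(beta * axis_t[cols])
    for factor in config.coexpression:
        z = rng.standard_normal(n_cells)
        mask = (np.ones(n_cells, dtype=bool) if factor.clusters is None
                else np.isin(cluster_of, factor.clusters))
        for g, load in factor.loadings.items():
            mu[gene_pos[g], mask] *= np.exp(load * z[mask])
    size = config.nb_size
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    if np.isfinite(size):
        counts[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
    else:
        counts[pos] = rng.poisson(mu[pos])
    return mu, counts


def _spots_from_counts(rng, config, codebook, counts, centers, semi_axes, genes):
    """Place each nuclear transcript uniformly in its cell's dilated ellipsoid."""
    n_genes, n_cells = counts.shape
    flat = counts.ravel()
    rep = np.repeat(np.arange(flat.size), flat)
    gene_idx = rep // n_cells
    cell_idx = rep % n_cells
    n = len(rep)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    rad = rng.uniform(0, 1, n) ** (1 / 3)
    semi = semi_axes[cell_idx] + config.spot_dilation_um
    pos = centers[cell_idx] + u * rad[:, None] * semi
    return _spot_frame(rng, config, codebook, genes, gene_idx, pos, cell_idx + 1)


def _background_spots(rng, config, codebook, extent_um):
    """Homogeneous Poisson false positives over the tissue bounding volume."""
    lam = config.background_rate_per_cell * config.n_cells
    n = int(rng.poisson(lam))
    all_names = list(codebook.entries)
    gene_idx = rng.integers(0, len(all_names), n)
    pos = rng.uniform(0, 1, (n, 3)) * np.asarray(extent_um)
    return _spot_frame(rng, config, codebook, all_names, gene_idx, pos,
                       np.zeros(n, dtype=np.int64))


def _spot_frame(rng, config, codebook, genes, gene_idx, pos, cell_ids):
    names = np.asarray(genes, dtype=object)[gene_idx]
    chan = np.array([codebook.entries[g].channel for g in names], dtype=np.int64) \
        if len(names) else np.zeros(0, dtype=np.int64)
    cyc = np.array([codebook.entries[g].cycle for g in names], dtype=np.int64) \
        if len(names) else np.zeros(0, dtype=np.int64)
    amp = np.array([config.amplification[c] for c in chan]) if len(chan) else np.zeros(0)
    intensity = amp * rng.lognormal(0.0, config.intensity_sigma, len(names))
    spots = pd.DataFrame({
        "x_um": pos[:, 2], "y_um": pos[:, 1], "z_um": pos[:, 0],
        "channel": chan, "cycle": cyc, "gene": names, "intensity": intensity,
    })
    truth = pd.DataFrame({"gene": names, "cell": cell_ids})
    return spots, truth


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _finalize(rng, config, codebook, geom_extent, centers, semi_axes, cluster_of,
              axis_t, shape, side):
    mu, counts = _draw_counts(rng, config, np.asarray(cluster_of), np.asarray(axis_t))
    genes = list(config.genes)
    spots_n, truth_n = _spots_from_counts(rng, config, codebook, counts,
                                          centers, semi_axes, genes)
    spots_b, truth_b = _background_spots(rng, config, codebook, geom_extent)
    spots = pd.concat([spots_n, spots_b], ignore_index=True)
    truth_spots = pd.concat([truth_n, truth_b], ignore_index=True)

    labels = _paint_nuclei(shape, centers, semi_axes, config.voxel_size_um)
    volume = LabelVolume(labels, config.voxel_size_um)

    cell_ids = np.arange(1, len(centers) + 1)
    cells = pd.DataFrame({
        "cluster": cluster_of,
        "z_um": centers[:, 0], "y_um": centers[:, 1], "x_um": centers[:, 2],
        "axis_t": axis_t,
        "side": side,
    }, index=pd.Index(cell_ids, name="cell"))
    truth = GroundTruth(
        cells=cells,
        true_counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cell_ids),
        expected_rates=pd.DataFrame(mu, index=pd.Index(genes, name="gene"), columns=cell_ids),
        spots=truth_spots,
    )
    return volume, spots, truth


def generate_embryo(config: FateMapConfig, codebook: Codebook):
    """Synthesize an egg-cylinder embryo: (LabelVolume, SpotTable, GroundTruth)."""
    config.validate()
    if config.kind != "egg_cylinder":
        raise ValueError("generate_embryo requires an egg_cylinder config")
    missing = (set(config.genes) - set(codebook.entries))
    if missing:
        raise ValueError(f"codebook does not cover genes: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(config.seed)
    geom = dict(config.geometry)
    R, H, m = geom["radius_um"], geom["height_um"], geom["margin_um"]
    outer = geom.get("outer_frac", 1.2)
    half = outer * R + m
    geom["center_yx_um"] = (half, half)
    extent = (H + 2 * m, 2 * half, 2 * half)
    shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, config.voxel_size_um))

    centers, cluster_of, axis_t = _place_cells(rng, config, geom)
    semi_axes = config.nucleus_radius_um * rng.uniform(
        1 - config.radius_jitter, 1 + config.radius_jitter, (len(centers), 3))
    side = np.where(centers[:, 2] > geom["center_yx_um"][1], "right", "left")
    return _finalize(rng, config, codebook, extent, centers, semi_axes,
                     cluster_of, axis_t, shape, side)


def generate_hippocampus(config: FateMapConfig, codebook: Codebook | None = None):
    """Synthesize a layered hippocampal band.

    Returns (LabelVolume, SpotTable, GroundTruth, ProteinTable); ``axis_t``
    in the ground truth is the normalized midline arc-length position.
    """
    config.validate()
    if config.kind != "band":
        raise ValueError("generate_hippocampus requires a band config")
    if codebook is None:
        codebook = build_codebook(list(config.genes), config.n_controls,
                                  seed=config.seed)
    rng = np.random.default_rng(config.seed)
    geom = dict(config.geometry)
    geom["_curve"] = _band_curve(geom)
    y_of, _, xs, _ = geom["_curve"]
    w = max(abs(b["offset"][0]) for c in config.clusters for b in c.region)
    w = max(w, max(b["offset"][1] for c in config.clusters for b in c.region))
    y_max = float(np.max(y_of(xs))) + w + geom["y_margin_um"]
    extent = (geom["thickness_um"] + 2 * geom["z_margin_um"],
              y_max, geom["x_max_um"] + geom["x_margin_um"])
    shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, config.voxel_size_um))

    centers, cluster_of, axis_t = _place_cells(rng, config, geom)
    semi_axes = config.nucleus_radius_um * rng.uniform(
        1 - config.radius_jitter, 1 + config.radius_jitter, (len(centers), 3))
    side = np.where(axis_t > 0.5, "right", "left")
    volume, spots, truth = _finalize(rng, config, codebook, extent, centers,
                                     semi_axes, cluster_of, axis_t, shape, side)
    protein = _protein_table(rng, config, truth.cells)
    return volume, spots, truth, protein


def _protein_table(rng, config: FateMapConfig, cells: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-nucleus antigen intensities, reference included."""
    rows = []
    ref = config.reference_intensity * rng.lognormal(0.0, config.protein_sigma, len(cells))
    for cell, r in zip(cells.index, ref):
        rows.append({"cell": cell, "antigen": config.reference_antigen, "mean_intensity": r})
    for antigen, folds in config.antigen_folds.items():
        noise = rng.lognormal(0.0, config.protein_sigma, len(cells))
        for (cell, row), r, e in zip(cells.iterrows(), ref, noise):
            fold = folds.get(row["cluster"], 1.0)
            rows.append({"cell": cell, "antigen": antigen, "mean_intensity": fold * r * e})
    return pd.DataFrame(rows, columns=["cell", "antigen", "mean_intensity"])


def render_protein_volume(volume: LabelVolume, per_cell: pd.Series,
                          background: float = 0.0) -> np.ndarray:
    """Paint a per-cell intensity onto the nucleus masks (test/demo helper)."""
    out = np.full(volume.labels.shape, float(background))
    lut = np.full(int(volume.labels.max()) + 1, float(background))
    for cell, v in per_cell.items():
        lut[int(cell)] = v
    mask = volume.labels > 0
    out[mask] = lut[volume.labels[mask]]
    return out


# ---------------------------------------------------------------------------
# default configurations (the package's study conditions)
# ---------------------------------------------------------------------------

def default_embryo_config(seed: int = 0, scale: float = 1.0) -> FateMapConfig:
    """Nine-cluster egg-cylinder fate map, ~1,500 cells / 60 genes at scale 1.

    Five marker genes per cluster (strong in their own cluster, near-silent
    elsewhere), five broadly expressed genes — two carrying opposite axial
    gradients in the epiblast column, two sharing a latent co-expression
    factor — and ten silent genes. ``scale=7.3`` approximates the full-size
    11,000-cell study; geometry scales with the cube root of cell number.
    """
    marker_rate, off_rate, broad_rate = 12.0, 0.3, 4.0
    genes: list[str] = []
    cluster_counts = {"C1": 320, "C2": 210, "C3": 190, "C4": 110, "C5": 260,
                      "C6": 110, "C7": 120, "C8": 70, "C9": 110}
    regions = {
        "C1": [{"z": (0.05, 0.45), "r": (0.00, 0.40)}],
        "C2": [{"z": (0.05, 0.45), "r": (0.40, 0.62)}],
        "C3": [{"z": (0.05, 0.45), "r": (0.62, 0.80)}],
        "C4": [{"z": (0.45, 0.57), "r": (0.00, 0.80)}],
        "C5": [{"z": (0.57, 0.95), "r": (0.00, 0.80)}],
        "C6": [{"z": (0.05, 0.45), "r": (0.84, 1.00)}],
        "C7": [{"z": (0.57, 0.95), "r": (0.84, 1.00)}],
        "C8": [{"z": (0.42, 0.60), "r": (1.04, 1.20)}],
        "C9": [{"z": (0.05, 0.40), "r": (1.04, 1.20)},
               {"z": (0.62, 0.95), "r": (1.04, 1.20)}],
    }
    markers = {c: [f"M{c[1]}_{i + 1}" for i in range(5)] for c in cluster_counts}
    for c in cluster_counts:
        genes += markers[c]
    broad = [f"B{i + 1}" for i in range(5)]
    silent = [f"S{i + 1}" for i in range(10)]
    genes += broad + silent

    lin = np.cbrt(scale)
    clusters = []
    for cname, n in cluster_counts.items():
        base = {g: off_rate for ms in markers.values() for g in ms}
        base.update({g: marker_rate for g in markers[cname]})
        base.update({g: broad_rate for g in broad})
        base.update({g: 0.0 for g in silent})
        gradients = {}
        if cname == "C1":
            gradients = {"B1": 1.2, "B2": -1.2}
        if cname == "C2":
            gradients = {"B3": 1.0, "B4": 1.0}
        clusters.append(ClusterSpec(
            name=cname, n_cells=max(1, int(round(n * scale))),
            region=regions[cname], base_rates=base, gradients=gradients))

    return FateMapConfig(
        kind="egg_cylinder",
        geometry={"radius_um": 85.0 * lin, "height_um": 245.0 * lin,
                  "outer_frac": 1.2, "margin_um": 4.0},
        clusters=clusters,
        genes=genes,
        n_controls=6,
        coexpression=[CoexpressionFactor(loadings={"B3": 0.6, "B4": 0.6},
                                         clusters=["C1"])],
        seed=seed,
    )


def default_hippocampus_config(seed: int = 0) -> FateMapConfig:
    """Curved three-layer band, 600 cells / 30 genes, with designated
    strong descending / ascending / flat gene sets along the midline and
    three antigen channels plus the H3K27me3 reference."""
    desc = [f"D{i + 1}" for i in range(5)]
    asc = [f"A{i + 1}" for i in range(5)]
    flat = [f"F{i + 1}" for i in range(14)]
    layer_markers = {"C1": ["LM1_1", "LM1_2"], "C2": ["LM2_1", "LM2_2"],
                     "C3": ["LM3_1", "LM3_2"]}
    genes = desc + asc + flat + [g for ms in layer_markers.values() for g in ms]

    gradients = {g: -1.4 for g in desc} | {g: 1.4 for g in asc}
    designations = ({g: "descending" for g in desc} | {g: "ascending" for g in asc}
                    | {g: "flat" for g in flat})

    offsets = {"C1": (-25.0, -8.33), "C2": (-8.33, 8.33), "C3": (8.33, 25.0)}
    clusters = []
    for cname, off in offsets.items():
        base = {g: 8.0 for g in desc + asc} | {g: 6.0 for g in flat}
        for other, ms in layer_markers.items():
            for g in ms:
                base[g] = 10.0 if other == cname else 0.5
        clusters.append(ClusterSpec(
            name=cname, n_cells=150,
            region=[{"offset": off}], base_rates=base, gradients=dict(gradients)))

    return FateMapConfig(
        kind="band",
        geometry={"x_min_um": 8.0, "x_max_um": 368.0, "curvature": 0.0006,
                  "y_apex_um": 30.0, "thickness_um": 32.0,
                  "z_margin_um": 4.0, "y_margin_um": 4.0, "x_margin_um": 8.0},
        clusters=clusters,
        genes=genes,
        n_controls=3,
        gene_designations=designations,
        antigen_folds={
            "H3K27ac": {"C1": 1.0, "C2": 1.5, "C3": 0.7},
            "H3K4me1": {"C1": 1.0, "C2": 0.8, "C3": 1.3},
            "Nup98": {"C1": 1.0, "C2": 1.0, "C3": 1.0},
        },
        seed=seed,
    )
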