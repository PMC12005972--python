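import numpy as np
import pytest

import cyclehcr as chc


@pytest.fixture(scope="session")
def embryo():
    """Default synthetic embryo (seed 1) run through assignment."""
    cfg = chc.default_embryo_config(seed=1)
    cb = chc.build_codebook(cfg.genes, cfg.n_controls, seed=cfg.seed)
    vol, spots, truth = chc.generate_embryo(cfg, cb)
    dil = chc.dilate_labels(vol, 1.0)
    assignment = chc.assign_spots(spots, dil)
    cm = chc.build_count_matrix(assignment, spots, vol, cb)
    return {"cfg": cfg, "cb": cb, "vol": vol, "spots": spots, "truth": truth,
            "dil": dil, "assignment": assignment, "cm": cm}


@pytest.fixture(scope="session")
def embryo_clustered(embryo):
    """Clustering (with UMAP embedding) of the session embryo."""
    cm = embryo["cm"]
    active = sorted(chc.filter_active_genes(cm, 200))
    rows = [cm.genes.get_loc(g) for g in active]
    norm, _ = chc.normalize_counts(cm.counts[rows])
    result = chc.cluster_cells(norm, seed=1, embed=True)
    return {"active": active, "normalized": norm, "result": result}


@pytest.fixture(scope="session")
def hippocampus():
    """Default synthetic hippocampal band (seed 2) run through assignment."""
    cfg = chc.default_hippocampus_config(seed=2)
    cb = chc.build_codebook(cfg.genes, cfg.n_controls, seed=cfg.seed)
    vol, spots, truth, protein = chc.generate_hippocampus(cfg, cb)
    dil = chc.dilate_labels(vol, 1.0)
    assignment = chc.assign_spots(spots, dil)
    cm = chc.build_count_matrix(assignment, spots, vol, cb)
    arc = truth.cells.loc[cm.cells, "axis_t"].to_numpy()
    return {"cfg": cfg, "cb": cb, "vol": vol, "spots": spots, "truth": truth,
            "protein": protein, "assignment": assignment, "cm": cm, "arc": arc}


def brute_force_dilate(labels: np.ndarray, voxel_size, radius_um: float) -> np.ndarray:
    """Per-voxel exhaustive nearest-labeled-voxel search (test oracle)."""
    labels = np.asarray(labels)
    scale = np.asarray(voxel_size, dtype=float)
    src = np.argwhere(labels > 0)
    src_labels = labels[tuple(src.T)].astype(np.int64)
    out = labels.copy()
    bg = np.argwhere(labels == 0)
    if len(src) == 0 or len(bg) == 0:
        return out
    # (n_bg, n_src) squared distances, fully vectorized
    d2 = ((bg[:, None, :] * scale - src[None, :, :] * scale) ** 2).sum(axis=2)
    best = d2.min(axis=1)
    within = best <= radius_um ** 2 + 1e-9
    tied = d2 <= best[:, None] + 1e-9
    winners = np.where(tied, src_labels[None, :], np.iinfo(np.int64).max).min(axis=1)
    sel = bg[within]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = winners[within].astype(labels.dtype)
    return out


def tiny_embryo_config(seed: int, n_cells: int = 220, gradient: float = 0.0,
                       nb_size: float = 5.0, background: float = 0.05):
    """Single-cluster cylinder used for calibration / recovery micro-tests."""
    genes = ["G1", "G2", "G3"]
    base = {"G1": 6.0, "G2": 10.0, "G3": 2.0}
    spec = chc.ClusterSpec(
        name="A", n_cells=n_cells,
        region=[{"z": (0.05, 0.95), "r": (0.0, 0.95)}],
        base_rates=base,
        gradients={"G1": gradient} if gradient else {},
    )
    return chc.FateMapConfig(
        kind="egg_cylinder",
        geometry={"radius_um": 36.0, "height_um": 110.0, "outer_frac": 1.0,
                  "margin_um": 4.0},
        clusters=[spec], genes=genes, n_controls=2,
        background_rate_per_cell=background, nb_size=nb_size, seed=seed,
    )
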