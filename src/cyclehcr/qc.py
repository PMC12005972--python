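"""Quality control: false-positive estimation from non-targeting barcodes,
active-gene and low-count-cell filtering, and per-cycle stability checks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import CountMatrix, LabelVolume


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    fp_rate_per_cell: float = np.nan
    control_totals: dict = field(default_factory=dict)
    active_genes: list = field(default_factory=list)
    excluded_cells: list = field(default_factory=list)
    detection_by_cycle: dict = field(default_factory=dict)
    volume_by_cycle: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        text = json.dumps(asdict(self), indent=2, default=_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def estimate_false_positive_rate(cm: CountMatrix) -> tuple[float, pd.Series]:
    """Conservative false-positive rate: worst control gene's total / n cells.

    Non-targeting barcodes have no matching probe, so their spot totals bound
    the per-barcode noise floor; taking the max control total is the
    conservative reading of "typically fewer than N counts".
    Returns (rate, per-control totals).
    """
    controls = cm.gene_meta.index[cm.gene_meta["is_control"]]
    if len(controls) == 0:
        raise QCError("no control genes flagged in gene_meta['is_control']")
    idx = [cm.genes.get_loc(g) for g in controls]
    totals = pd.Series(cm.counts[idx].sum(axis=1), index=controls, name="total")
    return float(totals.max()) / cm.n_cells, totals


def filter_active_genes(cm: CountMatrix, min_total: int | None = None) -> set:
    """Genes with embryo-wide total strictly above ``min_total``; controls never.

    Default threshold = the maximum observed control total (the data-driven
    noise ceiling), falling back to 200 when no controls are present.
    """
    if min_total is None:
        if cm.gene_meta["is_control"].any():
            min_total, _ = estimate_false_positive_rate(cm)
            min_total = int(min_total * cm.n_cells + 0.5)
        else:
            min_total = 200
    if min_total < 0:
        raise QCError("min_total must be >= 0")
    totals = cm.counts.sum(axis=1)
    active = {
        g for g, tot, ctrl in zip(cm.genes, totals, cm.gene_meta["is_control"])
        if tot > min_total and not ctrl
    }
    cm.gene_meta["active"] = [g in active for g in cm.genes]
    return active


def filter_cells(cm: CountMatrix, min_cell_total: int = 10,
                 active_genes: set | None = None) -> set:
    """Cells whose total over active genes is below ``min_cell_total``.

    Excluded cells are flagged in ``cell_meta['excluded']``, never dropped,
    so spot conservation is preserved.
    """
    if active_genes is None:
        if "active" in cm.gene_meta:
            active_genes = set(cm.gene_meta.index[cm.gene_meta["active"].fillna(False)])
        else:
            active_genes = set(cm.genes[~cm.gene_meta["is_control"]])
    rows = [cm.genes.get_loc(g) for g in active_genes]
    totals = cm.counts[rows].sum(axis=0) if rows else np.zeros(cm.n_cells)
    excluded = {c for c, t in zip(cm.cells, totals) if t < min_cell_total}
    cm.cell_meta["excluded"] = [c in excluded for c in cm.cells]
    return excluded


def detection_rate_by_cycle(cm: CountMatrix, codebook,
                            active_genes: set | None = None) -> pd.DataFrame:
    """Mean spots per active gene in each imaging cycle, with a linear trend.

    The returned frame has one row per cycle; its ``attrs`` carry the fitted
    slope, a 95% CI, and a ``stable`` flag (CI covers zero). A single cycle
    leaves the trend undefined.
    """
    if active_genes is None:
        active_genes = set(cm.genes[~cm.gene_meta["is_control"]])
    per_cycle = {}
    for gene in active_genes:
        if gene not in codebook.entries:
            continue
        cyc = codebook.entries[gene].cycle
        per_cycle.setdefault(cyc, []).append(cm.counts[cm.genes.get_loc(gene)].sum())
    rows = [{"cycle": c, "n_genes": len(v), "mean_spots_per_gene": float(np.mean(v))}
            for c, v in sorted(per_cycle.items())]
    df = pd.DataFrame(rows)
    if len(df) < 2:
        df.attrs.update({"slope": np.nan, "ci": (np.nan, np.nan),
                         "stable": None, "trend_defined": False})
        return df
    fit = stats.linregress(df["cycle"], df["mean_spots_per_gene"])
    tcrit = stats.t.ppf(0.975, len(df) - 2) if len(df) > 2 else np.inf
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    ci = (fit.slope - tcrit * stderr, fit.slope + tcrit * stderr)
    # numerical slack so an exactly-flat series counts as stable
    tol = 1e-9 * max(1.0, float(np.abs(df["mean_spots_per_gene"]).max()))
    df.attrs.update({"slope": float(fit.slope), "ci": ci,
                     "stable": bool(ci[0] <= tol and ci[1] >= -tol),
                     "trend_defined": True})
    return df


def nuclear_volume_stability(volumes: list[LabelVolume]) -> pd.DataFrame:
    """Median nuclear volume per cycle and the max relative drift vs cycle 1."""
    if not volumes:
        raise QCError("need at least one label volume")
    medians = []
    for i, vol in enumerate(volumes, start=1):
        counts = np.bincount(vol.labels.ravel())
        counts = counts[1:][counts[1:] > 0]
        medians.append({"cycle": i,
                        "median_volume_um3": float(np.median(counts) * vol.voxel_volume_um3)})
    df = pd.DataFrame(medians)
    ref = df["median_volume_um3"].iloc[0]
    drift = float(np.max(np.abs(df["median_volume_um3"] - ref)) / ref)
    df.attrs["max_relative_drift"] = drift
    return df


def run_qc(cm: CountMatrix, codebook=None, min_total: int | None = None,
           min_cell_total: int = 10) -> QCReport:
    """Full QC pass over a count matrix; mutates the matrix's QC flags."""
    rate, totals = estimate_false_positive_rate(cm)
    active = filter_active_genes(cm, min_total)
    excluded = filter_cells(cm, min_cell_total, active)
    report = QCReport(
        fp_rate_per_cell=rate,
        control_totals=totals.to_dict(),
        active_genes=sorted(active),
        excluded_cells=sorted(int(c) for c in excluded),
    )
    if codebook is not None:
        det = detection_rate_by_cycle(cm, codebook, active)
        report.detection_by_cycle = {
            "table": det.to_dict(orient="list"), **{k: det.attrs[k] for k in det.attrs}}
    return report
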