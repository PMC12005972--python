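"""Per-nucleus protein quantification and cluster-wise comparison.

Antigen intensities are averaged over undilated nucleus masks, normalized
per cell to an inactive-chromatin reference antigen (default H3K27me3) to
cancel local staining imbalances, and compared across clusters with a
one-way ANOVA followed by pairwise Bonferroni-adjusted tests against a
reference cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .assignment import LabelVolume


class ProteinError(ValueError):
    pass


DEFAULT_REFERENCE = "H3K27me3"


def quantify_masks(intensity: np.ndarray, volume: LabelVolume,
                   antigen: str) -> pd.DataFrame:
    """Mean voxel intensity per label over the undilated nucleus masks."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != volume.labels.shape:
        raise ProteinError("intensity volume shape must match label volume")
    ids = volume.label_ids
    if ids.size == 0:
        return pd.DataFrame(columns=["cell", "antigen", "mean_intensity"])
    means = ndimage.mean(intensity, labels=volume.labels, index=ids)
    return pd.DataFrame({"cell": ids, "antigen": antigen,
                         "mean_intensity": np.asarray(means, dtype=float)})


def normalize_to_reference(table: pd.DataFrame,
                           reference: str = DEFAULT_REFERENCE) -> pd.DataFrame:
    """Per-cell target/reference intensity ratios.

    Cells with a missing or non-positive reference measurement are excluded
    and reported in the frame's ``attrs['excluded_cells']``.
    """
    required = {"cell", "antigen", "mean_intensity"}
    if not required <= set(table.columns):
        raise ProteinError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(index="cell", columns="antigen",
                             values="mean_intensity", aggfunc="mean")
    if reference not in wide.columns:
        raise ProteinError(f"reference antigen {reference!r} not in table")
    ref = wide[reference]
    valid = ref.notna() & (ref > 0)
    targets = [c for c in wide.columns if c != reference]
    ratios = wide.loc[valid, targets].div(ref[valid], axis=0)
    out = ratios.reset_index().melt(id_vars="cell", var_name="antigen",
                                    value_name="ratio").dropna(subset=["ratio"])
    out = out.sort_values(["antigen", "cell"]).reset_index(drop=True)
    out.attrs["excluded_cells"] = sorted(wide.index[~valid].tolist())
    out.attrs["reference"] = reference
    return out


def significance_code(p: float) -> str:
    """Legend thresholds: n.s. p > 0.05; * <0.05; ** <0.01; *** <0.001; **** <0.0001."""
    if np.isnan(p) or p > 0.05:
        return "n.s."
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return "*"


def compare_groups(values_by_group: dict, reference_group) -> dict:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise tests.

    Each non-reference group is compared to ``reference_group`` with a
    Welch two-sample t-test; raw p-values are multiplied by the number of
    comparisons and capped at 1. Degenerate all-constant input yields p = 1
    (n.s.) when means are equal.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if reference_group not in groups:
        raise ProteinError(f"reference group {reference_group!r} missing")
    if len(groups) < 2:
        raise ProteinError("need >= 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ProteinError(f"group {k!r} needs >= 2 values")

    all_const = all(g.std() == 0 for g in groups.values())
    if all_const:
        means = {k: g.mean() for k, g in groups.items()}
        anova_p = np.nan
        anova_f = np.nan
        degenerate = True
    else:
        anova_f, anova_p = stats.f_oneway(*groups.values())
        degenerate = False

    n_comp = len(groups) - 1
    pairwise = {}
    ref = groups[reference_group]
    for k, g in groups.items():
        if k == reference_group:
            continue
        if g.std() == 0 and ref.std() == 0:
            raw = 1.0 if g.mean() == ref.mean() else 0.0
        else:
            raw = float(stats.ttest_ind(g, ref, equal_var=False).pvalue)
        adj = min(raw * n_comp, 1.0)
        pairwise[k] = {"p_raw": raw, "p_adjusted": adj,
                       "code": significance_code(adj)}
    return {"anova_f": float(anova_f) if np.isfinite(anova_f) else np.nan,
            "anova_p": float(anova_p) if np.isfinite(anova_p) else np.nan,
            "degenerate": degenerate, "test": "welch_t",
            "n_comparisons": n_comp, "pairwise": pairwise}


def boxplot_summary(values_by_group: dict) -> pd.DataFrame:
    """10/25/50/75/90 percentiles plus mean per group (boxplot conventions)."""
    rows = []
    for k, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
        rows.append({"group": k, "n": len(v), "p10": q10, "p25": q25,
                     "median": q50, "p75": q75, "p90": q90, "mean": v.mean()})
    return pd.DataFrame(rows).set_index("group")
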