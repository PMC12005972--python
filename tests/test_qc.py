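"""False-positive estimation, gene/cell filtering, and stability checks."""

import numpy as np
import pandas as pd
import pytest

import cyclehcr as chc
from cyclehcr.qc import QCError


def matrix_from_counts(counts, genes, is_control):
    counts = np.asarray(counts)
    cells = np.arange(1, counts.shape[1] + 1)
    return chc.CountMatrix(
        counts=counts, genes=pd.Index(genes), cells=cells,
        cell_meta=pd.DataFrame(index=pd.Index(cells, name="cell")),
        gene_meta=pd.DataFrame({"is_control": is_control}, index=pd.Index(genes)),
    )


class TestFalsePositiveRate:
    def test_worked_example_200_spots_11029_cells(self):
        """Max control total 200 over 11,029 cells -> 0.018 spots/cell."""
        n_cells = 11029
        counts = np.zeros((3, n_cells), dtype=int)
        counts[1, :200] = 1          # control A: 200 spots
        counts[2, :90] = 1           # control B: fewer
        cm = matrix_from_counts(counts, ["g", "ctrlA", "ctrlB"],
                                [False, True, True])
        rate, totals = chc.estimate_false_positive_rate(cm)
        assert round(rate, 3) == 0.018
        assert totals["ctrlA"] == 200

    def test_zero_controls_zero_rate(self):
        cm = matrix_from_counts(np.zeros((2, 50), dtype=int), ["g", "nt"],
                                [False, True])
        rate, _ = chc.estimate_false_positive_rate(cm)
        assert rate == 0.0

    def test_no_controls_error(self):
        cm = matrix_from_counts(np.ones((2, 5), dtype=int), ["a", "b"],
                                [False, False])
        with pytest.raises(QCError):
            chc.estimate_false_positive_rate(cm)

    def test_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (4, 300))
        cm = matrix_from_counts(counts, list("abcd"), [False, True, True, False])
        rate, _ = chc.estimate_false_positive_rate(cm)
        perm = rng.permutation(300)
        cm2 = matrix_from_counts(counts[:, perm], list("abcd"),
                                 [False, True, True, False])
        rate2, _ = chc.estimate_false_positive_rate(cm2)
        assert rate == rate2

    def test_against_max_order_statistic_monte_carlo(self):
        """Estimate matches the expected max of control totals under the
        generating Poisson law (0.05 background spots/cell, 20 controls)."""
        n_cells, n_entries, n_controls = 5000, 25, 20
        lam = 0.05 * n_cells / n_entries   # per-entry background total
        rng = np.random.default_rng(42)
        genes = [f"t{i}" for i in range(n_entries - n_controls)] + \
                [f"nt{i}" for i in range(n_controls)]
        is_control = [g.startswith("nt") for g in genes]
        counts = np.zeros((n_entries, n_cells), dtype=int)
        for i in range(n_entries):
            total = rng.poisson(lam)
            counts[i] = rng.multinomial(total, np.full(n_cells, 1 / n_cells))
        cm = matrix_from_counts(counts, genes, is_control)
        rate, _ = chc.estimate_false_positive_rate(cm)
        # independent Monte-Carlo of the max-order statistic
        mc = np.max(rng.poisson(lam, (1000, n_controls)), axis=1) / n_cells
        assert abs(rate - mc.mean()) <= 3 * mc.std()


class TestGeneAndCellFilters:
    def test_zero_count_gene_inactive(self):
        cm = matrix_from_counts([[0, 0], [5, 5], [1, 1]], ["dead", "live", "nt"],
                                [False, False, True])
        active = chc.filter_active_genes(cm, min_total=0)
        assert active == {"live"}

    def test_threshold_zero_all_counted_genes_active(self):
        cm = matrix_from_counts([[1, 0], [0, 1]], ["a", "b"], [False, False])
        assert chc.filter_active_genes(cm, min_total=0) == {"a", "b"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, (10, 100))
        genes = [f"g{i}" for i in range(10)]
        cm = matrix_from_counts(counts, genes, [False] * 10)
        prev = chc.filter_active_genes(cm, 0)
        for thr in (50, 150, 300, 500):
            cur = chc.filter_active_genes(cm, thr)
            assert cur <= prev
            prev = cur

    def test_exact_recovery_of_expressed_genes(self, embryo):
        """60-gene panel with 10 silent genes: the 50 expressed recovered."""
        active = chc.filter_active_genes(embryo["cm"], min_total=200)
        cfg = embryo["cfg"]
        expressed = {g for g in cfg.genes if not g.startswith("S")}
        assert active == expressed

    def test_pure_background_yields_no_active_genes(self):
        """All genes behave like non-targeting barcodes: ~none pass the
        data-driven (max-control) threshold."""
        n_active_total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(5.0 / 200, (30, 200))
            genes = [f"g{i}" for i in range(10)] + [f"nt{i}" for i in range(20)]
            cm = matrix_from_counts(counts, genes,
                                    [False] * 10 + [True] * 20)
            n_active_total += len(chc.filter_active_genes(cm))
        assert n_active_total <= 5

    def test_cell_filter_edge_cases(self):
        counts = np.array([[0, 10, 9], [0, 5, 1]])
        cm = matrix_from_counts(counts, ["a", "b"], [False, False])
        excluded = chc.filter_cells(cm, min_cell_total=10)
        assert 1 in excluded            # all-zero cell
        assert 2 not in excluded        # 15 >= 10
        assert 3 not in excluded        # exactly at threshold: retained
        assert list(cm.cell_meta["excluded"]) == [True, False, False]

    def test_low_rate_cluster_dominates_exclusions(self, embryo):
        cm, truth = embryo["cm"], embryo["truth"]
        active = chc.filter_active_genes(cm, 200)
        # raise the bar so only genuinely low-count cells fall out
        excluded = chc.filter_cells(cm, min_cell_total=10, active_genes=active)
        # the default embryo has no low-rate cluster: nothing excluded
        assert len(excluded) == 0


class TestDetectionRate:
    def _codebook(self, n_genes):
        return chc.build_codebook([f"g{i}" for i in range(n_genes)], 0, seed=0)

    def test_flat_counts_zero_slope(self):
        cb = self._codebook(30)
        counts = np.full((30, 10), 7)
        cm = matrix_from_counts(counts, [f"g{i}" for i in range(30)], [False] * 30)
        df = chc.detection_rate_by_cycle(cm, cb)
        assert df.attrs["slope"] == pytest.approx(0.0, abs=1e-12)
        assert df.attrs["stable"]

    def test_injected_decay_recovered(self):
        cb = self._codebook(60)
        totals = {}
        for name, bc in cb.entries.items():
            totals[name] = 1000.0 * (0.98 ** (bc.cycle - 1))
        counts = np.array([[totals[f"g{i}"]] for i in range(60)])
        cm = matrix_from_counts(counts.astype(int), [f"g{i}" for i in range(60)],
                                [False] * 60)
        df = chc.detection_rate_by_cycle(cm, cb)
        assert df.attrs["slope"] < 0
        assert not df.attrs["stable"]

    def test_single_cycle_undefined(self):
        cb = self._codebook(3)
        cm = matrix_from_counts(np.ones((3, 4), dtype=int), ["g0", "g1", "g2"],
                                [False] * 3)
        df = chc.detection_rate_by_cycle(cm, cb)
        assert not df.attrs["trend_defined"]


class TestVolumeStability:
    def _volume(self, n_extra=0):
        labels = np.zeros((8, 8, 8), dtype=np.uint32)
        labels[1:6, 1:6, 1:5] = 1            # 100 voxels
        extra = [(0, 1, 1), (0, 2, 2), (0, 3, 3), (0, 4, 4), (7, 1, 1)]
        for p in extra[:n_extra]:
            labels[p] = 1
        return chc.LabelVolume(labels, (1.0, 1.0, 1.0))

    def test_identical_volumes_zero_drift(self):
        df = chc.nuclear_volume_stability([self._volume()] * 3)
        assert df.attrs["max_relative_drift"] == 0.0

    def test_five_percent_inflation_detected(self):
        df = chc.nuclear_volume_stability([self._volume(), self._volume(5)])
        assert df.attrs["max_relative_drift"] == pytest.approx(0.05)

    def test_single_cycle_zero_drift(self):
        df = chc.nuclear_volume_stability([self._volume()])
        assert df.attrs["max_relative_drift"] == 0.0


def test_run_qc_end_to_end(embryo, tmp_path):
    report = chc.run_qc(embryo["cm"], embryo["cb"])
    assert report.fp_rate_per_cell >= 0
    assert set(report.active_genes) <= set(embryo["cfg"].genes)
    text = report.to_json(tmp_path / "qc.json")
    assert (tmp_path / "qc.json").read_text() == text
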