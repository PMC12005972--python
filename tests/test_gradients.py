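"""Gradient regression, slope ranking, co-expression, segment classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cyclehcr as chc
from cyclehcr.gradients import GradientError
from conftest import tiny_embryo_config


def scaled_ols_oracle(y, x):
    """Independent re-implementation of the min-max-scaled OLS slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.max() == y.min():
        return 0.0
    ys = (y - y.min()) / (y.max() - y.min())
    xs = (x - x.min()) / (x.max() - x.min())
    return float(np.polyfit(xs, ys, 1)[0])


def make_axes(dp):
    dp = np.asarray(dp, dtype=float)
    return pd.DataFrame({"dp_um": dp, "ap_deg": 0.0, "radial_um": 0.0,
                         "side": "left", "on_midline": False})


class TestFitGradient:
    def test_expression_equals_coordinate_slope_one(self):
        dp = np.linspace(0, 100, 40)
        counts = dp[None, :].copy()
        fit = chc.fit_gradient(counts, ["g"], make_axes(dp),
                               np.ones(40, dtype=int), 1, "dp", "g")
        assert fit.slope_k == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_gene_degenerate(self):
        dp = np.linspace(0, 100, 25)
        counts = np.full((1, 25), 4.0)
        fit = chc.fit_gradient(counts, ["g"], make_axes(dp),
                               np.ones(25, dtype=int), 1, "dp", "g")
        assert fit.slope_k == 0.0
        assert fit.degenerate

    def test_min_cells_enforced(self):
        dp = np.arange(10.0)
        with pytest.raises(GradientError):
            chc.fit_gradient(np.ones((1, 10)), ["g"], make_axes(dp),
                             np.ones(10, dtype=int), 1, "dp", "g")

    def test_slope_invariant_to_affine_count_rescaling(self):
        rng = np.random.default_rng(0)
        dp = rng.uniform(0, 50, 60)
        y = rng.poisson(3 + dp / 10).astype(float)
        labels = np.ones(60, dtype=int)
        base = chc.fit_gradient(y[None, :], ["g"], make_axes(dp), labels, 1, "dp", "g")
        scaled = chc.fit_gradient((7.0 * y + 11.0)[None, :], ["g"], make_axes(dp),
                                  labels, 1, "dp", "g")
        assert scaled.slope_k == pytest.approx(base.slope_k, abs=1e-12)

    def test_injected_gradient_recovery_against_monte_carlo_oracle(self):
        """Sign always recovered; magnitude within 0.1 of the slope implied
        by the generating NB law (Monte-Carlo over fresh draws)."""
        rng = np.random.default_rng(99)
        for seed in range(5):
            cfg = tiny_embryo_config(seed=seed, gradient=1.0)
            cb = chc.build_codebook(cfg.genes, cfg.n_controls, seed=seed)
            _, _, truth = chc.generate_embryo(cfg, cb)
            t = truth.cells["axis_t"].to_numpy()
            counts = truth.true_counts.to_numpy().astype(float)
            labels = np.ones(len(t), dtype=int)
            fit = chc.fit_gradient(counts, cfg.genes, make_axes(t * 100),
                                   labels, 1, "dp", "G1")
            assert fit.slope_k > 0
            # oracle: expected scaled slope under the generating law
            mu = truth.expected_rates.loc["G1"].to_numpy()
            size = cfg.nb_size
            mc = [scaled_ols_oracle(rng.negative_binomial(size, size / (size + mu)), t)
                  for _ in range(200)]
            assert abs(fit.slope_k - np.mean(mc)) < 0.1


class TestRankGenes:
    def test_order_and_tie_break(self):
        fits = pd.DataFrame({"gene": ["b", "a", "c"],
                             "slope_k": [0.5, -0.5, 0.5]})
        out = chc.rank_genes_by_slope(fits)
        assert list(out["gene"]) == ["b", "c", "a"]

    def test_all_equal_lexicographic(self):
        fits = pd.DataFrame({"gene": ["z", "m", "a"], "slope_k": [0.1] * 3})
        assert list(chc.rank_genes_by_slope(fits)["gene"]) == ["a", "m", "z"]

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(0)
        fits = pd.DataFrame({"gene": [f"g{i}" for i in range(20)],
                             "slope_k": rng.normal(size=20).round(2)})
        out1 = chc.rank_genes_by_slope(fits)
        out2 = chc.rank_genes_by_slope(fits.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1, out2)


def spearman_bruteforce(a, b):
    """Textbook Spearman: Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks
    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


class TestCoexpression:
    def test_diag_and_reversed_ranks(self):
        counts = np.array([[1, 2, 3, 4], [4, 3, 2, 1], [1, 3, 2, 4]], dtype=float)
        cx = chc.coexpression_matrix(counts, ["a", "b", "c"],
                                     np.ones(4, dtype=int), 1)
        assert cx.rho[0, 0] == 1.0
        assert cx.rho[0, 1] == pytest.approx(-1.0)

    def test_exact_symmetry_and_range(self, embryo):
        cm, truth = embryo["cm"], embryo["truth"]
        genes = [f"M1_{i + 1}" for i in range(5)] + ["B1", "B2"]
        rows = [cm.genes.get_loc(g) for g in genes]
        cx = chc.coexpression_matrix(cm.counts[rows], genes,
                                     truth.cells["cluster"].to_numpy(), "C1")
        assert np.array_equal(cx.rho, cx.rho.T)   # bit-for-bit symmetric
        assert np.all(np.diag(cx.rho) == 1.0)
        assert cx.rho.min() >= -1 and cx.rho.max() <= 1

    def test_eight_cell_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5, (3, 8)).astype(float)
        cx = chc.coexpression_matrix(counts, ["a", "b", "c"],
                                     np.ones(8, dtype=int), 1)
        for i in range(3):
            for j in range(3):
                expected = spearman_bruteforce(counts[i], counts[j])
                assert abs(cx.rho[i, j] - expected) < 1e-12

    def test_constant_gene_masked(self):
        counts = np.array([[1, 2, 3, 4], [5, 5, 5, 5]], dtype=float)
        cx = chc.coexpression_matrix(counts, ["a", "const"],
                                     np.ones(4, dtype=int), 1)
        assert cx.rho[0, 1] == 0.0
        assert cx.undefined[0, 1] and not cx.undefined[0, 0]
        assert cx.rho[1, 1] == 1.0   # diagonal stays 1 by convention

    def test_shared_gradient_does_not_imply_coexpression(self, embryo):
        """B3 and B4 share the dp gradient in C2 (slope same sign, low rho)
        but share a latent factor only in C1 (high rho)."""
        cm, truth = embryo["cm"], embryo["truth"]
        cent = truth.cells[["z_um", "y_um", "x_um"]].to_numpy()
        lab = truth.cells["cluster"].to_numpy()
        ml = chc.fit_midline(cent, lab, anchor_clusters=["C1", "C2", "C3", "C4", "C5"],
                             proximal_anchor="C5")
        ax = chc.transform_coordinates(cent, ml, np.array([0.0, 1.0, 0.0]))
        counts = cm.counts.astype(float)
        fits = [chc.fit_gradient(counts, cm.genes, ax, lab, "C2", "dp", g)
                for g in ("B3", "B4")]
        assert np.sign(fits[0].slope_k) == np.sign(fits[1].slope_k)
        genes = ["B3", "B4", "B5"]
        rows = [cm.genes.get_loc(g) for g in genes]
        cx_c2 = chc.coexpression_matrix(cm.counts[rows], genes, lab, "C2")
        cx_c1 = chc.coexpression_matrix(cm.counts[rows], genes, lab, "C1")
        assert abs(cx_c2.rho[0, 1]) < 0.3          # independent noise in C2
        assert cx_c1.rho[0, 1] > 0.25              # shared factor in C1
        assert cx_c1.rho[0, 1] > cx_c2.rho[0, 1]


class TestClassifySegments:
    def test_perfect_linear_profiles(self):
        n_cells_per_seg = 10
        arc = np.repeat(np.linspace(0.05, 0.95, 9), n_cells_per_seg)
        seg_idx = np.repeat(np.arange(9), n_cells_per_seg)
        desc = (80.0 - 10.0 * seg_idx)[None, :]
        flat = np.full((1, 90), 5.0)
        asc = (10.0 + 10.0 * seg_idx)[None, :]
        counts = np.vstack([desc, flat, asc])
        out = chc.classify_segments(counts, ["down", "flat", "up"], arc)
        assert out.loc["down", "slope_k"] == pytest.approx(-1.0, abs=1e-12)
        assert out.loc["down", "class"] == "descending"
        assert out.loc["flat", "slope_k"] == 0.0
        assert out.loc["flat", "class"] == "flat"
        assert out.loc["up", "slope_k"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["up", "class"] == "ascending"

    def test_only_first_n_fit_segments_used(self):
        arc = np.repeat(np.linspace(0.05, 0.95, 9), 5)
        seg_idx = np.repeat(np.arange(9), 5)
        # linear over segments 1-8, then a huge jump in segment 9
        y = np.where(seg_idx < 8, 80.0 - 10.0 * seg_idx, 1000.0)[None, :]
        out = chc.classify_segments(y, ["g"], arc)
        assert out.loc["g", "slope_k"] == pytest.approx(-1.0, abs=1e-12)

    def test_empty_segment_flagged(self):
        arc = np.concatenate([np.full(30, 0.05), np.full(30, 0.95)])
        counts = np.vstack([np.r_[np.full(30, 10.0), np.full(30, 2.0)]])
        out = chc.classify_segments(counts, ["g"], arc)
        assert out.loc["g", "low_support"]

    def test_n_fit_exceeds_segments_rejected(self):
        with pytest.raises(GradientError):
            chc.classify_segments(np.ones((1, 10)), ["g"], np.linspace(0, 1, 10),
                                  n_segments=4, n_fit=5)

    def test_strong_gradient_genes_recovered(self, hippocampus):
        cfg, cm, arc = hippocampus["cfg"], hippocampus["cm"], hippocampus["arc"]
        rows = [cm.genes.get_loc(g) for g in cfg.genes]
        out = chc.classify_segments(cm.counts[rows], cfg.genes, arc)
        strong = {g: d for g, d in cfg.gene_designations.items() if d != "flat"}
        for gene, designation in strong.items():
            assert out.loc[gene, "class"] == designation
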