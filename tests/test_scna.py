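"""Expression normalization and two-component mixture SCNA recalling."""

import numpy as np
import pandas as pd
import pytest

import karyoclone as kc
from karyoclone.karyotype import RearrangementEvent
from karyoclone.scna import fit_region_mixture, posterior_scna
from karyoclone.simulate import ExpressionCellMatrix
from karyoclone.trees import Clone, CloneTree


def expr_matrix(genome, counts, cells=None):
    n_genes, n_cells = counts.shape
    genes = genome.genes[:n_genes]
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "baseline_mean": [g.baseline_mean for g in genes],
        }
    )
    cells_df = pd.DataFrame(
        {
            "cell_id": cells or [f"c{i}" for i in range(n_cells)],
            "clone_id": "SC1",
            "library_factor": 1.0,
        }
    )
    return ExpressionCellMatrix(genome, genes_df, cells_df, counts)


class TestNormalize:
    def test_zero_count_is_exactly_zero(self, genome):
        counts = np.zeros((3, 4), dtype=int)
        counts[0] = [1, 1, 1, 1]  # nonzero library
        expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        assert np.all(expr.values.iloc[1:].to_numpy() == 0.0)

    def test_closed_form_value(self, genome):
        # a library of 1e6 counts with 10 on a gene: log2(10/10 + 1) = 1.0
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 1_000_000 - 10
        expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        assert expr.values.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, genome, rng):
        counts = rng.integers(0, 50, size=(20, 15))
        counts[0] += 1  # no zero libraries
        expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        lib = counts.sum(axis=0)
        for i in range(20):
            for j in range(15):
                expected = np.log2((counts[i, j] / lib[j] * 1e6) / 10 + 1)
                assert abs(expr.values.iloc[i, j] - expected) < 1e-12

    def test_zero_library_cell_dropped(self, genome):
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = [5, 2, 1]
        counts[:, 2] = [1, 1, 1]
        with pytest.warns(UserWarning):
            expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        assert expr.values.shape[1] == 2


class TestRegionScores:
    def test_small_region_skipped(self, genome):
        counts = np.ones((30, 40), dtype=int)
        expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        g0 = genome.genes[0]
        region = (g0.chrom, g0.start, g0.end)  # contains ~1 gene
        assert kc.region_scores(region, expr) is None

    def test_identical_cells_score_zero(self, genome):
        counts = np.tile(np.arange(1, 31)[:, None], (1, 25))
        expr = kc.normalize_expression(expr_matrix(genome, counts), min_cells_expr=1)
        region = ("chr1", 0, genome.chrom_length("chr1"))
        scores = kc.region_scores(region, expr)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_het_deletion_gives_bimodal_scores(self, genome):
        ev = RearrangementEvent("chr1", 10_000_000, 40_000_000, "H1", "DEL")
        tree = CloneTree(
            [Clone("A", None, [], 0.5), Clone("B", "A", [ev], 0.5)], "linear", genome
        )
        e = kc.simulate_expression_cells(tree, genome, kc.SimConfig(seed=3, n_expr_cells=400))
        expr = kc.normalize_expression(e)
        scores = kc.region_scores(("chr1", 10_000_000, 40_000_000), expr)
        is_b = (e.cells.set_index("cell_id").clone_id == "B").loc[scores.index]
        gap = scores[~is_b].mean() - scores[is_b].mean()
        pooled_se = np.sqrt(
            scores[is_b].var() / is_b.sum() + scores[~is_b].var() / (~is_b).sum()
        )
        assert gap > 4 * pooled_se


class TestMixtureFit:
    def test_degenerate_scores_fail(self):
        scores = pd.Series(np.zeros(50), index=[f"c{i}" for i in range(50)])
        fit = fit_region_mixture(scores)
        assert fit.lrt_p == 1.0
        kc.filter_and_adjust([fit])
        assert fit.passed is False

    def test_two_cluster_parameter_recovery(self, rng):
        x = np.concatenate([rng.normal(-1, 0.05, 100), rng.normal(1, 0.05, 100)])
        scores = pd.Series(x, index=[f"c{i}" for i in range(200)])
        fit = fit_region_mixture(scores, n_genes_expressed=20, seed=0)
        kc.filter_and_adjust([fit])
        assert fit.delta_bic > 200
        assert fit.adj_p < 0.01
        assert fit.means[0] == pytest.approx(-1, abs=0.05)
        assert fit.means[1] == pytest.approx(1, abs=0.05)

    def test_em_never_below_single_component(self, rng):
        for i in range(100):
            x = rng.normal(size=30)
            fit = fit_region_mixture(pd.Series(x, index=[f"c{j}" for j in range(30)]))
            assert fit.loglik2 >= fit.loglik1 - 1e-9

    def test_component_ordering_stable_across_restarts(self, rng):
        x = np.concatenate([rng.normal(-0.5, 0.2, 80), rng.normal(0.5, 0.2, 80)])
        scores = pd.Series(x, index=[f"c{i}" for i in range(160)])
        fits = [fit_region_mixture(scores, seed=s) for s in range(5)]
        for f in fits:
            assert f.means[0] < f.means[1]
        mus = np.array([f.means for f in fits])
        assert np.ptp(mus, axis=0).max() < 0.05


class TestFilterAdjust:
    def test_single_region_adjustment_identity(self, rng):
        x = np.concatenate([rng.normal(-1, 0.1, 50), rng.normal(1, 0.1, 50)])
        fit = fit_region_mixture(pd.Series(x, index=[f"c{i}" for i in range(100)]))
        kc.filter_and_adjust([fit])
        assert fit.adj_p == pytest.approx(fit.lrt_p)

    def test_one_signal_among_nine_nulls(self, rng):
        fits = []
        for i in range(9):
            x = rng.normal(0, 0.3, 300)
            fits.append(
                fit_region_mixture(
                    pd.Series(x, index=[f"c{j}" for j in range(300)]),
                    region=("chr1", i, i + 1),
                    n_genes_expressed=20,
                    seed=i,
                )
            )
        x = np.concatenate([rng.normal(-0.8, 0.1, 150), rng.normal(0.4, 0.1, 150)])
        fits.append(
            fit_region_mixture(
                pd.Series(x, index=[f"c{j}" for j in range(300)]),
                region=("chr1", 99, 100),
                n_genes_expressed=20,
                seed=99,
            )
        )
        kc.filter_and_adjust(fits)
        assert [f.passed for f in fits] == [False] * 9 + [True]


@pytest.fixture(scope="module")
def separated_fit():
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(-1, 0.05, 100), rng.normal(1, 0.05, 100)])
    scores = pd.Series(x, index=[f"c{i}" for i in range(200)])
    return fit_region_mixture(scores, region=("chr1", 0, 1_000_000))


class TestPosteriors:

    def test_far_from_boundary_confident(self, separated_fit):
        post = posterior_scna(separated_fit)
        at_mu1 = post[post.cell_id == "c0"]  # drawn around -1
        assert float(at_mu1.p_low.iloc[0]) > 0.99

    def test_equal_density_point_uncertain(self):
        # an exactly symmetric mixture: the midpoint carries equal density
        from karyoclone.scna import RegionFit

        scores = pd.Series([0.0, -1.0, 1.0], index=["x", "lo", "hi"])
        fit = RegionFit(
            region=("chr1", 0, 1), n_genes_expressed=20, scores=scores,
            mean1=0.0, sd1=1.0, loglik1=0.0, bic1=0.0,
            means=(-1.0, 1.0), sds=(0.2, 0.2), weight_low=0.5,
            loglik2=0.0, bic2=0.0, lrt_stat=0.0, lrt_p=0.0,
        )
        post = posterior_scna(fit).set_index("cell_id")
        assert post.loc["x", "p_low"] == pytest.approx(0.5, abs=1e-9)
        assert not bool(post.loc["x", "confident"])
        assert post.loc["lo", "p_low"] > 0.99

    def test_confident_assignment_accuracy(self, separated_fit):
        post = posterior_scna(separated_fit).set_index("cell_id")
        truth_low = [f"c{i}" for i in range(100)]
        conf = post[post.confident]
        pred_low = conf.p_low > 0.5
        truth = conf.index.isin(truth_low)
        assert (pred_low == truth).mean() >= 0.95

    def test_responsibilities_sum_to_one(self, separated_fit):
        post = posterior_scna(separated_fit)
        assert np.allclose(post.p_low + post.p_high, 1.0, atol=1e-9)


class TestCalibrationAndPower:
    def test_null_pass_rate_at_most_two_percent(self, genome):
        """200 regions with no copy-number effect: joint filter keeps <= 2%."""
        rng = np.random.default_rng(17)
        fits = []
        for i in range(200):
            x = rng.normal(0, 0.25, 250)
            fits.append(
                fit_region_mixture(
                    pd.Series(x, index=[f"c{j}" for j in range(250)]),
                    region=("chr1", i, i + 1),
                    n_genes_expressed=25,
                    seed=i,
                )
            )
        kc.filter_and_adjust(fits)
        assert np.mean([f.passed for f in fits]) <= 0.02

    def test_power_on_het_deletion_regions(self, genome):
        """30% of cells with a heterozygous deletion over a 30-gene region."""
        passed = []
        for rep in range(10):
            ev = RearrangementEvent("chr1", 10_000_000, 30_000_000, "H1", "DEL")
            tree = CloneTree(
                [Clone("A", None, [], 0.7), Clone("B", "A", [ev], 0.3)],
                "linear", genome,
            )
            e = kc.simulate_expression_cells(
                tree, genome, kc.SimConfig(seed=100 + rep, n_expr_cells=500)
            )
            expr = kc.normalize_expression(e)
            region = ("chr1", 10_000_000, 30_000_000)
            scores = kc.region_scores(region, expr)
            n_genes = int(
                expr.expressed.loc[
                    expr.genes.gene_id[
                        (expr.genes.chrom == "chr1")
                        & (expr.genes.start < 30_000_000)
                        & (expr.genes.end > 10_000_000)
                    ]
                ].sum()
            )
            fit = fit_region_mixture(scores, region, n_genes, seed=rep)
            kc.filter_and_adjust([fit])
            passed.append(fit.passed)
        assert np.mean(passed) >= 0.85
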