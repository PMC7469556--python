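"""Non-specific filtering and empirical-Bayes moderated t."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from adiposcan.datamodel import ExpressionMatrix
from adiposcan.diffexpr import (
    DEResult,
    DiffExprParams,
    fit_variance_prior,
    intersect_disease_genes,
    moderated_t,
    nonspecific_filter,
    select_degs,
    trigamma_inverse,
)
from adiposcan.synthetic import SimulationConfig, simulate_dataset

from conftest import two_group_matrix


class TestFilter:
    def test_zero_iqr_gene_removed(self):
        df = pd.DataFrame(
            {"s1": [8.0, 8.0], "s2": [9.0, 8.0], "s3": [7.0, 8.0]},
            index=["varies", "flat"],
        )
        params = DiffExprParams(filter_min_intensity=0.0, filter_min_fraction=0.0,
                                filter_min_iqr=0.1)
        out = nonspecific_filter(ExpressionMatrix(df), params)
        assert out.gene_ids == ["varies"]

    def test_zero_thresholds_identity(self, small_expr):
        params = DiffExprParams(filter_min_intensity=0.0, filter_min_fraction=0.0,
                                filter_min_iqr=0.0)
        assert nonspecific_filter(small_expr, params) == small_expr

    def test_planted_near_constant_genes_removed_exactly(self):
        """100 near-constant genes among 1000 are exactly the ones dropped."""
        rng = np.random.default_rng(0)
        n_s = 20
        wide = 8.0 + rng.normal(0, 1.0, size=(900, n_s))     # IQR ~ 1.35
        flat = 8.0 + rng.normal(0, 0.01, size=(100, n_s))    # IQR ~ 0.013
        x = np.vstack([wide, flat])
        genes = [f"w{i}" for i in range(900)] + [f"f{i}" for i in range(100)]
        m = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=[f"s{j}" for j in range(n_s)]))
        params = DiffExprParams(filter_min_intensity=0.0, filter_min_fraction=0.0,
                                filter_min_iqr=0.3)
        kept = nonspecific_filter(m, params).gene_ids
        assert kept == [f"w{i}" for i in range(900)]

    def test_all_removed_is_error(self, small_expr):
        params = DiffExprParams(filter_min_iqr=100.0)
        with pytest.raises(ValueError):
            nonspecific_filter(small_expr, params)


class TestModeratedT:
    def test_without_moderation_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        expr, tab = two_group_matrix(rng, n_genes=50, n_per_group=10)
        res = moderated_t(expr, tab, DiffExprParams(use_moderation=False))
        ref = stats.ttest_ind(
            expr.data[tab.cases].to_numpy(),
            expr.data[tab.controls].to_numpy(),
            axis=1,
        )
        np.testing.assert_allclose(res.table["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.table["p"], ref.pvalue, rtol=1e-10)
        assert res.d0 == 0.0

    def test_infinite_prior_df_shrinks_to_s0(self):
        """All residual variances equal => d0 = inf and s_post = s0 everywhere."""
        rng = np.random.default_rng(2)
        # construct exact equal pooled SDs by symmetric +/- patterns
        base = rng.normal(size=20)
        x = np.vstack([8.0 + base + off for off in (0.0, 0.5, 1.0)])
        expr = ExpressionMatrix(pd.DataFrame(x, index=["a", "b", "c"],
                                             columns=[f"s{i}" for i in range(20)]))
        tab = two_group_matrix(rng, n_genes=3, n_per_group=10)[1]
        tab.data.index = expr.sample_ids
        res = moderated_t(expr, tab, DiffExprParams())
        assert np.isinf(res.d0)
        np.testing.assert_allclose(res.table["s_post"] ** 2, res.s0_squared)

    def test_s_post_between_s_and_s0(self):
        rng = np.random.default_rng(3)
        expr, tab = two_group_matrix(rng, n_genes=300, n_per_group=5)
        # heteroscedastic genes so d0 is finite
        expr = ExpressionMatrix(expr.data * rng.uniform(0.2, 3.0, size=(300, 1)))
        res = moderated_t(expr, tab, DiffExprParams())
        assert np.isfinite(res.d0) and res.d0 > 0
        s2 = res.table["s"] ** 2
        s2p = res.table["s_post"] ** 2
        lo = np.minimum(s2, res.s0_squared) - 1e-12
        hi = np.maximum(s2, res.s0_squared) + 1e-12
        assert ((s2p >= lo) & (s2p <= hi)).all()

    def test_prior_recovery_from_scaled_inverse_chisq(self):
        """Moment matching recovers known (d0, s0^2) from simulated variances."""
        rng = np.random.default_rng(4)
        d0_true, s0_true, d_g = 8.0, 0.25, 58
        n = 20000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = sigma2 * rng.chisquare(d_g, size=n) / d_g
        d0, s0_2 = fit_variance_prior(s2, d_g)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0_2 == pytest.approx(s0_true, rel=0.05)

    def test_trigamma_inverse_inverts(self):
        for x in (0.01, 0.5, 3.0, 40.0):
            assert trigamma_inverse(float(special.polygamma(1, x))) == pytest.approx(x, rel=1e-6)

    def test_p_monotone_in_abs_t(self):
        rng = np.random.default_rng(5)
        expr, tab = two_group_matrix(rng, n_genes=200, n_per_group=8)
        res = moderated_t(expr, tab, DiffExprParams())
        t = res.table.sort_values("p")
        assert (np.diff(np.abs(t["t"])) <= 1e-12).all()

    def test_small_group_is_error(self):
        rng = np.random.default_rng(6)
        expr, tab = two_group_matrix(rng, n_genes=10, n_per_group=5)
        tab2 = tab.data[tab.data.index.isin(expr.sample_ids[:6])]
        from adiposcan.datamodel import SampleTable

        with pytest.raises(ValueError):
            moderated_t(expr.subset_samples(expr.sample_ids[:6]), SampleTable(tab2.iloc[:6]), DiffExprParams())


class TestSelection:
    def _result(self, pvals, genes=None, lfc=None):
        n = len(pvals)
        genes = genes or [f"g{i}" for i in range(n)]
        lfc = lfc if lfc is not None else np.ones(n)
        tab = pd.DataFrame(
            {"gene": genes, "logFC": lfc, "p": pvals, "q": pvals,
             "direction": np.where(np.asarray(lfc) >= 0, "up", "down")}
        )
        return DEResult(tab, 1.0, 1.0)

    def test_alpha_one_selects_all(self):
        res = self._result([0.2, 0.9, 1.0])
        assert len(select_degs(res, 1.0)) == 3

    def test_alpha_zero_selects_none(self):
        res = self._result([0.0, 0.2])
        assert len(select_degs(res, 0.0)) == 0

    def test_planted_de_sensitivity(self):
        """Planted delta=1, sigma=0.5, n=30/30: >=90% of DE genes at p<0.05."""
        cfg = SimulationConfig(seed=21, n_genes=1000, n_de=100, n_modules=0,
                               n_disease_genes=50, n_disease_de_up=4,
                               n_disease_de_down=4, n_outlier_patients=0)
        expr, samples, *_ , truth = simulate_dataset(cfg)
        res = moderated_t(expr, samples, DiffExprParams())
        degs = select_degs(res, 0.05)
        hit = set(degs["gene"]) & set(truth.de_genes)
        assert len(hit) / len(truth.de_genes) >= 0.9

    def test_intersect_disease_genes(self):
        res = self._result([0.01, 0.01, 0.01, 0.5],
                           genes=["a", "b", "c", "d"], lfc=[1, -1, 1, 1])
        degs = select_degs(res, 0.05)
        up, down, counts = intersect_disease_genes(degs, ["b", "c", "zz"])
        assert up == ["c"] and down == ["b"]
        assert counts == {"up": 1, "down": 1, "total": 2}
        up2, down2, c2 = intersect_disease_genes(degs, ["zz"])
        assert up2 == [] and down2 == [] and c2["total"] == 0

    def test_planted_disease_overlap_counts(self):
        """Generator plants 5 up / 3 down disease DEGs; truth readback matches."""
        cfg = SimulationConfig(seed=8, n_genes=800, n_de=60, n_modules=0,
                               n_disease_genes=40, n_disease_de_up=5,
                               n_disease_de_down=3, n_outlier_patients=0)
        expr, samples, *_ , truth = simulate_dataset(cfg)
        res = moderated_t(expr, samples, DiffExprParams())
        degs = select_degs(res, 0.05)
        # restrict to planted truth to avoid false positives in the count
        planted = degs[degs["gene"].isin(set(truth.de_genes))]
        up, down, counts = intersect_disease_genes(planted, truth.disease_genes)
        assert counts["up"] == 5 and counts["down"] == 3
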