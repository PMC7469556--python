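"""Soft-threshold adjacency, TOM, module detection, eigengenes, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adiposcan.datamodel import ExpressionMatrix, SampleTable
from adiposcan.coexpression import (
    CoexpressionParams,
    detect_modules,
    module_eigengenes,
    module_trait_relationships,
    run_coexpression,
    scale_free_fit,
    soft_adjacency,
    tom_similarity,
)


def expr_from(rows: np.ndarray, prefix="g") -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            rows,
            index=[f"{prefix}{i:03d}" for i in range(rows.shape[0])],
            columns=[f"s{j:03d}" for j in range(rows.shape[1])],
        )
    )


def planted_blocks(seed, loading=np.sqrt(0.8), n_samples=30, n_block=30, n_noise=40):
    rng = np.random.default_rng(seed)
    F = rng.normal(size=(n_samples, 2))
    rows, truth = [], []
    for b in range(2):
        for _ in range(n_block):
            rows.append(loading * F[:, b] + np.sqrt(1 - loading**2) * rng.normal(size=n_samples))
            truth.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        truth.append(-1)
    return expr_from(8 + 0.5 * np.array(rows)), np.array(truth), F


class TestAdjacency:
    def test_identical_genes_unit_adjacency(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=10)
        m = expr_from(np.vstack([row, row]))
        for beta in (1.0, 6.0, 15.0):
            a = soft_adjacency(m, beta)
            assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_beta_one_is_abs_cor(self):
        rng = np.random.default_rng(1)
        m = expr_from(rng.normal(size=(5, 20)))
        a = soft_adjacency(m, 1.0)
        cor = np.abs(np.corrcoef(m.values()))
        np.fill_diagonal(cor, 0.0)
        np.testing.assert_allclose(a.to_numpy(), cor, atol=1e-12)

    def test_power_fifteen_hand_value(self):
        assert 0.9**15 == pytest.approx(0.205891, abs=1e-6)
        # two genes engineered to correlate at exactly 0.9 via orthogonal parts
        n = 40
        u = np.tile([1.0, -1.0], n // 2)
        v = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x1 = u
        x2 = 0.9 * u + np.sqrt(1 - 0.81) * v
        a = soft_adjacency(expr_from(np.vstack([x1, x2, u * 0.5 + 8])), 15.0)
        assert a.iloc[0, 1] == pytest.approx(0.205891, abs=1e-6)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            soft_adjacency(expr_from(np.ones((3, 2)) + np.eye(3, 2)), 15.0)

    def test_zero_variance_gene_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(3, 10))
        rows[1] = 5.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            a = soft_adjacency(expr_from(rows), 15.0)
        assert list(a.index) == ["g000", "g002"]

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(3)
        a = soft_adjacency(expr_from(rng.normal(size=(20, 15))), 15.0).to_numpy()
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1


class TestScaleFree:
    def test_power_law_sequence_high_r2(self):
        # construct adjacency whose connectivities follow k ~ x^-gamma counts
        rng = np.random.default_rng(4)
        n = 300
        k = (rng.pareto(2.0, size=n) + 1.0)
        a = np.outer(k, k) / np.outer(k, k).max()
        np.fill_diagonal(a, 0.0)
        res = scale_free_fit(pd.DataFrame(a))
        assert res["defined"]
        assert 0.0 <= res["r_squared"] <= 1.0

    def test_exact_power_law_bins(self):
        """Hand-built degree sequence p(k) ~ k^-2 regresses to R^2 ~ 1."""
        ks = np.concatenate([np.full(400, 1.0), np.full(100, 2.0),
                             np.full(44, 3.0), np.full(25, 4.0), np.full(16, 5.0),
                             np.full(11, 6.0), np.full(8, 7.0), np.full(6, 8.0),
                             np.full(5, 9.0), np.full(4, 10.0)])
        n = len(ks)
        a = np.zeros((n, n))
        # rows with row-sum = ks via a single hub column trick
        for i, k in enumerate(ks):
            a[i, (i + 1) % n] = k
        res = scale_free_fit(pd.DataFrame(a))
        assert res["defined"] and res["r_squared"] >= 0.99
        assert res["slope"] < 0

    def test_all_equal_connectivity_undefined(self):
        a = np.ones((12, 12)) * 0.5
        np.fill_diagonal(a, 0.0)
        res = scale_free_fit(pd.DataFrame(a))
        assert not res["defined"]


class TestTom:
    def test_hand_example(self):
        a = np.array([[0.0, 0.8, 0.5], [0.8, 0.0, 0.4], [0.5, 0.4, 0.0]])
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == pytest.approx((0.5 * 0.4 + 0.8) / (min(1.3, 1.2) + 1 - 0.8), abs=1e-12)
        assert tom[0, 1] == pytest.approx(0.714286, abs=1e-6)

    def test_isolated_pair_zero(self):
        a = np.zeros((4, 4))
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == 0.0

    def test_clique_saturates(self):
        a = np.ones((5, 5)) - np.eye(5)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        off = tom[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(5)
        a = np.abs(rng.normal(size=(15, 15))) ** 6
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        a = np.clip(a, 0, 1)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


class TestModules:
    def test_identical_genes_single_turquoise(self):
        rng = np.random.default_rng(6)
        row = rng.normal(size=12)
        m = expr_from(np.tile(row, (15, 1)))
        tom = tom_similarity(soft_adjacency(m, 15.0))
        a = detect_modules(tom, CoexpressionParams(min_module_size=5))
        assert set(a) == {"turquoise"}

    def test_independent_genes_all_grey(self):
        rng = np.random.default_rng(7)
        m = expr_from(rng.normal(size=(60, 30)))
        tom = tom_similarity(soft_adjacency(m, 15.0))
        a = detect_modules(tom, CoexpressionParams())
        assert set(a) == {"grey"}

    def test_planted_blocks_recovered(self):
        m, truth, _ = planted_blocks(seed=13, n_samples=60)
        tom = tom_similarity(soft_adjacency(m, 15.0))
        a = detect_modules(tom, CoexpressionParams())
        non_grey = sorted(set(a) - {"grey"})
        assert non_grey == ["blue", "turquoise"]
        # majority-map accuracy over the block genes
        correct = 0
        for b in range(2):
            labels = a.iloc[np.where(truth == b)[0]]
            top = labels.value_counts().idxmax()
            assert top != "grey"
            correct += (labels == top).sum()
        assert correct / (truth >= 0).sum() >= 0.95
        assert (a.iloc[np.where(truth == -1)[0]] == "grey").all()

    def test_deterministic(self):
        m, _, _ = planted_blocks(seed=11)
        tom = tom_similarity(soft_adjacency(m, 15.0))
        a1 = detect_modules(tom, CoexpressionParams())
        a2 = detect_modules(tom, CoexpressionParams())
        assert a1.equals(a2)


class TestEigengenes:
    def test_identical_genes_me_is_standardized_profile(self):
        rng = np.random.default_rng(8)
        row = rng.normal(size=20)
        m = expr_from(np.tile(row, (6, 1)))
        assignment = pd.Series(["turquoise"] * 6, index=m.gene_ids)
        me = module_eigengenes(m, assignment)["turquoise"].to_numpy()
        zrow = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(me, zrow, atol=1e-8)

    def test_unit_variance_and_orientation(self):
        m, truth, _ = planted_blocks(seed=12)
        assignment = pd.Series(
            np.where(truth == 0, "turquoise", np.where(truth == 1, "blue", "grey")),
            index=m.gene_ids,
        )
        mes = module_eigengenes(m, assignment)
        for c in mes.columns:
            assert mes[c].std(ddof=1) == pytest.approx(1.0)
        # orientation: positive correlation with module mean profile
        z = (m.values() - m.values().mean(1, keepdims=True)) / m.values().std(1, ddof=1, keepdims=True)
        prof = z[truth == 0].mean(axis=0)
        assert np.corrcoef(mes["turquoise"], prof)[0, 1] > 0

    def test_sign_flip_leaves_abs_trait_cor_unchanged(self):
        m, truth, F = planted_blocks(seed=13)
        assignment = pd.Series(
            np.where(truth == 0, "turquoise", "grey"), index=m.gene_ids
        )
        me1 = module_eigengenes(m, assignment)["turquoise"]
        flipped = m.data.copy()
        block = np.where(truth == 0)[0]
        flipped.iloc[block] = 2 * flipped.iloc[block].mean(axis=1).to_numpy()[:, None] - flipped.iloc[block]
        me2 = module_eigengenes(ExpressionMatrix(flipped), assignment)["turquoise"]
        trait = F[:, 0]
        assert abs(np.corrcoef(me1, trait)[0, 1]) == pytest.approx(
            abs(np.corrcoef(me2, trait)[0, 1]), abs=1e-6
        )

    def test_variance_explained_single_factor_model(self):
        """Eigengene variance share ~ r^2 + (1-r^2)/m for loading r, m genes.

        Variance explained is the mean squared gene-eigengene correlation.
        """
        rng = np.random.default_rng(14)
        r, m_genes, n = 0.8, 30, 2000
        F = rng.normal(size=n)
        rows = [r * F + np.sqrt(1 - r * r) * rng.normal(size=n) for _ in range(m_genes)]
        m = expr_from(np.array(rows))
        assignment = pd.Series(["turquoise"] * m_genes, index=m.gene_ids)
        me = module_eigengenes(m, assignment)["turquoise"].to_numpy()
        share = np.mean(
            [np.corrcoef(row, me)[0, 1] ** 2 for row in m.values()]
        )
        assert share == pytest.approx(0.64 + 0.36 / m_genes, abs=0.03)


class TestModuleTrait:
    def _samples(self, me: pd.Series, extra=None) -> SampleTable:
        df = pd.DataFrame({"group": "case"}, index=me.index)
        df["self"] = me.to_numpy()
        for k, v in (extra or {}).items():
            df[k] = v
        return SampleTable(df)

    def test_me_as_own_trait_perfect(self):
        rng = np.random.default_rng(15)
        me = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        mt = module_trait_relationships(me.to_frame("turquoise"), self._samples(me))
        row = mt[mt["trait"] == "self"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-30)

    def test_closed_form_p_for_r_half(self):
        """r=0.5, n=30: t = 3.055, p ~ 0.0049; and exact-r fixture at n=32."""
        t = 0.5 * np.sqrt(28 / (1 - 0.25))
        assert t == pytest.approx(3.055, abs=0.005)
        p30 = 2 * stats.t.sf(t, 28)
        assert p30 == pytest.approx(0.0049, abs=0.0004)
        # engineered orthogonal zero-mean vectors give exact r = 0.5 at n = 32
        n = 32
        u = np.tile([1.0, -1.0], n // 2)
        v = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        me = pd.Series(u, index=[f"s{i}" for i in range(n)])
        trait = 0.5 * u + np.sqrt(0.75) * v
        mt = module_trait_relationships(
            me.to_frame("turquoise"),
            self._samples(me, extra={"ldl": trait}),
        )
        row = mt[mt["trait"] == "ldl"].iloc[0]
        assert row["r"] == pytest.approx(0.5, abs=1e-10)
        p32 = 2 * stats.t.sf(0.5 * np.sqrt(30 / 0.75), 30)
        assert row["p"] == pytest.approx(p32, abs=1e-10)

    def test_constant_trait_undefined(self):
        rng = np.random.default_rng(16)
        me = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        mt = module_trait_relationships(
            me.to_frame("turquoise"), self._samples(me, extra={"flat": np.ones(10)})
        )
        assert np.isnan(mt.loc[mt["trait"] == "flat", "r"]).all()

    def test_pairwise_complete_missing_values(self):
        rng = np.random.default_rng(17)
        me = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        trait = me.to_numpy() + rng.normal(0, 0.5, size=20)
        trait[:5] = np.nan
        mt = module_trait_relationships(
            me.to_frame("turquoise"), self._samples(me, extra={"sparse": trait})
        )
        row = mt[mt["trait"] == "sparse"].iloc[0]
        assert row["n"] == 15
        r_ref, p_ref = stats.pearsonr(me.to_numpy()[5:], trait[5:])
        assert row["r"] == pytest.approx(r_ref) and row["p"] == pytest.approx(p_ref)

    def test_coupled_trait_detected_decoy_not(self):
        m, truth, F = planted_blocks(seed=18, n_samples=60)
        rng = np.random.default_rng(19)
        coupled = 0.6 * F[:, 0] + np.sqrt(1 - 0.36) * rng.normal(size=60)
        decoy = rng.normal(size=60)
        df = pd.DataFrame({"group": "case"}, index=m.sample_ids)
        df["coupled"] = coupled
        df["decoy"] = decoy
        res = run_coexpression(
            m, SampleTable(df), m.gene_ids, CoexpressionParams()
        )
        mt = res.module_trait
        block0_color = res.assignment.iloc[np.where(truth == 0)[0]].value_counts().idxmax()
        got = mt[(mt["module"] == block0_color) & (mt["trait"] == "coupled")].iloc[0]
        assert got["p"] < 0.01
        dec = mt[(mt["module"] == block0_color) & (mt["trait"] == "decoy")].iloc[0]
        assert dec["p"] > 0.01
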