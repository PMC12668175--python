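import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from arousalnet.gene_association import (
    CHOLINERGIC_PANEL,
    GeneExpressionMatrix,
    normalize_expression,
    pca_expression,
    rank_components,
    select_k,
    spin_permutation,
    spin_rotation_permutation,
    SpinTestResult,
    williams_hotelling,
)
from arousalnet.synthetic_cohort import generate_gene_maps


def raw_matrix(rng, n_regions=60, n_genes=6):
    vals = rng.standard_normal((n_regions, n_genes)) * 3 + 10
    return GeneExpressionMatrix(
        vals, [f"G{i}" for i in range(n_genes)],
        [f"ctx_{i:03d}" for i in range(n_regions)], state="raw")


def williams_reference(r12, r13, r23, n):
    """Williams' statistic assembled independently via the determinant of
    the full 3x3 correlation matrix."""
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, 1 * r23, 1.0]])
    R[2, 1] = r23
    detR = np.linalg.det(R)
    rbar = (r12 + r13) / 2
    num = (r12 - r13) * np.sqrt((n - 1) * (1 + r23))
    den = np.sqrt(2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3)
    return num / den


class TestNormalization:
    def test_median_maps_to_sigmoid_center(self, rng):
        raw = raw_matrix(rng)
        x = raw.values[:, 0]
        med, iqr = np.median(x), np.subtract(*np.percentile(x, [75, 25]))
        s = expit((x - med) / (iqr / 1.35))
        at_median = np.argmin(np.abs(x - med))
        # odd region counts put one sample exactly at the median
        if x[at_median] == med:
            assert s[at_median] == pytest.approx(0.5)
        # the normalised output preserves the sigmoid's ordering
        out = normalize_expression(raw)
        assert stats.spearmanr(x, out.values[:, 0]).statistic == pytest.approx(1.0)

    def test_rank_order_preserved(self, rng):
        raw = raw_matrix(rng)
        out = normalize_expression(raw)
        for g in range(raw.n_genes):
            np.testing.assert_array_equal(
                np.argsort(raw.values[:, g]), np.argsort(out.values[:, g]))

    def test_outlier_compressed_relative_to_raw_zscore(self, rng):
        raw = raw_matrix(rng, n_regions=101, n_genes=1)
        x = raw.values[:, 0]
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        x[0] = np.median(x) + 10 * iqr
        raw2 = GeneExpressionMatrix(x[:, None], ["G0"], raw.region_labels,
                                    state="raw")
        out = normalize_expression(raw2)
        raw_z = (x[0] - x.mean()) / x.std()
        assert abs(out.values[0, 0]) < abs(raw_z)

    def test_columns_zscored(self, rng):
        out = normalize_expression(raw_matrix(rng))
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-8)
        assert out.state == "zscored"

    def test_zero_iqr_names_gene(self, rng):
        raw = raw_matrix(rng)
        raw.values[:, 2] = np.where(np.arange(60) == 0, 9.0, 5.0)
        with pytest.raises(ValueError, match="G2"):
            normalize_expression(raw)


class TestPCA:
    def test_eigenvalue_sum_equals_gene_count(self, rng):
        z = normalize_expression(raw_matrix(rng, n_regions=80, n_genes=7))
        comps = pca_expression(z)
        assert comps.eigenvalues.sum() == pytest.approx(7.0, abs=1e-8)

    def test_cumulative_threshold_rule(self):
        assert select_k(np.array([0.5, 0.25, 0.15, 0.10]), 0.8) == 3
        assert select_k(np.array([0.9, 0.1]), 0.8) == 1
        assert select_k(np.array([0.5, 0.3, 0.2]), 1.0) == 3

    def test_rank_one_structure_recovered(self, rng):
        # equal-magnitude loadings keep column variances equal, so the
        # per-column standardisation does not distort the planted vector
        planted = rng.choice([-1.0, 1.0], 10) / np.sqrt(10)
        scores = rng.standard_normal(300)
        X = np.outer(scores, planted) + 0.02 * rng.standard_normal((300, 10))
        Z = (X - X.mean(0)) / X.std(0)
        mat = GeneExpressionMatrix(Z, [f"G{i}" for i in range(10)],
                                   [f"r{i}" for i in range(300)],
                                   state="zscored")
        comps = pca_expression(mat)
        assert comps.explained_ratio[0] >= 0.90
        r = np.corrcoef(comps.loadings[:, 0], planted)[0, 1]
        assert abs(r) >= 0.99

    def test_variance_bookkeeping(self, rng):
        z = normalize_expression(raw_matrix(rng, n_regions=90, n_genes=8))
        comps = pca_expression(z, var_threshold=0.8)
        resid = z.values - comps.scores @ comps.loadings.T
        discarded = comps.eigenvalues[comps.k:].sum()
        assert (resid**2).sum() / z.n_regions == pytest.approx(
            discarded, abs=1e-8)

    def test_sign_convention(self, rng):
        z = normalize_expression(raw_matrix(rng, n_regions=70, n_genes=5))
        comps = pca_expression(z)
        for j in range(comps.k):
            v = comps.loadings[:, j]
            assert v[np.argmax(np.abs(v))] > 0

    def test_invalid_threshold_rejected(self, rng):
        z = normalize_expression(raw_matrix(rng))
        with pytest.raises(ValueError):
            pca_expression(z, var_threshold=1.5)

    def test_planted_gradient_separates_genes(self, rng, geometry_100):
        genes = generate_gene_maps(
            100, 24, 0.5, {"gene_indices": list(range(8)), "weight": 2.0},
            geometry_100, seed=5)
        comps = pca_expression(normalize_expression(genes))
        lead = np.abs(comps.loadings[:, 0])
        assert lead[:8].min() > lead[8:].max()


class TestSpin:
    def test_rotation_induces_bijection(self, geometry_100, rng):
        from scipy.stats import special_ortho_group

        for _ in range(5):
            R = special_ortho_group.rvs(3, random_state=rng)
            perm = spin_rotation_permutation(geometry_100, R)
            assert np.array_equal(np.sort(perm), np.arange(100))
            # hemispheres never mix
            for h in ("L", "R"):
                idx = geometry_100.hemisphere_indices(h)
                assert set(perm[idx]) == set(idx)

    def test_self_correlation_minimal_p(self, geometry_100, rng):
        a = rng.standard_normal(100)
        res = spin_permutation(a, a, geometry_100, n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_spin == pytest.approx(1 / 100)

    def test_geometry_size_mismatch_rejected(self, geometry_100, rng):
        with pytest.raises(ValueError, match="cover"):
            spin_permutation(rng.standard_normal(50),
                             rng.standard_normal(50), geometry_100, n_perm=9)

    def test_spearman_default_matches_scipy(self, geometry_100, rng):
        a, b = rng.standard_normal((2, 100))
        res = spin_permutation(a, b, geometry_100, n_perm=19, seed=0)
        assert res.observed == pytest.approx(
            stats.spearmanr(a, b).statistic, abs=1e-12)

    def test_seeded_determinism(self, geometry_100, rng):
        a, b = rng.standard_normal((2, 100))
        r1 = spin_permutation(a, b, geometry_100, n_perm=49, seed=3)
        r2 = spin_permutation(a, b, geometry_100, n_perm=49, seed=3)
        assert r1.p_spin == r2.p_spin
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)


class TestWilliamsHotelling:
    def test_equal_correlations_give_zero(self):
        T, p, df = williams_hotelling(0.4, 0.4, 0.2, 50)
        assert T == 0.0 and p == 1.0 and df == 47

    def test_reference_fixture(self):
        T, p, df = williams_hotelling(0.5, 0.3, 0.4, 100)
        assert df == 97
        assert T == pytest.approx(williams_reference(0.5, 0.3, 0.4, 100),
                                  abs=1e-6)
        assert T == pytest.approx(2.0650, abs=5e-4)

    def test_antisymmetry(self):
        T1, _, _ = williams_hotelling(0.6, 0.2, 0.3, 80)
        T2, _, _ = williams_hotelling(0.2, 0.6, 0.3, 80)
        assert T1 == pytest.approx(-T2, abs=1e-12)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="non-PSD"):
            williams_hotelling(0.9, -0.9, 0.9, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            williams_hotelling(0.5, 0.3, 0.4, 4)


class TestRanking:
    def make_results(self, rvals, n_perm=99):
        return [SpinTestResult(observed=r, p_spin=(i + 1) / 100,
                               n_perm=n_perm, method="spearman",
                               null_sample=np.zeros(n_perm))
                for i, r in enumerate(rvals)]

    def test_eight_components_yield_28_pairs(self, rng):
        scores = rng.standard_normal((100, 8))
        comp, pairs = rank_components(self.make_results([0.5] * 8), n=100,
                                      scores=scores)
        assert len(pairs) == 28

    def test_ranking_and_effect_classes(self, rng):
        scores = rng.standard_normal((100, 3))
        comp, _ = rank_components(self.make_results([0.9, 0.1, 0.05]),
                                  n=100, scores=scores)
        assert comp["rank"].tolist() == [1, 2, 3]
        assert comp["effect_size"].tolist() == ["large", "small", "negligible"]

    def test_duplicated_component_pairwise_t_zero(self, rng):
        base = rng.standard_normal(100)
        scores = np.column_stack([base, base])
        comp, pairs = rank_components(self.make_results([0.42, 0.42]),
                                      n=100, scores=scores)
        assert pairs["T"].iloc[0] == 0.0

    def test_panel_has_24_symbols(self):
        assert len(CHOLINERGIC_PANEL) == 24
        assert len(set(CHOLINERGIC_PANEL)) == 24
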