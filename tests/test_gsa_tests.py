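"""Test statistics and permutation engine: algebraic oracles and invariances."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lctgsa import (
    GeneSetData,
    Phenotype,
    center_columns,
    globaltest_statistic,
    lct2_statistic,
    lct_statistic,
    permutation_indices,
    permutation_pvalue,
    samgs_statistic,
    shrink_covariance,
)
from lctgsa import test_gene_set as run_set_test

METHODS = ("LCT", "LCT2", "SAMGS", "GLOBAL")


def random_case(seed, n=10, p=4):
    g = np.random.default_rng(seed)
    X = g.standard_normal((n, p))
    y = Phenotype(g.standard_normal(n))
    return X, y


class TestLct:
    def test_zero_when_phenotype_orthogonal_to_basis(self, centered_10x4):
        fit = shrink_covariance(centered_10x4)
        data = GeneSetData(centered_10x4.values)
        V = data.V
        y = np.random.default_rng(1).standard_normal(10)
        yc = y - y.mean()
        # project out every column of V (and the constant) -> all covariances 0
        yc -= V @ np.linalg.lstsq(V, yc, rcond=None)[0]
        assert lct_statistic(Phenotype(yc), V) == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_inverse_covariance_quadratic_form(self, seed):
        X, y = random_case(seed, n=12, p=6)
        data = GeneSetData(X)
        n = 12
        cv = data.xc.values.T @ y.centered / (n - 1)
        qf = cv @ np.linalg.solve(data.fit.omega_star, cv)
        assert lct_statistic(y, data.V) == pytest.approx(qf, rel=1e-8)

    def test_invariant_to_single_gene_rescaling(self):
        X, y = random_case(11, n=10, p=5)
        base = lct_statistic(y, GeneSetData(X).V)
        X2 = X.copy()
        X2[:, 2] *= -17.5
        assert lct_statistic(y, GeneSetData(X2).V) == pytest.approx(base, rel=1e-8)

    def test_length_mismatch_rejected(self):
        X, y = random_case(0)
        with pytest.raises(ValueError, match="does not match"):
            lct_statistic(Phenotype(np.arange(7.0)), GeneSetData(X).V)


class TestLct2:
    def test_zero_when_phenotype_uncorrelated_with_genes(self, centered_10x4):
        fit = shrink_covariance(centered_10x4)
        Xc = centered_10x4
        y = np.random.default_rng(2).standard_normal(10)
        yc = y - y.mean()
        yc -= Xc.values @ np.linalg.lstsq(Xc.values, yc, rcond=None)[0]
        assert lct2_statistic(Phenotype(yc), Xc, fit) == pytest.approx(0.0, abs=1e-18)

    def test_reduces_to_ols_fitted_norm(self):
        # lambda* forced to 0 with n > p and full rank: f is the OLS fit
        g = np.random.default_rng(5)
        X = g.standard_normal((20, 3))
        y = Phenotype(g.standard_normal(20))
        xc = center_columns(X, genes_in_rows=False)
        fit = shrink_covariance(xc, lambda_star=0.0)
        beta, *_ = np.linalg.lstsq(xc.values, y.centered, rcond=None)
        fitted = xc.values @ beta
        assert lct2_statistic(y, xc, fit) == pytest.approx(float(fitted @ fitted), rel=1e-8)

    def test_matches_dense_inverse(self, centered_10x4, frozen_phenotype):
        fit = shrink_covariance(centered_10x4)
        n = 10
        Xc = centered_10x4.values
        f = Xc @ np.linalg.inv((n - 1) * fit.omega_star) @ Xc.T @ frozen_phenotype.centered
        assert lct2_statistic(frozen_phenotype, centered_10x4, fit) == pytest.approx(
            float(f @ f), rel=1e-8
        )


class TestSamgs:
    def test_single_gene_equals_squared_t(self):
        g = np.random.default_rng(9)
        x = g.standard_normal(15)
        y = 0.7 * x + g.standard_normal(15)
        xc = center_columns(x[:, None], genes_in_rows=False)
        fit = stats.linregress(x, y)
        t = fit.slope / fit.stderr
        assert samgs_statistic(Phenotype(y), xc) == pytest.approx(t**2, rel=1e-10)

    def test_additive_over_genes(self):
        X, y = random_case(3, n=12, p=2)
        both = samgs_statistic(y, center_columns(X, genes_in_rows=False))
        g1 = samgs_statistic(y, center_columns(X[:, :1], genes_in_rows=False))
        g2 = samgs_statistic(y, center_columns(X[:, 1:], genes_in_rows=False))
        assert both == pytest.approx(g1 + g2, rel=1e-10)

    def test_orthogonal_phenotype_gives_zero(self):
        X = np.random.default_rng(4).standard_normal((8, 3))
        xc = center_columns(X, genes_in_rows=False)
        y = np.random.default_rng(5).standard_normal(8)
        yc = y - y.mean()
        yc -= xc.values @ np.linalg.lstsq(xc.values, yc, rcond=None)[0]
        assert samgs_statistic(Phenotype(yc), xc) == pytest.approx(0.0, abs=1e-20)

    def test_collinear_gene_rejected(self):
        g = np.random.default_rng(6)
        y = g.standard_normal(10)
        X = np.column_stack([g.standard_normal(10), 2.0 * y + 1.0])
        with pytest.raises(ValueError, match="degenerate regression"):
            samgs_statistic(Phenotype(y), center_columns(X, genes_in_rows=False))


class TestGlobalTest:
    def test_constant_phenotype_gives_zero(self, centered_10x4):
        assert globaltest_statistic(Phenotype(np.full(10, 3.3)), centered_10x4) == 0.0

    def test_equals_expanded_sum(self, centered_10x4, frozen_phenotype):
        p = centered_10x4.p_genes
        expected = (
            sum(
                float(centered_10x4.values[:, h] @ frozen_phenotype.centered) ** 2
                for h in range(p)
            )
            / p
        )
        assert globaltest_statistic(frozen_phenotype, centered_10x4) == pytest.approx(
            expected, rel=1e-12
        )

    def test_hand_computed_single_active_gene(self):
        # Y equals the only non-null gene's centered expression: Q = (sum x^2)^2 / p
        x = np.array([1.0, -1.0, 2.0, -2.0])
        X = np.column_stack([x, np.zeros(4), np.zeros(4)])
        xc = center_columns(X, genes_in_rows=False)
        q = globaltest_statistic(Phenotype(x), xc)
        assert q == pytest.approx((1 + 1 + 4 + 4) ** 2 / 3)


class TestPermutationPvalue:
    def test_constant_phenotype_p_is_one(self):
        X = np.random.default_rng(0).standard_normal((8, 3))
        res = run_set_test(X, np.full(8, 2.0), B=99, seed=4)
        assert all(r.p_value == 1.0 for r in res.values())

    def test_extreme_observed_p_is_minimal(self):
        # sorted-ascending dot product is uniquely maximised by the identity
        # arrangement (rearrangement inequality), so observed > all permuted
        y = Phenotype(np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0]))
        w = np.arange(8.0)

        def stat(ph):
            return float(ph.values @ w)

        res = permutation_pvalue(stat, y, B=50, seed=12)
        assert res.p_value == pytest.approx(1 / 51)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        n = 5
        g = np.random.default_rng(8)
        X = g.standard_normal((n, 3))
        y = Phenotype(g.standard_normal(n))
        data = GeneSetData(X)
        obs = data.statistic(y, "LCT")
        exceed = sum(
            data.statistic(Phenotype(y.values[list(perm)]), "LCT") >= obs
            for perm in itertools.permutations(range(n))
        )
        exact = exceed / 120
        mc = run_set_test(Y=y, data=data, methods=("LCT",), B=10_000, seed=3)["LCT"]
        assert abs(mc.p_value - exact) < 0.02

    def test_pvalues_invariant_under_affine_phenotype_transform(self):
        X, y = random_case(21, n=12, p=6)
        y2 = Phenotype(3.0 * y.values + 7.0)
        r1 = run_set_test(X, y, methods=METHODS, B=200, seed=77)
        r2 = run_set_test(X, y2, methods=METHODS, B=200, seed=77)
        for m in METHODS:
            assert r1[m].p_value == r2[m].p_value

    def test_lct_pvalues_invariant_to_gene_reordering(self):
        X, y = random_case(22, n=10, p=7)
        perm = np.random.default_rng(1).permutation(7)
        r1 = run_set_test(X, y, methods=("LCT", "LCT2"), B=200, seed=5)
        r2 = run_set_test(X[:, perm], y, methods=("LCT", "LCT2"), B=200, seed=5)
        for m in ("LCT", "LCT2"):
            assert r1[m].statistic == pytest.approx(r2[m].statistic, rel=1e-9)
            assert r1[m].p_value == r2[m].p_value

    def test_rejects_zero_permutations(self):
        X, y = random_case(1)
        with pytest.raises(ValueError, match="at least one permutation"):
            run_set_test(X, y, B=0, seed=0)

    def test_pvalues_on_add_one_grid(self):
        X, y = random_case(30, n=9, p=5)
        B = 37
        res = run_set_test(X, y, B=B, seed=9)
        for r in res.values():
            k = round(r.p_value * (B + 1))
            assert r.p_value == pytest.approx(k / (B + 1)) and 1 <= k <= B + 1


class TestBatchConsistency:
    def test_batch_rows_equal_scalar_statistics(self):
        X, y = random_case(40, n=11, p=8)
        data = GeneSetData(X)
        idx = permutation_indices(11, 25, seed=2)
        Yc = y.centered[idx]
        batch = data.batch_statistics(Yc, METHODS)
        for m in METHODS:
            for b in range(25):
                assert batch[m][b] == pytest.approx(
                    data.statistic(Phenotype(y.values[idx[b]]), m), rel=1e-10
                )


def test_null_pvalues_are_uniform_for_all_methods():
    """Under Y independent of X each permutation p-value is ~Uniform(0,1)."""
    from lctgsa import SimulationScenario, simulate_dataset

    sc = SimulationScenario(n=10, p=20, p1=5, p2=5, rho=0.6, n_replicates=300,
                            n_permutations=100, seed=424242)
    pvals = {m: [] for m in METHODS}
    for rep in range(300):
        X, Y = simulate_dataset(sc, rep)
        res = run_set_test(X, Y, methods=METHODS, B=100, seed=rep)
        for m in METHODS:
            pvals[m].append(res[m].p_value)
    for m in METHODS:
        ks = stats.kstest(pvals[m], "uniform")
        assert ks.pvalue > 0.005, f"{m} null p-values non-uniform (KS p={ks.pvalue:.4g})"
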