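import numpy as np
import pytest
from scipy.stats import norm

from jointfa.factor_analysis import (
    kaiser_count,
    principal_axes_fa,
    promax_rotate,
    regression_scores,
    rotate_model,
    sample_correlation,
    select_factor_genes,
    smc_communalities,
    varimax,
)
from jointfa.io import ExpressionMatrix

from conftest import run_pipeline


def expr(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        row_ids=[f"g{i}" for i in range(n)],
        row_kinds=["mRNA"] * n,
        sample_ids=sample_ids or [f"s{j}" for j in range(m)],
        values=values,
        scales={"mRNA": "log2"},
    )


# tetrad-consistent single-factor correlation matrix: r_jk = lambda_j lambda_k
R_TETRAD = np.array([
    [1.00, 0.72, 0.63],
    [0.72, 1.00, 0.56],
    [0.63, 0.56, 1.00],
])


class TestSampleCorrelation:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 100)
        r = sample_correlation(expr(np.column_stack([col, col])))
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_sample(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 100)
        r = sample_correlation(expr(np.column_stack([col, -col])))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_single_factor_population_values(self):
        # y_j = lambda_j f + noise, population corr = lambda_j lambda_k
        rng = np.random.default_rng(42)
        lam = np.array([0.9, 0.8, 0.7])
        f = rng.normal(0, 1, 10_000)
        noise = rng.normal(0, 1, (10_000, 3)) * np.sqrt(1 - lam**2)
        r = sample_correlation(expr(f[:, None] * lam + noise))
        assert r[0, 1] == pytest.approx(0.72, abs=0.02)
        assert r[0, 2] == pytest.approx(0.63, abs=0.02)
        assert r[1, 2] == pytest.approx(0.56, abs=0.02)

    def test_constant_sample_rejected(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            sample_correlation(expr(vals))

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            sample_correlation(expr(np.ones((2, 3)) + np.arange(3)))


class TestPrincipalAxes:
    def test_tetrad_closed_form(self):
        model = principal_axes_fa(R_TETRAD, 1)
        np.testing.assert_allclose(
            np.abs(model.loadings.ravel()), [0.9, 0.8, 0.7], atol=1e-4
        )
        assert model.converged

    def test_identity_correlation(self):
        model = principal_axes_fa(np.eye(4), 1)
        assert np.all(model.communalities < 1e-3)
        assert np.all(np.abs(model.loadings) < 0.05)

    def test_exact_two_factor_reproduction(self):
        # planted 6x2 loadings, R = LL^T off-diagonal (unit diagonal)
        rng = np.random.default_rng(3)
        lam = rng.uniform(-0.8, 0.8, (6, 2))
        h = np.sum(lam**2, axis=1)
        lam *= np.sqrt(np.minimum(1.0, 0.9 / h))[:, None]
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        model = principal_axes_fa(r, 2, tol=1e-10, max_iter=500)
        fit = model.loadings @ model.loadings.T
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(fit[off], r[off], atol=1e-6)

    def test_monotone_offdiagonal_residual(self):
        # final off-diagonal residual never exceeds the first-iteration one
        rng = np.random.default_rng(9)
        off = ~np.eye(6, dtype=bool)
        for trial in range(10):
            lam = rng.uniform(-0.7, 0.7, (6, 2))
            r = lam @ lam.T + np.diag(rng.uniform(0.05, 0.3, 6))
            d = np.sqrt(np.diag(r))
            r = r / np.outer(d, d)
            first = principal_axes_fa(r, 2, max_iter=1)
            final = principal_axes_fa(r, 2, max_iter=200)
            res_first = np.linalg.norm((r - first.loadings @ first.loadings.T)[off])
            res_final = np.linalg.norm((r - final.loadings @ final.loadings.T)[off])
            assert res_final <= res_first + 1e-12

    def test_communality_uniqueness_partition(self):
        model = principal_axes_fa(R_TETRAD, 1)
        np.testing.assert_allclose(model.communalities + model.uniqueness, 1.0)
        assert np.all((model.communalities >= 0) & (model.communalities <= 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="factor count"):
            principal_axes_fa(R_TETRAD, 3)
        with pytest.raises(ValueError, match="unit diagonal"):
            principal_axes_fa(R_TETRAD * 2, 1)

    def test_non_convergence_warns(self):
        with pytest.warns(UserWarning, match="converge"):
            model = principal_axes_fa(R_TETRAD, 1, tol=0.0, max_iter=3)
        assert not model.converged

    def test_smc_singular_fallback(self):
        r = np.ones((3, 3))
        with pytest.warns(UserWarning, match="singular"):
            h = smc_communalities(r)
        assert h.shape == (3,)


class TestKaiser:
    def test_example(self):
        assert kaiser_count(np.array([3.2, 1.5, 0.9, 0.4])) == 2

    def test_none_above_threshold(self):
        assert kaiser_count(np.array([1.0, 0.8, 0.2])) == 0

    def test_strict_inequality_at_threshold(self):
        assert kaiser_count(np.array([1.0]), t=1.0) == 0

    def test_requires_descending(self):
        with pytest.raises(ValueError, match="descending"):
            kaiser_count(np.array([0.5, 2.0]))


class TestRotation:
    def test_single_factor_identity(self):
        lam = np.arange(5, dtype=float)[:, None]
        rotated, phi = promax_rotate(lam)
        np.testing.assert_array_equal(rotated, lam)
        np.testing.assert_array_equal(phi, [[1.0]])

    def test_planted_simple_structure_recovered(self):
        # each sample loads on exactly one factor
        pattern = np.zeros((9, 3))
        for i in range(9):
            pattern[i, i % 3] = [0.9, 0.8, 0.7][i % 3]
        mixing = np.linalg.qr(np.random.default_rng(5).normal(size=(3, 3)))[0]
        rotated, phi = promax_rotate(pattern @ mixing)
        # match columns up to permutation/sign
        congr = np.abs(rotated.T @ pattern) / (
            np.linalg.norm(rotated, axis=0)[:, None]
            * np.linalg.norm(pattern, axis=0)[None, :]
        )
        best = congr.max(axis=0)
        assert np.all(best > 0.99)
        np.testing.assert_allclose(phi, np.eye(3), atol=0.05)

    def test_span_preserved(self):
        rng = np.random.default_rng(8)
        lam = rng.normal(0, 0.5, (10, 3))
        rotated, _ = promax_rotate(lam)
        q, _ = np.linalg.qr(lam)
        resid = rotated - q @ (q.T @ rotated)
        assert np.linalg.norm(resid) < 1e-8

    def test_varimax_orthogonal(self):
        rng = np.random.default_rng(8)
        lam = rng.normal(0, 0.5, (10, 3))
        _, rot = varimax(lam)
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-10)

    def test_rank_deficient_rejected(self):
        lam = np.ones((5, 2))
        with pytest.raises(ValueError, match="rank"):
            promax_rotate(lam)

    def test_factor_correlation_invariants(self, default_result):
        phi = default_result.model.factor_correlation
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(phi)) > -1e-10


class TestRegressionScores:
    def _planted(self, seed=11, noise=0.2):
        # moderate noise keeps R comfortably non-singular; at (near) zero
        # noise R is rank-deficient and the regression weights degrade
        rng = np.random.default_rng(seed)
        m, l, n = 10, 2, 4000
        loadings = np.zeros((m, l))
        loadings[:5, 0] = np.linspace(0.6, 0.9, 5)
        loadings[5:, 1] = np.linspace(0.5, 0.8, 5)
        scores = rng.normal(0, 1, (l, n))
        data = (loadings @ scores + rng.normal(0, noise, (m, n))).T
        return expr(data), loadings, scores

    def test_recovers_planted_scores(self):
        joint, loadings, scores = self._planted()
        r = sample_correlation(joint)
        model = principal_axes_fa(r, 2, sample_ids=joint.sample_ids)
        model = rotate_model(model, "promax")
        est = regression_scores(joint, model, r)
        # match factors by |corr| and check recovery
        for f in range(2):
            cors = [abs(np.corrcoef(est[j], scores[f])[0, 1]) for j in range(2)]
            assert max(cors) > 0.99

    def test_scores_centered(self, default_result):
        means = default_result.model.scores.mean(axis=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-8)

    def test_paper_scale_score_sd_range(self, default_result):
        sds = default_result.model.scores.std(axis=1)
        assert np.all(sds >= 0.5) and np.all(sds <= 1.0)

    def test_sample_mismatch_rejected(self):
        joint, _, _ = self._planted()
        r = sample_correlation(joint)
        model = principal_axes_fa(r, 2)
        bad = expr(joint.values[:, :5])
        with pytest.raises(ValueError, match="samples"):
            regression_scores(bad, model)


class TestSelectFactorGenes:
    def test_outlier_pair(self):
        scores = np.array([[0, 0, 0, 5, -5, 0, 0, 0, 0, 0]], dtype=float)
        ids = [f"gene{i}" for i in range(1, 11)]
        (fs,) = select_factor_genes(scores, ids)
        assert set(fs.positive_set) == {"gene4"}
        assert set(fs.negative_set) == {"gene5"}
        assert fs.selected_ids == {"gene4", "gene5"}

    def test_constant_scores_empty(self):
        with pytest.warns(UserWarning, match="zero score variance"):
            (fs,) = select_factor_genes(np.ones((1, 5)), list("abcde"))
        assert not fs.positive_set and not fs.negative_set

    def test_gaussian_selected_fraction(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, (1, 10_000))
        (fs,) = select_factor_genes(scores, [str(i) for i in range(10_000)])
        frac = len(fs.selected_ids) / 10_000
        assert frac == pytest.approx(2 * norm.cdf(-2), abs=0.005)

    def test_sets_disjoint_and_outside_band(self, default_result):
        for fs in default_result.gene_sets:
            assert not (set(fs.positive_set) & set(fs.negative_set))
            for s in fs.positive_set.values():
                assert s > fs.score_mean + 2 * fs.score_sd
            for s in fs.negative_set.values():
                assert s < fs.score_mean - 2 * fs.score_sd


class TestPipelineRecoveryProperty:
    def test_low_rank_reproduction_through_pipeline(self, default_dataset):
        result = run_pipeline(default_dataset)
        model = result.model
        assert model.n_factors == 3
        assert model.loadings.shape == (12, 3)
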