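import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import svca
from svca import kernels as k
from svca.model import SVCAParameters, log_marginal_likelihood
from svca.preprocess import standardize_columns

from conftest import make_sim_image


def build_random_terms(rng, n, l=0.5):
    x = standardize_columns(rng.normal(size=(n, 6)))
    pos = rng.uniform(0, 2, (n, 2))
    d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return k.build_terms(x, d, l)


class TestLogMarginalLikelihood:
    def test_identity_covariance_equals_iid_normal_density(self, rng):
        y = rng.normal(size=40)
        terms = {"noise": k.noise_covariance(40)}
        params = SVCAParameters(sigma2_noise=1.0)
        ours = log_marginal_likelihood(params, terms, y)
        # identity + jitter: compare against iid normal density at that variance
        expected = norm.logpdf(y, scale=np.sqrt(1.0 + 1e-6)).sum()
        assert ours == pytest.approx(expected, abs=1e-8)

    def test_matches_explicit_multivariate_normal(self, rng):
        n = 50
        terms = build_random_terms(rng, n)
        params = SVCAParameters(0.4, 0.3, 0.2, 0.5, 0.5)
        y = rng.normal(size=n)
        cov = sum(params.scale(name) * t.matrix for name, t in terms.items())
        jitter = 1e-6 * max(np.trace(cov) / n, 1.0)
        expected = multivariate_normal.logpdf(y, np.zeros(n), cov + jitter * np.eye(n))
        assert log_marginal_likelihood(params, terms, y) == pytest.approx(expected, abs=1e-8)


class TestFit:
    def test_pure_noise_yields_noise_dominated_signature(self):
        base = svca.synthesize_image(100, 10, seed=42)
        proc = svca.preprocess_counts(base.expression)
        fracs = []
        for seed in range(20):
            expr = proc.copy()
            expr[:, 0] = np.random.default_rng(seed).normal(size=100)
            img = svca.SpatialExpressionImage(
                "noise", base.positions, expr, base.gene_names
            )
            m = svca.fit(img, "g00", n_restarts=1, seed=seed)
            fracs.append(svca.variance_signature(m).noise)
        assert np.median(fracs) > 0.9

    def test_environmental_length_scale_recovered(self, processed_image):
        d = svca.pairwise_distances(processed_image)
        grid = svca.default_length_grid(processed_image, 4)
        l0 = grid[1]
        kenv = np.exp(-(d**2) / (2 * l0**2))
        chol = np.linalg.cholesky(kenv + 1e-8 * np.eye(processed_image.n_cells))
        hits = 0
        n_seeds = 7
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = chol @ rng.normal(size=processed_image.n_cells)
            y = y + 0.2 * rng.normal(size=processed_image.n_cells)
            img = make_sim_image(processed_image, y)
            m = svca.fit(img, "target", grid=grid, components=("environmental",), seed=seed)
            hits += m.parameters.length_scale == pytest.approx(l0)
        assert hits > n_seeds / 2

    def test_permuted_target_does_not_beat_structured_fit(self, processed_image):
        terms, scales = __import__("svca").simulate.base_terms_for_image(
            processed_image, "g00"
        )
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            y = svca.simulate_from_generative(terms, scales, 0.5, seed=seed)
            img = make_sim_image(processed_image, y)
            m = svca.fit(img, "target", n_restarts=1, seed=seed)
            rng = np.random.default_rng(seed + 1000)
            y_perm = rng.permutation(y)
            img_p = make_sim_image(processed_image, y_perm)
            m_p = svca.fit(img_p, "target", n_restarts=1, seed=seed)
            wins += m_p.log_marginal_likelihood <= m.log_marginal_likelihood
        assert wins > n_seeds / 2

    def test_too_few_cells_rejected(self):
        img = svca.SpatialExpressionImage(
            "tiny", np.random.default_rng(0).uniform(0, 1, (5, 2)),
            np.random.default_rng(1).uniform(1, 2, (5, 3)), ["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="at least 10 cells"):
            svca.fit(img, "a")

    def test_full_model_likelihood_dominates_nested_reduced(self, processed_image):
        grid = svca.default_length_grid(processed_image, 4)
        full = svca.fit(processed_image, "g01", grid=grid, n_restarts=2, seed=0)
        for comps in [("intrinsic",), ("intrinsic", "cell_cell"),
                      ("intrinsic", "environmental")]:
            red = svca.fit(processed_image, "g01", grid=grid, components=comps,
                           n_restarts=2, seed=0)
            assert full.log_marginal_likelihood >= red.log_marginal_likelihood - 1e-3


class TestVarianceSignature:
    def test_equal_scales_on_unit_gower_terms_give_quarters(self, rng):
        terms = build_random_terms(rng, 30)
        m = svca.FittedModel(
            image_id="t", gene="g", parameters=SVCAParameters(1.0, 1.0, 1.0, 1.0, 0.5),
            included_components=("intrinsic", "environmental", "cell_cell"),
            log_marginal_likelihood=0.0, terms=terms,
        )
        sig = svca.variance_signature(m)
        np.testing.assert_allclose(sig.fractions, 0.25, atol=1e-8)

    def test_noise_only_signature(self, rng):
        terms = build_random_terms(rng, 30)
        m = svca.FittedModel(
            image_id="t", gene="g", parameters=SVCAParameters(0.0, 0.0, 0.0, 2.0, 0.5),
            included_components=("intrinsic", "environmental", "cell_cell"),
            log_marginal_likelihood=0.0, terms=terms,
        )
        sig = svca.variance_signature(m)
        np.testing.assert_allclose(sig.fractions, [0, 0, 0, 1], atol=1e-12)

    def test_fractions_match_independent_gower_ratios(self, rng):
        terms = build_random_terms(rng, 25)
        params = SVCAParameters(0.7, 0.2, 0.4, 0.9, 0.5)
        m = svca.FittedModel(
            image_id="t", gene="g", parameters=params,
            included_components=("intrinsic", "environmental", "cell_cell"),
            log_marginal_likelihood=0.0, terms=terms,
        )
        sig = svca.variance_signature(m)
        n = 25
        p = np.eye(n) - np.ones((n, n)) / n
        gowers = np.array([
            np.trace(p @ (params.scale(c) * terms[c].matrix) @ p) / (n - 1)
            for c in ("intrinsic", "environmental", "cell_cell", "noise")
        ])
        np.testing.assert_allclose(sig.fractions, gowers / gowers.sum(), atol=1e-8)
        assert sig.fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_scales_rejected(self, rng):
        terms = build_random_terms(rng, 20)
        m = svca.FittedModel(
            image_id="t", gene="g", parameters=SVCAParameters(0, 0, 0, 0, 0.5),
            included_components=("intrinsic", "environmental", "cell_cell"),
            log_marginal_likelihood=0.0, terms=terms,
        )
        with pytest.raises(ValueError, match="degenerate"):
            svca.variance_signature(m)


class TestPredict:
    def test_matches_brute_force_posterior_mean(self, processed_image):
        n = processed_image.n_cells
        rng = np.random.default_rng(3)
        perm = rng.permutation(n)
        train, test = perm[:50], perm[50:60]
        m = svca.fit(processed_image, "g02", cell_indices=train, n_restarts=1, seed=0)
        pred = svca.predict(m, train, test, processed_image)

        # brute force: explicit inverse of the training covariance
        from svca.model import _cross_terms

        gi = processed_image.gene_index("g02")
        x_all = standardize_columns(np.delete(processed_image.expression, gi, axis=1))
        k_cross = _cross_terms(m, x_all[test], processed_image.positions[test])
        k_train = m.total_covariance()
        jitter = 1e-6 * max(np.trace(k_train) / len(train), 1.0)
        brute = k_cross @ np.linalg.inv(k_train + jitter * np.eye(len(train))) @ m.y
        np.testing.assert_allclose(pred, brute, atol=1e-8)

    def test_noise_only_model_predicts_prior_mean(self, processed_image):
        n = processed_image.n_cells
        train = np.arange(n - 10)
        test = np.arange(n - 10, n)
        m = svca.fit(processed_image, "g03", cell_indices=train, n_restarts=1, seed=0)
        # force a noise-only parameterization
        m.parameters.sigma2_int = 0.0
        m.parameters.sigma2_env = 0.0
        m.parameters.sigma2_cc = 0.0
        m.parameters.sigma2_noise = 1.0
        pred = svca.predict(m, train, test, processed_image)
        np.testing.assert_allclose(pred, 0.0, atol=1e-12)

    def test_interpolation_limit_for_duplicated_cell(self, rng):
        # a test cell that duplicates a training cell, noise -> 0:
        # the posterior mean approaches the training observation
        base = svca.synthesize_image(60, 8, seed=9)
        proc = svca.preprocess_counts(base.expression)
        proc = np.vstack([proc, proc[0]])
        pos = np.vstack([base.positions, base.positions[0]])
        img = svca.SpatialExpressionImage("dup", pos, proc, base.gene_names)
        train = np.arange(60)
        m = svca.fit(img, "g00", cell_indices=train, components=("intrinsic", "environmental"),
                     n_restarts=1, seed=0)
        m.parameters.sigma2_noise = 1e-9
        pred = svca.predict(m, train, [60], img)
        assert pred[0] == pytest.approx(m.y[0], abs=1e-3)

    def test_overlapping_index_sets_rejected(self, processed_image):
        m = svca.fit(processed_image, "g00", cell_indices=np.arange(60),
                     n_restarts=1, seed=0)
        with pytest.raises(ValueError):
            svca.predict(m, np.arange(60), np.array([10]), processed_image)
        with pytest.raises(ValueError):
            svca.predict(m, np.arange(60), np.array([]), processed_image)


class TestCrossValidate:
    def test_same_seed_gives_identical_folds_and_r2(self, processed_image):
        grid = svca.default_length_grid(processed_image, 3)
        a = svca.cross_validate(processed_image, "g04", k=4, seed=5, grid=grid,
                                variants={"full": ("intrinsic", "environmental", "cell_cell")})
        b = svca.cross_validate(processed_image, "g04", k=4, seed=5, grid=grid,
                                variants={"full": ("intrinsic", "environmental", "cell_cell")})
        assert a == b

    def test_invalid_fold_count_rejected(self, processed_image):
        with pytest.raises(ValueError):
            svca.cross_validate(processed_image, "g00", k=1)

    def test_pure_noise_has_low_r2_everywhere(self, processed_image):
        rng = np.random.default_rng(17)
        medians = {"intrinsic": [], "full": []}
        for seed in range(3):
            expr = processed_image.expression.copy()
            expr[:, 0] = rng.normal(size=processed_image.n_cells)
            img = svca.SpatialExpressionImage(
                "noise", processed_image.positions, expr, processed_image.gene_names
            )
            grid = svca.default_length_grid(img, 3)
            r2 = svca.cross_validate(
                img, "g00", k=4, seed=seed, grid=grid,
                variants={"intrinsic": ("intrinsic",),
                          "full": ("intrinsic", "environmental", "cell_cell")},
            )
            for key, v in r2.items():
                medians[key].append(v)
        for key in medians:
            assert np.median(medians[key]) <= 0.1
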