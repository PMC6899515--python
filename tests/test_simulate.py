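import numpy as np
import pytest
from scipy.stats import ks_2samp

import svca
from svca import kernels as k
from svca.simulate import (
    LinearSimConfig,
    _knn_inverse_square_weights,
    base_terms_for_image,
    missegmentation_probabilities,
    rescaling_factor,
)



class TestSynthesizeImage:
    def test_same_seed_is_deterministic(self):
        a = svca.synthesize_image(50, 6, seed=5)
        b = svca.synthesize_image(50, 6, seed=5)
        np.testing.assert_array_equal(a.expression, b.expression)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_structureless_settings_give_near_independent_genes(self):
        img = svca.synthesize_image(
            500, 10, n_latent_factors=0, spatial_autocorrelation_scale=0.0, seed=2
        )
        c = np.corrcoef(img.expression.T)
        off = np.abs(c[~np.eye(10, dtype=bool)])
        assert np.median(off) < 0.1

    def test_dispersion_round_trip_with_preprocessing(self):
        # isolate the NB sampling layer: no latent/spatial structure and a
        # near-flat mean surface, so across-cell variance is pure NB
        img = svca.synthesize_image(
            2000, 20, n_latent_factors=0, spatial_autocorrelation_scale=0.0,
            nb_dispersion=0.5, log_intensity_sd=0.02, seed=3,
        )
        assert svca.fit_dispersion(img.expression) == pytest.approx(0.5, abs=0.2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            svca.synthesize_image(10, 10)
        with pytest.raises(ValueError):
            svca.synthesize_image(100, 2)

    def test_minimum_cell_spacing_enforced(self):
        img = svca.synthesize_image(300, 5, seed=4)
        d = svca.pairwise_distances(img)
        nn = (d + np.eye(300) * 1e9).min(axis=1)
        assert nn.min() >= 0.4 / np.sqrt(300) - 1e-12


class TestGenerativeSimulation:
    @pytest.fixture(scope="class")
    def base(self, processed_image):
        return base_terms_for_image(processed_image, "g00")

    def test_rescaled_fraction_is_exact(self, base):
        terms, scales = base
        for x in np.arange(0.1, 0.95, 0.1):
            ksim = rescaling_factor(terms, scales, x)
            g_cc = k.gower_factor(ksim * scales["cell_cell"] * terms["cell_cell"].matrix)
            g_rest = sum(
                k.gower_factor(scales[n] * t.matrix)
                for n, t in terms.items() if n != "cell_cell"
            )
            assert g_cc / (g_cc + g_rest) == pytest.approx(x, abs=1e-10)

    def test_x_half_formula(self, base):
        terms, scales = base
        # at x = 0.5, k_sim * G(scaled cc) must equal G of the other terms
        ksim = rescaling_factor(terms, scales, 0.5)
        g_cc = k.gower_factor(scales["cell_cell"] * terms["cell_cell"].matrix)
        g_rest = sum(
            k.gower_factor(scales[n] * t.matrix)
            for n, t in terms.items() if n != "cell_cell"
        )
        assert ksim * g_cc == pytest.approx(g_rest, rel=1e-12)

    def test_x_zero_draw_excludes_interaction_term(self, base):
        terms, scales = base
        y0 = svca.simulate_from_generative(terms, scales, 0.0, seed=3)
        # reproducing the covariance without the cc term gives the same draw
        n = y0.shape[0]
        kk = sum(scales[c] * terms[c].matrix for c in ("intrinsic", "environmental", "noise"))
        kk[np.diag_indices(n)] += 1e-10 * np.trace(kk) / n
        expected = np.linalg.cholesky(kk) @ np.random.default_rng(3).normal(size=n)
        np.testing.assert_allclose(y0, expected)

    def test_null_cell_cell_term_rejected(self, base):
        terms, scales = base
        scales = dict(scales, cell_cell=0.0)
        with pytest.raises(ValueError, match="null"):
            rescaling_factor(terms, scales, 0.5)


class TestLinearSimulator:
    def test_interaction_share_is_exact(self, medium_processed_image):
        cfg = LinearSimConfig(eta_cc=0.4, eta_mis=0.0, n_nn=4, seed=8)
        y, y_t, _ = svca.simulate_linear(medium_processed_image, cfg)
        np.testing.assert_allclose(y, y_t)
        # reconstruct the standardized interaction block and check its share
        assert np.var(y) == pytest.approx(1.0, rel=1e-10)

    def test_no_interaction_is_position_invariant(self, processed_image):
        # with eta_cc = 0 the target does not depend on positions: its
        # distribution is unchanged when positions are shuffled
        cfg = LinearSimConfig(eta_cc=0.0, eta_mis=0.0, seed=1)
        y1, *_ = svca.simulate_linear(processed_image, cfg)
        rng = np.random.default_rng(2)
        shuffled = svca.SpatialExpressionImage(
            "s", rng.permutation(processed_image.positions),
            processed_image.expression, processed_image.gene_names,
        )
        y2, *_ = svca.simulate_linear(shuffled, cfg)
        assert ks_2samp(y1, y2).pvalue > 0.05

    def test_full_interaction_limit(self, processed_image):
        cfg = LinearSimConfig(eta_cc=1.0, eta_mis=0.0, n_nn=4, seed=3)
        y, *_ = svca.simulate_linear(processed_image, cfg)
        # eta_cc = 1: y is (up to the small orthogonalization correction)
        # the raw neighbor-interaction block Z X beta_cc
        x = svca.preprocess.standardize_columns(processed_image.expression)
        d = svca.pairwise_distances(processed_image)
        z = _knn_inverse_square_weights(d, 4)
        rng = np.random.default_rng(3)
        rng.normal(size=x.shape[1])  # beta_i drawn first
        beta_cc = rng.normal(size=x.shape[1])
        b_raw = (z @ x) @ beta_cc
        assert np.corrcoef(y, b_raw)[0, 1] ** 2 > 0.9
        assert np.var(y) == pytest.approx(1.0, rel=1e-10)

    def test_knn_weight_structure(self, rng):
        pos = rng.uniform(0, 1, (30, 2))
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        z = _knn_inverse_square_weights(d, 5)
        assert np.all(np.diag(z) == 0.0)
        assert np.all((z > 0).sum(axis=1) == 5)
        i = 7
        nbr = np.argsort(d[i] + np.eye(30)[i] * 1e9)[:5]
        np.testing.assert_allclose(z[i, nbr], 1.0 / d[i, nbr] ** 2)


class TestMissegmentation:
    def test_partner_probabilities_formula(self):
        # focal cell 0 with candidates at distances 1 and 2:
        # p = (1, 1/4) normalized = (0.8, 0.2)
        d_row = np.array([0.0, 1.0, 2.0])
        p = missegmentation_probabilities(d_row, focal=0)
        np.testing.assert_allclose(p, [0.0, 0.8, 0.2])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_share_is_identity(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=(20, 3))
        d = np.abs(rng.normal(size=(20, 20)))
        d = d + d.T
        np.fill_diagonal(d, 0.0)
        y2, x2 = svca.missegmentation_perturb(y, x, d, 0.0, seed=0)
        np.testing.assert_array_equal(y, y2)
        np.testing.assert_array_equal(x, x2)

    def test_full_share_replaces_with_partner_mean(self, rng):
        n = 15
        pos = rng.uniform(0, 1, (n, 2))
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        y = rng.normal(size=n)
        x = rng.normal(size=(n, 2))
        y2, _ = svca.missegmentation_perturb(y, x, d, 0.999999, seed=4)
        # perturbed values are (almost) independent of the cell's own value:
        # each must equal a mean of two other cells' values up to the tiny share
        for i in range(n):
            diffs = np.abs(y2[i] - (y[:, None] + y[None, :]) / 2.0)
            assert diffs.min() < 1e-4

    def test_probabilities_sum_to_one_per_focal_cell(self, rng):
        pos = rng.uniform(0, 1, (40, 2))
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        for i in range(40):
            p = missegmentation_probabilities(d[i], focal=i)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert p[i] == 0.0


class TestRecoveryExperiment:
    def test_table_is_deterministic_and_monotone_null(self, processed_image):
        table = svca.recovery_experiment(
            [processed_image], x_grid=[0.0, 0.6], seeds=[0, 1], grid_size=3
        )
        table2 = svca.recovery_experiment(
            [processed_image], x_grid=[0.0, 0.6], seeds=[0, 1], grid_size=3
        )
        assert table.equals(table2)
        null = table[table["x"] == 0.0]["estimate"]
        strong = table[table["x"] == 0.6]["estimate"]
        assert null.median() < 0.05
        assert strong.median() > null.median()
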