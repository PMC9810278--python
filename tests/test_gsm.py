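"""GSM generative model and ideal-observer tests against brute-force oracles."""

import numpy as np
import pytest

from gsmring import gsm

from oracles import contrast_weights_direct, grid_posterior_moments, ring_kernel_bruteforce


class TestGaborBank:
    def test_uniform_orientation_spacing(self):
        A = gsm.build_gabor_bank(4, 8)
        assert A.shape == (64, 4)
        assert np.allclose(gsm.uniform_orientations(4), [-90.0, -45.0, 0.0, 45.0])

    def test_equal_column_norms(self):
        A = gsm.build_gabor_bank(12, 16)
        norms = np.linalg.norm(A, axis=0)
        assert np.allclose(norms, norms[0], atol=1e-6)

    def test_quarter_turn_columns_are_image_rotations(self):
        """Columns 90 deg apart must be 90-degree pixel rotations of each other."""
        n, side = 8, 16
        A = gsm.build_gabor_bank(n, side)
        for k in range(n // 2):
            img = A[:, k].reshape(side, side)
            img_rot = A[:, k + n // 2].reshape(side, side)
            err = min(
                np.abs(np.rot90(img, rot) - img_rot).max() for rot in (1, 3)
            )
            assert err < 1e-10

    def test_degenerate_envelope_rejected(self):
        with pytest.raises(ValueError):
            gsm.build_gabor_bank(4, 8, gsm.GaborParams(sigma=0.0))


class TestPriorCov:
    def test_narrow_kernel_is_diagonal(self):
        ori = gsm.uniform_orientations(6)
        C = gsm.build_prior_cov(ori, gsm.RingKernel(width_deg=0.5))
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-12
        assert np.allclose(np.diag(C), C[0, 0])

    def test_positive_definite_and_circulant(self):
        ori = gsm.uniform_orientations(8)
        C = gsm.build_prior_cov(ori, gsm.RingKernel(width_deg=30.0))
        assert np.linalg.eigvalsh(C)[0] > 0
        # circulant: every row is a rotation of the first
        for i in range(8):
            assert np.allclose(C[i], np.roll(C[0], i))

    def test_matches_bruteforce_kernel_evaluation(self):
        ori = gsm.uniform_orientations(6)
        kp = gsm.RingKernel(variance=1.3, width_deg=25.0, jitter=0.0)
        C = gsm.build_prior_cov(ori, kp)
        C_oracle = ring_kernel_bruteforce(ori, kp)
        assert np.allclose(C, C_oracle, atol=1e-12)

    def test_nonpd_kernel_reports_smallest_eigenvalue(self):
        class BadKernel(gsm.RingKernel):
            def __call__(self, d):
                return -np.ones_like(np.asarray(d, dtype=float))

        with pytest.raises(ValueError, match="eigenvalue"):
            gsm.build_prior_cov(gsm.uniform_orientations(4), BadKernel(jitter=0.0))


class TestSamplePatch:
    def test_zero_contrast_is_pure_pixel_noise(self, tiny_model):
        xs = np.array(
            [gsm.sample_patch(tiny_model, z=0.0, seed=s)[0] for s in range(4000)]
        )
        cov = np.cov(xs.T)
        assert np.abs(np.diag(cov) - tiny_model.sigma_x2).max() < 0.1
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.1

    def test_seeded_sampling_is_bit_reproducible(self, tiny_model):
        x1, rec1 = gsm.sample_patch(tiny_model, seed=42)
        x2, rec2 = gsm.sample_patch(tiny_model, seed=42)
        assert np.array_equal(x1, x2)
        assert rec1["z"] == rec2["z"] and np.array_equal(rec1["y"], rec2["y"])

    def test_marginal_pixel_covariance(self, tiny_model):
        """At fixed z=1 the patch covariance is A C A^T + sigma_x2 I."""
        xs = np.array(
            [gsm.sample_patch(tiny_model, z=1.0, seed=s)[0] for s in range(10_000)]
        )
        expected = tiny_model.A @ tiny_model.C @ tiny_model.A.T + tiny_model.sigma_x2 * np.eye(
            tiny_model.n_pixels
        )
        assert np.abs(np.cov(xs.T) - expected).max() < 0.12

    def test_negative_contrast_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            gsm.sample_patch(tiny_model, z=-1.0)


class TestConditionalPosterior:
    def test_zero_contrast_returns_prior_exactly(self, tiny_model):
        x = np.ones(tiny_model.n_pixels)
        ps = gsm.posterior_given_z(tiny_model, x, 0.0)
        assert np.array_equal(ps.mean, np.zeros(3))
        assert np.array_equal(ps.cov, tiny_model.C)

    def test_univariate_conjugate_values(self):
        """1-latent instance with C=4, A=10, sigma_x2=100: mean = var = 0.8."""
        model = gsm.GSMModel(
            A=np.array([[10.0]]),
            C=np.array([[4.0]]),
            sigma_x2=100.0,
            orientations=np.array([0.0]),
        )
        ps = gsm.posterior_given_z(model, np.array([10.0]), 1.0)
        assert np.allclose(ps.mean, 0.8, atol=1e-12)
        assert np.allclose(ps.cov, 0.8, atol=1e-12)

    def test_matches_dense_grid_quadrature(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=1.0, seed=3)
        ps = gsm.posterior_given_z(tiny_model, x, 1.0)
        mean_o, cov_o = grid_posterior_moments(
            tiny_model.A, tiny_model.C, tiny_model.sigma_x2, x, 1.0
        )
        assert np.abs(ps.mean - mean_o).max() / np.abs(mean_o).max() < 1e-6
        assert np.abs(ps.cov - cov_o).max() / np.abs(cov_o).max() < 1e-6

    def test_wrong_pixel_count_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            gsm.posterior_given_z(tiny_model, np.zeros(5), 1.0)


class TestContrastPosterior:
    def test_weights_normalised(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=2.0, seed=0)
        w = gsm.contrast_posterior(tiny_model, x, gsm.default_z_grid())
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0)

    def test_matches_direct_evidence_evaluation(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=1.5, seed=5)
        zg = gsm.default_z_grid(40)
        w = gsm.contrast_posterior(tiny_model, x, zg)
        w_o = contrast_weights_direct(
            tiny_model.A,
            tiny_model.C,
            tiny_model.sigma_x2,
            tiny_model.contrast_prior.shape,
            tiny_model.contrast_prior.scale,
            x,
            zg,
        )
        assert np.abs(w - w_o).max() < 1e-10

    def test_zero_patch_prefers_low_contrast(self, tiny_model):
        zg = gsm.default_z_grid()
        w = gsm.contrast_posterior(tiny_model, np.zeros(tiny_model.n_pixels), zg)
        assert (w @ zg) < tiny_model.contrast_prior.shape * tiny_model.contrast_prior.scale

    def test_strong_patch_shifts_contrast_estimate_up(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=3.0, seed=11)
        zg = gsm.default_z_grid()
        z_hat_strong = gsm.contrast_posterior(tiny_model, x, zg) @ zg
        z_hat_weak = gsm.contrast_posterior(tiny_model, x / 10.0, zg) @ zg
        assert z_hat_strong > z_hat_weak


class TestPosteriorMoments:
    def test_single_point_grid_reduces_to_conditional(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=1.0, seed=7)
        ps_mix = gsm.posterior_moments(tiny_model, x, np.array([1.3]))
        ps_cond = gsm.posterior_given_z(tiny_model, x, 1.3)
        assert np.array_equal(ps_mix.mean, ps_cond.mean)
        assert np.array_equal(ps_mix.cov, ps_cond.cov)

    def test_grid_refinement_converges(self, tiny_model):
        x, _ = gsm.sample_patch(tiny_model, z=1.0, seed=9)
        coarse = gsm.posterior_moments(tiny_model, x, gsm.default_z_grid(50))
        fine = gsm.posterior_moments(tiny_model, x, gsm.default_z_grid(500))
        assert np.abs(coarse.mean - fine.mean).max() / np.abs(fine.mean).max() < 1e-3
        assert np.abs(coarse.cov - fine.cov).max() / np.abs(fine.cov).max() < 1e-3

    def test_mixture_variance_dominates_conditional_minimum(self, tiny_model):
        """Law of total variance: mixture variance >= min conditional variance."""
        x, _ = gsm.sample_patch(tiny_model, z=1.0, seed=13)
        zg = gsm.default_z_grid(30)
        mix_var = np.diag(gsm.posterior_moments(tiny_model, x, zg).cov)
        cond_min = np.min(
            [np.diag(gsm.posterior_given_z(tiny_model, x, z).cov) for z in zg], axis=0
        )
        assert np.all(mix_var >= cond_min - 1e-12)


class TestHypoprior:
    def test_identity_at_alpha_one(self, tiny_model):
        out = gsm.apply_hypoprior(tiny_model, 1.0)
        assert np.array_equal(out.C, tiny_model.C)
        assert np.array_equal(out.A, tiny_model.A)

    def test_prior_sd_scales_by_sqrt_alpha(self, default_model):
        hypo = gsm.apply_hypoprior(default_model, 1.5)
        assert np.allclose(
            np.sqrt(np.diag(hypo.C)), np.sqrt(1.5) * np.sqrt(np.diag(default_model.C))
        )

    def test_posterior_sd_increases_under_hypoprior(self, tiny_model):
        hypo = gsm.apply_hypoprior(tiny_model, 1.5)
        x, _ = gsm.sample_patch(tiny_model, z=1.0, seed=21)
        for z in (0.25, 1.0, 4.0):
            sd_true = gsm.posterior_given_z(tiny_model, x, z).sd.mean()
            sd_hypo = gsm.posterior_given_z(hypo, x, z).sd.mean()
            assert sd_hypo > sd_true

    def test_alpha_below_one_warns(self, tiny_model):
        with pytest.warns(UserWarning):
            gsm.apply_hypoprior(tiny_model, 0.5)

    def test_nonpositive_alpha_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            gsm.apply_hypoprior(tiny_model, 0.0)


class TestToy1D:
    def test_prior_limit_at_zero_contrast(self):
        df = gsm.toy1d_curves(4.0, 10.0, 100.0, 1.5, 10.0, np.array([0.0]))
        assert df["mean_true"].iloc[0] == 0.0
        assert df["sd_true"].iloc[0] == pytest.approx(2.0)

    def test_reference_values_at_unit_contrast(self):
        """C=4, A=10, sigma_x2=100, z=1, x=10: closed-form conjugate values."""
        df = gsm.toy1d_curves(4.0, 10.0, 100.0, 1.5, 10.0, np.array([1.0]))
        row = df.iloc[0]
        assert row["mean_true"] == pytest.approx(0.8, abs=1e-12)
        assert row["sd_true"] == pytest.approx(np.sqrt(0.8), abs=1e-12)
        assert row["mean_hypo"] == pytest.approx(6.0 / 7.0, abs=1e-12)
        assert row["sd_hypo"] == pytest.approx(np.sqrt(6.0 / 7.0), abs=1e-12)

    def test_closed_form_matches_numerical_quadrature(self):
        """Cross-check the conjugate formulas by 1D grid quadrature."""
        C, A, s2, x_obs, z = 4.0, 10.0, 100.0, 10.0, 0.7
        df = gsm.toy1d_curves(C, A, s2, 1.5, x_obs, np.array([z]))
        y = np.linspace(-10, 10, 20001)
        for tag, Cp in (("true", C), ("hypo", 1.5 * C)):
            logp = -0.5 * y**2 / Cp - 0.5 * (x_obs - z * A * y) ** 2 / s2
            w = np.exp(logp - logp.max())
            w /= w.sum()
            mean_q = w @ y
            sd_q = np.sqrt(w @ (y - mean_q) ** 2)
            assert df[f"mean_{tag}"].iloc[0] == pytest.approx(mean_q, abs=1e-9)
            assert df[f"sd_{tag}"].iloc[0] == pytest.approx(sd_q, abs=1e-9)

    def test_likelihood_dominates_at_high_contrast(self):
        zs = np.array([50.0, 100.0])
        df = gsm.toy1d_curves(4.0, 10.0, 100.0, 1.5, 10.0, zs)
        point = 10.0 / (zs * 10.0)
        assert np.allclose(df["mean_true"], point, rtol=1e-2)
        assert np.allclose(df["mean_hypo"], point, rtol=1e-2)
        assert np.abs(df["mean_hypo"] - df["mean_true"]).iloc[-1] < 1e-5

    def test_sd_strictly_decreasing_in_contrast(self):
        zs = np.linspace(0.0, 5.0, 21)
        df = gsm.toy1d_curves(4.0, 10.0, 100.0, 1.5, 10.0, zs)
        assert np.all(np.diff(df["sd_true"]) < 0)
        assert np.all(np.diff(df["sd_hypo"]) < 0)
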