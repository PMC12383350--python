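import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otperturb.data_io import RunConfig
from otperturb.mmdvae import (
    MMDVAE,
    kl_regularizer,
    mmd2,
    rbf_kernel,
    total_loss,
    train,
    tune_alpha,
)


def mmd2_bruteforce(Z, Zp, bw):
    """Independent quadratic double-sum oracle (all pairs incl. self)."""
    m1, m2 = len(Z), len(Zp)
    t1 = sum(rbf_kernel(Z[a], Z[b], bw) for a in range(m1) for b in range(m1)) / m1**2
    t2 = sum(rbf_kernel(Zp[a], Zp[b], bw) for a in range(m2) for b in range(m2)) / m2**2
    t3 = sum(rbf_kernel(Z[a], Zp[b], bw) for a in range(m1) for b in range(m2)) / (m1 * m2)
    return t1 + t2 - 2 * t3


class TestRBFKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert rbf_kernel(x, x, 2.0) == 1.0

    def test_hand_value(self):
        # ||x-y||^2 = 2, bandwidth 1 -> exp(-1)
        assert rbf_kernel(np.array([1.0, 1.0]), np.array([0.0, 0.0]), 1.0) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )

    def test_monotone_in_distance(self):
        vals = [rbf_kernel(np.array([0.0]), np.array([t]), 1.5) for t in [0.1, 0.5, 1, 2, 5]]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(2), 0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)


class TestMMD2:
    def test_identical_samples_zero(self):
        Z = np.random.default_rng(0).normal(size=(15, 4))
        assert mmd2(Z, Z.copy(), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_1d(self):
        # Z={0}, Zp={1}: 1 + 1 - 2*exp(-0.5)
        got = mmd2(np.array([[0.0]]), np.array([[1.0]]), 1.0)
        assert got == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m1, m2, k = rng.integers(2, 20), rng.integers(2, 20), rng.integers(1, 6)
            Z = rng.normal(size=(m1, k))
            Zp = rng.normal(size=(m2, k))
            bw = float(rng.uniform(0.5, 3.0))
            assert mmd2(Z, Zp, bw) == pytest.approx(mmd2_bruteforce(Z, Zp, bw), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        Z, Zp = rng.normal(size=(8, 3)), rng.normal(size=(11, 3))
        assert mmd2(Z, Zp, 1.2) == pytest.approx(mmd2(Zp, Z, 1.2), abs=1e-12)

    def test_increases_with_mean_shift(self):
        # Monte-Carlo trend: larger mean offset -> larger expected mmd2
        rng = np.random.default_rng(7)
        means = []
        for c in [0.0, 1.0, 3.0]:
            vals = [
                mmd2(rng.normal(size=(30, 2)), rng.normal(c, 1.0, size=(30, 2)), 1.0)
                for _ in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mmd2(np.empty((0, 2)), np.zeros((3, 2)), 1.0)


class TestKL:
    def test_prior_equals_posterior(self):
        assert kl_regularizer(np.zeros((4, 3)), np.ones((4, 3))) == 0.0

    def test_hand_value(self):
        # mu=1, sigma=1, k=1: 0.5 * (1 + 1 - 1 - 0) = 0.5
        assert kl_regularizer(np.array([[1.0]]), np.array([[1.0]])) == pytest.approx(0.5)

    @given(
        mu=st.floats(-3, 3), logsig=st.floats(-1.5, 1.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_zero_only_at_prior(self, mu, logsig):
        val = kl_regularizer(np.array([[mu]]), np.array([[np.exp(logsig)]]))
        if abs(mu) > 1e-9 or abs(logsig) > 1e-9:
            assert val > 0
        else:
            assert val == pytest.approx(0.0, abs=1e-12)


class TestReparameterize:
    def test_eps_zero_gives_mu(self):
        mu = np.array([1.0, 2.0])
        assert np.array_equal(
            MMDVAE.reparameterize(mu, np.array([1.0, 3.0]), np.zeros(2)), mu
        )

    def test_hand_value(self):
        z = MMDVAE.reparameterize(
            np.array([1.0, 2.0]), np.array([1.0, 0.5]), np.array([1.0, -2.0])
        )
        np.testing.assert_allclose(z, [2.0, 1.0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            MMDVAE.reparameterize(np.zeros(2), np.zeros(3), np.zeros(2))


class TestTotalLoss:
    def test_perfect_reconstruction_and_matched_prior(self):
        D = np.random.default_rng(0).normal(size=(6, 4))
        Z = np.random.default_rng(1).normal(size=(6, 3))
        assert total_loss(D, D.copy(), Z, Z.copy(), alpha=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_zero_is_reconstruction(self):
        rng = np.random.default_rng(2)
        D, Dh = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        Z, Zp = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        expected = ((D - Dh) ** 2).sum(axis=1).mean()
        assert total_loss(D, Dh, Z, Zp, alpha=0.0) == pytest.approx(expected)

    def test_alpha_linearity(self):
        rng = np.random.default_rng(3)
        D, Dh = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        Z, Zp = rng.normal(size=(5, 2)), rng.normal(size=(5, 2)) + 2
        recon = ((D - Dh) ** 2).sum(axis=1).mean()
        l1 = total_loss(D, Dh, Z, Zp, alpha=1.0)
        l2 = total_loss(D, Dh, Z, Zp, alpha=2.0)
        assert l2 - recon == pytest.approx(2 * (l1 - recon), rel=1e-9)


class TestEncodeDecode:
    def test_encode_deterministic_and_shaped(self, small_model):
        model, cfg, train_set, *_ = small_model
        mu1, sig1 = model.encode(train_set.matrix[:7])
        mu2, sig2 = model.encode(train_set.matrix[:7])
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(sig1, sig2)
        assert mu1.shape == (7, cfg.latent_dim)
        assert np.all(sig1 > 0)

    def test_encode_order_preserving(self, small_model):
        model, _, train_set, *_ = small_model
        mu, _ = model.encode(train_set.matrix[:6])
        mu_rev, _ = model.encode(train_set.matrix[:6][::-1])
        np.testing.assert_allclose(mu, mu_rev[::-1], atol=1e-12)

    def test_decode_deterministic_finite(self, small_model):
        model, cfg, *_ = small_model
        z = np.random.default_rng(0).normal(size=(4, cfg.latent_dim))
        out1, out2 = model.decode(z), model.decode(z)
        np.testing.assert_array_equal(out1, out2)
        assert np.all(np.isfinite(out1))

    def test_dimension_errors(self, small_model):
        model, cfg, *_ = small_model
        with pytest.raises(ValueError):
            model.encode(np.zeros((2, model.input_dim + 1)))
        with pytest.raises(ValueError):
            model.decode(np.zeros((2, cfg.latent_dim + 1)))


class TestTraining:
    def test_loss_decreases(self, small_model):
        model, *_ = small_model
        assert model.loss_history[-1]["total"] < model.loss_history[0]["total"]

    def test_loss_history_length(self, small_model):
        model, cfg, *_ = small_model
        assert len(model.loss_history) == cfg.epochs == model.epochs_completed

    def test_seed_reproducibility(self, small_processed):
        processed, _ = small_processed
        cfg = RunConfig(
            seed=3, latent_dim=6, hidden_widths=[16], epochs=3, batch_size=64,
            min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200,
        )
        m1 = train(processed, None, cfg)
        m2 = train(processed, None, cfg)
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])

    def test_different_seeds_differ(self, small_processed):
        processed, _ = small_processed
        base = dict(
            latent_dim=6, hidden_widths=[16], epochs=2, batch_size=64,
            min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200,
        )
        m1 = train(processed, None, RunConfig(seed=3, **base))
        m2 = train(processed, None, RunConfig(seed=4, **base))
        assert m1.loss_history[-1]["total"] != m2.loss_history[-1]["total"]

    def test_alpha_zero_arms_identical(self, small_processed):
        # with alpha=0 the regularizer pathway is skipped entirely, so the
        # mmd and kl arms must produce bit-identical models
        processed, _ = small_processed
        base = dict(
            seed=5, latent_dim=6, hidden_widths=[16], epochs=3, batch_size=64,
            alpha=0.0, min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200,
        )
        m1 = train(processed, None, RunConfig(regularizer="mmd", **base))
        m2 = train(processed, None, RunConfig(regularizer="kl", **base))
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])

    def test_regularizer_arms_share_data_stream(self, small_processed):
        # mmd vs kl with alpha>0: losses differ but both run and log the
        # decomposition
        processed, _ = small_processed
        base = dict(
            seed=5, latent_dim=6, hidden_widths=[16], epochs=2, batch_size=64,
            alpha=1.0, min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200,
        )
        m1 = train(processed, None, RunConfig(regularizer="mmd", **base))
        m2 = train(processed, None, RunConfig(regularizer="kl", **base))
        for h in m1.loss_history + m2.loss_history:
            assert set(h) == {"epoch", "recon", "reg", "total"}

    def test_autoencoder_reduces_error_on_separable_fixture(self):
        # alpha=0, two well-separated blobs: reconstruction error falls
        # below 10% of the initial error
        from .conftest import make_dataset

        rng = np.random.default_rng(0)
        blob1 = rng.normal(0.0, 0.05, size=(60, 12))
        blob2 = rng.normal(3.0, 0.05, size=(60, 12))
        ds = make_dataset(np.vstack([blob1, blob2]), layer_tag="normalized_log")
        cfg = RunConfig(
            seed=0, latent_dim=4, hidden_widths=[16], epochs=80, batch_size=32,
            alpha=0.0, dropout=0.0, learning_rate=3e-3,
        )
        model = train(ds, None, cfg)
        assert model.loss_history[-1]["recon"] < 0.1 * model.loss_history[0]["recon"]

    def test_nonfinite_loss_aborts(self):
        from .conftest import make_dataset

        ds = make_dataset(
            np.random.default_rng(0).normal(size=(32, 5)) * 1e200,
            layer_tag="normalized_log",
        )
        cfg = RunConfig(seed=0, latent_dim=2, hidden_widths=[4], epochs=2,
                        batch_size=16, dropout=0.0)
        with pytest.raises((RuntimeError, FloatingPointError)):
            train(ds, None, cfg)

    def test_save_load_round_trip(self, small_model, tmp_path):
        model, cfg, train_set, *_ = small_model
        path = model.save(str(tmp_path / "model.npz"))
        back = MMDVAE.load(path)
        mu1, _ = model.encode(train_set.matrix[:3])
        mu2, _ = back.encode(train_set.matrix[:3])
        np.testing.assert_allclose(mu1, mu2, atol=1e-12)


class TestTuneAlpha:
    def _cfg(self):
        return RunConfig(
            seed=1, latent_dim=4, hidden_widths=[16], epochs=2, batch_size=32,
            min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200,
        )

    def test_single_admissible_candidate_returned(self, small_processed):
        processed, _ = small_processed
        cfg = self._cfg()
        got = tune_alpha([1.0], processed, cfg, ratio_bounds=(0.0, np.inf))
        assert got == 1.0

    def test_extreme_candidate_discarded(self, small_processed):
        # a huge alpha drives the regularizer term far above reconstruction,
        # violating the magnitude-ratio bound, so the default comes back
        processed, _ = small_processed
        cfg = self._cfg()
        got = tune_alpha([1e9], processed, cfg)
        assert got == cfg.alpha

    def test_deterministic(self, small_processed):
        processed, _ = small_processed
        cfg = self._cfg()
        a = tune_alpha([0.5, 1.0], processed, cfg, ratio_bounds=(0.0, np.inf))
        b = tune_alpha([0.5, 1.0], processed, cfg, ratio_bounds=(0.0, np.inf))
        assert a == b
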