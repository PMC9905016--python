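"""Cross-validated PCA: self-consistency with ordinary PCA, unbiasedness of
the signal-variance estimate, shuffle-test behavior, and Fisher averaging."""

import numpy as np
import pytest

from avcortex import cvpca
from avcortex.cvpca import (
    SplitSpec, component_halves, cvpca_spectrum, fisher_mean_correlation,
    odd_even_split, pc_timecourse, shuffle_significance,
)


def test_odd_even_split_convention():
    sp = odd_even_split(4)
    assert sp.train_repeats == (0, 2) and sp.test_repeats == (1, 3)
    with pytest.raises(ValueError):
        SplitSpec((0, 1), (1, 2))


class TestSpectrum:
    def test_self_covariance_equals_pca_eigenvalues(self, rng):
        comp = rng.standard_normal((10, 5, 8))
        comp -= comp.mean(axis=1, keepdims=True)
        res = cvpca_spectrum(comp, comp)
        X = comp.transpose(1, 0, 2).reshape(-1, 8)
        Xc = X - X.mean(axis=0)
        # noise-free: vhat equals the train-set variance per component,
        # i.e. the ordinary (centered) PCA eigenvalue spectrum
        ref = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1)))[::-1]
        assert (res.vhat >= -1e-12).all()
        assert (np.diff(res.vhat) <= 1e-9).all()
        np.testing.assert_allclose(res.vhat, ref, atol=1e-8)

    def test_orthonormal_weights_and_unit_norm_spectrum(self, rng):
        a = rng.standard_normal((6, 4, 5))
        b = rng.standard_normal((6, 4, 5))
        res = cvpca_spectrum(a, b)
        np.testing.assert_allclose(res.W.T @ res.W, np.eye(res.n_components),
                                   atol=1e-10)
        assert np.isclose(res.normalized_spectrum.sum(), 1.0)

    def test_unbiased_signal_variance_rank1(self):
        # planted rank-1 signal, independent noise in each half; the summed
        # test-retest covariance estimates the true signal variance
        rng = np.random.default_rng(7)
        n, c, sims = 120, 12, 200
        u = rng.standard_normal(n)
        v = rng.standard_normal(c) / np.sqrt(c)
        S = np.outer(u, v)
        truth = np.sum((S - S.mean(axis=0)) ** 2) / (n - 1)
        est = np.empty(sims)
        for i in range(sims):
            A = (S + 0.8 * rng.standard_normal((n, c))).reshape(n, 1, c)
            B = (S + 0.8 * rng.standard_normal((n, c))).reshape(n, 1, c)
            est[i] = cvpca_spectrum(A, B).vhat.sum()
        se = est.std(ddof=1) / np.sqrt(sims)
        assert abs(est.mean() - truth) < 2 * se

    def test_pure_noise_gives_zero_mean(self):
        rng = np.random.default_rng(8)
        n, c, sims = 100, 10, 200
        est = np.empty((sims, c))
        for i in range(sims):
            A = rng.standard_normal((n, 1, c))
            B = rng.standard_normal((n, 1, c))
            est[i] = cvpca_spectrum(A, B).vhat
        se = est.std(axis=0, ddof=1) / np.sqrt(sims)
        assert (np.abs(est.mean(axis=0)) < 2.5 * se).all()

    def test_channel_permutation_equivariance(self, rng):
        a = rng.standard_normal((8, 3, 6))
        b = rng.standard_normal((8, 3, 6))
        res = cvpca_spectrum(a, b)
        perm = rng.permutation(6)
        res_p = cvpca_spectrum(a[..., perm], b[..., perm])
        np.testing.assert_allclose(res_p.vhat, res.vhat, atol=1e-9)
        # rows of W permute with the channels (up to per-component sign)
        dots = np.abs(np.sum(res_p.W * res.W[perm], axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        a = rng.standard_normal((4, 2, 3))
        with pytest.raises(ValueError):
            cvpca_spectrum(a, a, n_components=5)


class TestShuffle:
    def test_single_stimulus_degenerate(self, rng):
        D = rng.standard_normal((5, 1, 1, 4, 3))
        res = shuffle_significance(D, "sound", n_shuffles=100, seed=0)
        assert res.n_significant == 0
        assert not res.significant.any()

    def test_pure_noise_tensor_rarely_significant(self):
        rng = np.random.default_rng(3)
        D = rng.standard_normal((6, 4, 4, 4, 8))
        res = shuffle_significance(D, "sound", n_shuffles=200, seed=4)
        # 99th-percentile threshold: a handful of false positives at most
        assert res.n_significant <= 1

    def test_planted_sound_signal_detected(self, rng):
        # strong sound-locked rank-1 structure shared by both halves
        latent = rng.standard_normal((8, 5))        # time x sound
        load = rng.standard_normal(10)
        D = rng.standard_normal((8, 3, 5, 4, 10)) * 0.1
        D += np.einsum("ta,c->tac", latent, load)[:, None, :, None, :]
        res = shuffle_significance(D, "sound", n_shuffles=200, seed=5)
        assert res.n_significant == 1

    def test_too_few_shuffles_rejected(self, rng):
        with pytest.raises(ValueError):
            shuffle_significance(rng.standard_normal((2, 2, 2, 2, 1)),
                                 "sound", n_shuffles=10)


class TestTimecourse:
    def test_sign_convention_makes_output_flip_invariant(self, rng):
        a = rng.standard_normal((6, 4, 5))
        res = cvpca_spectrum(a, a)
        tc = pc_timecourse(res, 0, "train")
        flipped = cvpca.CvPcaResult(
            W=-res.W, train_projections=-res.train_projections,
            vhat=res.vhat, normalized_spectrum=res.normalized_spectrum,
            n_components=res.n_components, comp_train=res.comp_train,
            comp_test=res.comp_test)
        np.testing.assert_allclose(pc_timecourse(flipped, 0, "train"), tc,
                                   atol=1e-12)

    def test_train_and_full_agree_when_noise_free(self, rng):
        comp = rng.standard_normal((6, 4, 5))
        res = cvpca_spectrum(comp, comp)
        tr = pc_timecourse(res, 0, "train")
        full = pc_timecourse(res, 0, "full", comp_full=comp)
        np.testing.assert_allclose(tr, full, atol=1e-12)

    def test_rank1_planted_matrix_timecourse(self):
        # rank-1 component with all-positive loadings and light noise: the
        # PC1 time course reproduces the planted latent almost exactly
        rng = np.random.default_rng(21)
        latent = rng.standard_normal((40, 6))        # time x stim
        load = np.abs(rng.normal(1.0, 0.3, 12))
        comp = np.einsum("ts,c->tsc", latent, load)
        tr = comp + 0.05 * rng.standard_normal(comp.shape)
        te = comp + 0.05 * rng.standard_normal(comp.shape)
        res = cvpca_spectrum(tr, te)
        tc = pc_timecourse(res, 0, "full", comp_full=comp)
        planted = comp.transpose(1, 0, 2)[..., 0].reshape(-1) / load[0]
        assert np.corrcoef(tc, planted)[0, 1] > 0.99

    def test_rank1_timecourse_tracks_planted_latent(self, full_session,
                                                    full_tensor):
        split = odd_even_split(4)
        tr, te = component_halves(full_tensor, "sound", split)
        res = cvpca_spectrum(tr, te)
        m = __import__("avcortex.marginalize", fromlist=["marginalize"])
        comp_full = m.marginalize(full_tensor).A
        tc = pc_timecourse(res, 0, "full", comp_full=comp_full)
        # oracle: the generator's per-sound latent drive passed through the
        # same forward model the pipeline sees (lead-time delay + causal
        # half-Gaussian smoothing of the binned rates)
        from avcortex.preprocess import BIN_SIZE, SMOOTH_SIGMA, \
            smooth_causal_half_gaussian
        truth = full_session.truth
        times = full_tensor.times + full_tensor.bin_size / 2 - truth.lead_time
        kern_t = np.arange(truth.sound_kernels.shape[2]) * truth.kernel_dt
        planted = np.stack([
            np.interp(times, kern_t, truth.sound_kernels[0, a],
                      left=0.0, right=0.0)
            for a in range(truth.n_sounds)])
        planted = smooth_causal_half_gaussian(planted, SMOOTH_SIGMA, BIN_SIZE)
        planted -= planted.mean(axis=0)           # sound-marginal convention
        r = np.corrcoef(tc, planted.reshape(-1))[0, 1]
        # end-to-end the match is strong but not perfect: spiking rectifies
        # at zero, so the realized drive is a mildly distorted copy
        assert r > 0.85


def test_normalize_spectra_modes(rng):
    spectra = {"sound": np.array([3.0, 1.0]), "video": np.array([4.0, 2.0])}
    within = cvpca.normalize_spectra(spectra, "within")
    assert np.isclose(within["sound"].sum(), 1.0)
    assert np.isclose(within["video"].sum(), 1.0)
    both = cvpca.normalize_spectra(spectra, "all")
    assert np.isclose(sum(v.sum() for v in both.values()), 1.0)
    with pytest.raises(ValueError):
        cvpca.normalize_spectra(spectra, "nope")


class TestFisher:
    def test_equal_values_pass_through(self):
        assert np.isclose(fisher_mean_correlation([0.4, 0.4, 0.4]), 0.4)

    def test_symmetric_values_cancel(self):
        assert np.isclose(fisher_mean_correlation([0.5, -0.5]), 0.0)

    def test_closed_form(self):
        expect = np.tanh((np.arctanh(0.9) + np.arctanh(0.3)) / 2)
        assert np.isclose(fisher_mean_correlation([0.9, 0.3]), expect)

    def test_saturated_coefficients_excluded(self):
        with pytest.warns(UserWarning, match="excluding"):
            out = fisher_mean_correlation([1.0, 0.5])
        assert np.isclose(out, 0.5)
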