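"""Design-matrix structure, ridge fitting, target projection, evaluation
metrics, and the pixel weight map."""

import numpy as np
import pytest

from avcortex import encode
from avcortex.cvpca import odd_even_split
from avcortex.encode import (
    LAGS, N_ENC_BINS, PAD, build_design,
    evaluate_noise_correlation, evaluate_trial_average, fit_ridge,
    full_data_basis, pixel_weight_map, project_target, weights_by_channel_lag,
    _ridge_solve_path,
)
from avcortex.marginalize import marginalize
from avcortex.preprocess import BIN_SIZE, WINDOW, TrialTensor


EXT_WINDOW = (WINDOW[0], WINDOW[1] + int(LAGS.max()) * BIN_SIZE)
EXT_BINS = int(round((EXT_WINDOW[1] - EXT_WINDOW[0]) / BIN_SIZE))


def _behav_tensor(rng, n_v, n_a, n_r, n_ch):
    data = rng.standard_normal((EXT_BINS, n_v, n_a, n_r, n_ch))
    return TrialTensor(data, window=EXT_WINDOW, channel_kind="behavioral",
                       channel_ids=[f"ch{i}" for i in range(n_ch)])


class TestDesignStructure:
    def test_auditory_indicator_structure(self):
        X = build_design("auditory", 3, 4, 2)
        n_trials = 3 * 4 * 2
        assert X.values.shape == ((N_ENC_BINS + 2 * PAD) * n_trials,
                                  4 * N_ENC_BINS)
        intrial = X.in_trial
        rows = X.values[intrial]
        assert np.nansum(rows, axis=1).max() == 1.0
        assert (np.nansum(rows, axis=1) == 1).all()
        assert np.isnan(X.values[~intrial]).all()
        # the active column encodes (sound of the trial, peristimulus bin)
        r0 = np.nonzero(intrial)[0][0]
        col = int(np.nanargmax(X.values[r0]))
        sound = X.trial_labels["sound_id"].iloc[X.row_trial[r0]]
        assert X.column_spec[col] == ("aud", sound, X.row_bin[r0])

    def test_behavioral_lag_structure(self, rng):
        B = _behav_tensor(rng, 2, 2, 1, 3)
        X = build_design("behavioral", behavioral=B)
        assert X.values.shape[1] == 3 * len(LAGS)
        intrial = X.in_trial
        assert not np.isnan(X.values[intrial]).any()
        assert np.isnan(X.values[~intrial]).all()

    def test_lagged_columns_are_shifts_of_each_other(self, rng):
        B = _behav_tensor(rng, 1, 2, 1, 1)
        X = build_design("behavioral", behavioral=B)
        lag_of = {s[2]: i for i, s in enumerate(X.column_spec)}
        base = X.values[X.in_trial, lag_of[0]]
        n = N_ENC_BINS
        for lag in (1, 3, -2):
            shifted = X.values[X.in_trial, lag_of[lag]]
            # within one trial, the lag-l column equals the lag-0 column
            # displaced by l bins (positive lag looks further back in time)
            s0 = base[:n]
            s1 = shifted[:n]
            if lag > 0:
                np.testing.assert_allclose(s1[lag:], s0[:-lag], atol=1e-12)
            else:
                np.testing.assert_allclose(s1[:lag], s0[-lag:], atol=1e-12)

    def test_full_is_concatenation(self, rng):
        B = _behav_tensor(rng, 2, 2, 2, 4)
        aud = build_design("auditory", 2, 2, 2)
        beh = build_design("behavioral", behavioral=B)
        full = build_design("full", 2, 2, 2, behavioral=B)
        assert full.values.shape[1] == aud.values.shape[1] + beh.values.shape[1]
        np.testing.assert_array_equal(full.values[:, :aud.values.shape[1]],
                                      aud.values)

    def test_lag_span_exceeding_pad_rejected(self, rng):
        with pytest.raises(ValueError, match="pad"):
            build_design("auditory", 2, 2, 1, lags=np.arange(-3, 20), pad=12)


class TestProjectTarget:
    def _tensor(self, rng, n_c=5):
        data = rng.standard_normal((160, 3, 4, 2, n_c))
        return TrialTensor(data)

    def test_pure_video_tensor_projects_to_zero(self, rng):
        M = rng.standard_normal((160, 4))
        V = rng.standard_normal((160, 3, 4))
        V -= V.mean(axis=1, keepdims=True)
        data = (M[:, None, None, None, :]
                + np.broadcast_to(V[:, :, None, None, :], (160, 3, 2, 2, 4)))
        D = TrialTensor(np.ascontiguousarray(data))
        marg = marginalize(D)
        W = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        Y = project_target(D, marg, W)
        np.testing.assert_allclose(np.nan_to_num(Y), 0.0, atol=1e-9)

    def test_rank1_sound_tensor_loads_on_first_component(self, rng):
        A = rng.standard_normal((160, 4))
        A -= A.mean(axis=1, keepdims=True)
        load = rng.standard_normal(5)
        data = np.einsum("ta,c->tac", A, load)[:, None, :, None, :]
        data = np.broadcast_to(data, (160, 2, 4, 2, 5))
        D = TrialTensor(np.ascontiguousarray(data))
        marg = marginalize(D)
        W = full_data_basis(D, "sound", 3)
        Y = project_target(D, marg, W)
        ok = ~np.isnan(Y[:, 0])
        assert np.sum(Y[ok, 1:] ** 2) < 1e-9 * np.sum(Y[ok, 0] ** 2)

    def test_matches_brute_force_loop(self, rng):
        D = self._tensor(rng)
        marg = marginalize(D)
        W = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        Y = project_target(D, marg, W)
        rpt = N_ENC_BINS + 2 * PAD
        onset = D.onset_bin
        i = 0
        for v in range(3):
            for a in range(4):
                for r in range(2):
                    for j in range(rpt):
                        row = Y[i * rpt + j]
                        t = j - PAD
                        if t < 0 or t >= N_ENC_BINS:
                            assert np.isnan(row).all()
                        else:
                            ref = (D.data[onset + t, v, a, r, :]
                                   - marg.M[onset + t, :]
                                   - marg.V[onset + t, v, :]) @ W
                            np.testing.assert_allclose(row, ref, atol=1e-10)
                    i += 1


class TestRidge:
    def test_ols_limit_recovers_weights_exactly(self, rng):
        B_true = rng.standard_normal((3 * len(LAGS), 2))
        Bt = _behav_tensor(rng, 2, 2, 4, 3)
        X = build_design("behavioral", behavioral=Bt)
        Y = np.where(np.isnan(X.values[:, :1]), np.nan, X.values @ np.nan_to_num(B_true))
        fit = fit_ridge(X, Y, lambda_grid=np.array([1e-10]))
        np.testing.assert_allclose(fit.B, B_true, atol=1e-6)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.standard_normal((50, 8))
        Y = rng.standard_normal((50, 2))
        grid = np.array([0.1, 1.0, 10.0, 100.0])
        norms = [np.linalg.norm(B) for B in _ridge_solve_path(X, Y, grid)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lambda_selected_from_grid_and_pads_excluded(self, rng):
        Bt = _behav_tensor(rng, 2, 2, 4, 2)
        X = build_design("behavioral", behavioral=Bt)
        Y = np.where(np.isnan(X.values[:, :1]), np.nan,
                     rng.standard_normal((X.values.shape[0], 2)))
        fit = fit_ridge(X, Y)
        assert fit.lambda_selected in encode.DEFAULT_LAMBDA_GRID

    def test_planted_lag_kernel_recovered_and_shift_convention(self, rng):
        # one behavioral channel driving Y at a known lag; shifting the
        # channel by +k bins moves the recovered peak by -k lags exactly
        n_v, n_a, n_r = 2, 2, 4
        for shift in (0, 2):
            data = rng.standard_normal((EXT_BINS, n_v, n_a, n_r, 1))
            B = TrialTensor(data, window=EXT_WINDOW, channel_kind="behavioral",
                            channel_ids=["x"])
            X = build_design("behavioral", behavioral=B)
            lag_cols = {s[2]: i for i, s in enumerate(X.column_spec)}
            planted_lag = 4
            y = X.values[:, [lag_cols[planted_lag - shift]]].copy()
            fit = fit_ridge(X, y, lambda_grid=np.array([1e-8]))
            w, chans = weights_by_channel_lag(fit, X)
            assert LAGS[int(np.argmax(np.abs(w[0])))] == planted_lag - shift


class TestEvaluation:
    def _setup(self, rng):
        Bt = _behav_tensor(rng, 2, 3, 4, 2)
        X = build_design("behavioral", behavioral=Bt)
        Y = np.where(np.isnan(X.values[:, :1]), np.nan,
                     rng.standard_normal((X.values.shape[0], 2)))
        split = odd_even_split(4)
        return X, Y, split

    def test_perfect_prediction_gives_unit_correlations(self, rng):
        # an identity design whose values are Y itself: prediction == data
        X, Y, split = self._setup(rng)
        Xid = encode.DesignMatrix(
            values=Y.copy(), column_spec=[("beh", "a", 0), ("beh", "b", 0)],
            kind="behavioral", trial_labels=X.trial_labels,
            row_trial=X.row_trial, row_bin=X.row_bin, lags=np.array([0]))
        perfect = encode.EncodingFit(B=np.eye(2), lambda_selected=0.0,
                                     lambda_grid=np.array([0.0]),
                                     cv_mse=np.array([0.0]), kind="behavioral")
        assert np.isclose(evaluate_trial_average(perfect, Xid, Y, split), 1.0)
        assert np.isclose(evaluate_noise_correlation(perfect, Xid, Y, split), 1.0)

    def test_zero_prediction_is_undefined(self, rng):
        X, Y, split = self._setup(rng)
        fit = encode.EncodingFit(B=np.zeros((X.values.shape[1], 2)),
                                 lambda_selected=1.0,
                                 lambda_grid=np.array([1.0]),
                                 cv_mse=np.array([0.0]), kind="behavioral")
        with pytest.warns(UserWarning):
            out = evaluate_trial_average(fit, X, Y, split)
        assert np.isnan(out)

    def test_repeat_constant_prediction_has_undefined_noise_corr(self, rng):
        # the auditory design predicts identically across repeats of a sound,
        # so its residual after per-sound means is structurally zero
        X = build_design("auditory", 2, 3, 4)
        rngl = np.random.default_rng(5)
        Y = np.where(np.isnan(X.values[:, :1]), np.nan,
                     rngl.standard_normal((X.values.shape[0], 2)))
        split = odd_even_split(4)
        fit = fit_ridge(X, Y, lambda_grid=np.array([1e-6]), split=split)
        with pytest.warns(UserWarning, match="noise"):
            out = evaluate_noise_correlation(fit, X, Y, split)
        assert np.isnan(out)


class TestPixelMap:
    def test_one_hot_returns_that_mask(self, rng):
        masks = rng.standard_normal((6, 4, 4))
        b = np.zeros(6)
        b[2] = 1.0
        np.testing.assert_array_equal(pixel_weight_map(b, masks), masks[2])

    def test_zero_weights_zero_image(self, rng):
        masks = rng.standard_normal((3, 5, 5))
        assert (pixel_weight_map(np.zeros(3), masks) == 0).all()

    def test_matches_per_pixel_summation_oracle(self, rng):
        masks = rng.standard_normal((4, 3, 2))
        b = rng.standard_normal(4)
        img = pixel_weight_map(b, masks)
        for i in range(3):
            for j in range(2):
                assert np.isclose(img[i, j],
                                  sum(b[k] * masks[k, i, j] for k in range(4)))

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pixel_weight_map(np.zeros(3), rng.standard_normal((4, 2, 2)))
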