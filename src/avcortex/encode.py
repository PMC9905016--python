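"""Ridge encoding models of sound-related population activity.

The target ``Y`` is the single-trial sound-plus-noise activity: the trial
tensor minus its grand-mean and video components, restricted to the 127
post-onset bins, projected onto the top sound-related PCs computed from the
full dataset. Three predictor sets are compared:

* **auditory** — one indicator column per (sound, peristimulus bin); with
  12 sounds and 127 bins this is 1,524 columns, and the ridge fit is
  essentially a train-half repeat average per sound;
* **behavioral** — sound-marginalized behavioral channels (9 eye channels +
  face motion PCs) at 12 bin lags each (with 128 motion PCs: 1,644
  columns);
* **full** — the horizontal concatenation (3,168 columns at full scale).

Rows are laid out trial-major (trials ordered video-major, then sound, then
repeat), 127 in-trial rows flanked by 12 NaN pad rows at each trial edge so
temporal filters never straddle trials; pad rows are excluded from fitting
and evaluation. The ridge penalty is selected by 3-fold cross-validation
over contiguous blocks of training trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .cvpca import SplitSpec, fisher_mean_correlation, odd_even_split
from .marginalize import MarginalComponents, component_matrix, marginalize
from .preprocess import TrialTensor

__all__ = [
    "N_ENC_BINS",
    "LAGS",
    "PAD",
    "DesignMatrix",
    "EncodingFit",
    "full_data_basis",
    "build_design",
    "project_target",
    "fit_ridge",
    "evaluate_trial_average",
    "evaluate_noise_correlation",
    "crossval_encoding",
    "pixel_weight_map",
    "weights_by_channel_lag",
    "DEFAULT_LAMBDA_GRID",
]

N_ENC_BINS = 127
#: predictor at lag ``l`` holds the channel's value ``l`` bins *before* the
#: predicted time point (positive lag = behavior precedes neural activity);
#: 12 lags, -3..+8 bins = -90..+240 ms at 30 ms
LAGS = np.arange(-3, 9)
PAD = 12
DEFAULT_LAMBDA_GRID = np.logspace(-3, 5, 9)


@dataclass
class DesignMatrix:
    """Predictor matrix with column provenance and trial-row bookkeeping.

    ``values`` is (rows x columns) with NaN on the 12 pad rows at each
    trial's start and end. ``column_spec`` holds one tuple per column:
    ``("aud", sound_id, peristimulus_bin)`` or ``("beh", channel, lag)``.
    ``trial_labels`` has one row per trial (video_id, sound_id, repeat) in
    row-block order; ``row_trial``/``row_bin`` map each row to its trial and
    encoding bin (-1 on pads).
    """

    values: np.ndarray
    column_spec: list
    kind: str
    trial_labels: pd.DataFrame
    row_trial: np.ndarray
    row_bin: np.ndarray
    lags: np.ndarray | None = None
    pad: int = PAD
    n_enc_bins: int = N_ENC_BINS

    @property
    def rows_per_trial(self) -> int:
        return self.n_enc_bins + 2 * self.pad

    @property
    def in_trial(self) -> np.ndarray:
        return self.row_bin >= 0


def _trial_frame(n_videos: int, n_sounds: int, n_repeats: int) -> pd.DataFrame:
    v, a, r = np.meshgrid(np.arange(n_videos), np.arange(n_sounds),
                          np.arange(n_repeats), indexing="ij")
    return pd.DataFrame({
        "video_id": v.ravel(), "sound_id": a.ravel(), "repeat": r.ravel(),
    })


def _row_maps(n_trials: int, n_enc: int, pad: int) -> tuple[np.ndarray, np.ndarray]:
    rpt = n_enc + 2 * pad
    row_trial = np.repeat(np.arange(n_trials), rpt)
    within = np.tile(np.arange(rpt), n_trials)
    row_bin = within - pad
    row_bin[(row_bin < 0) | (row_bin >= n_enc)] = -1
    return row_trial, row_bin


def build_design(
    kind: str,
    n_videos: int | None = None,
    n_sounds: int | None = None,
    n_repeats: int | None = None,
    behavioral: TrialTensor | None = None,
    behavioral_marg: MarginalComponents | None = None,
    n_enc_bins: int = N_ENC_BINS,
    lags: np.ndarray = LAGS,
    pad: int = PAD,
) -> DesignMatrix:
    """Build the auditory, behavioral, or full design matrix.

    For behavioral predictors pass the behavioral trial tensor; its channels
    are first marginalized to their sound-related single-trial modulations
    (tensor minus grand-mean and video components) before lagging. The
    tensor's window must extend at least ``max(lags)`` bins past the last
    encoding bin and ``-min(lags)`` bins before onset so that no in-trial
    predictor value is missing.
    """
    lags = np.asarray(lags)
    if pad < lags.max() or pad < -lags.min():
        raise ValueError("lag span exceeds the pad length")

    if kind == "auditory":
        if None in (n_videos, n_sounds, n_repeats):
            raise ValueError("auditory design needs n_videos, n_sounds, n_repeats")
        trials = _trial_frame(n_videos, n_sounds, n_repeats)
        n_trials = len(trials)
        row_trial, row_bin = _row_maps(n_trials, n_enc_bins, pad)
        vals = np.zeros((len(row_trial), n_sounds * n_enc_bins))
        intrial = row_bin >= 0
        sound_of_row = trials["sound_id"].to_numpy()[row_trial]
        cols = sound_of_row[intrial] * n_enc_bins + row_bin[intrial]
        vals[np.nonzero(intrial)[0], cols] = 1.0
        vals[~intrial] = np.nan
        spec = [("aud", a, t) for a in range(n_sounds) for t in range(n_enc_bins)]
        return DesignMatrix(vals, spec, "auditory", trials, row_trial, row_bin,
                            lags=None, pad=pad, n_enc_bins=n_enc_bins)

    if kind == "behavioral":
        if behavioral is None:
            raise ValueError("behavioral design needs the behavioral trial tensor")
        data = behavioral.data
        n_tb, n_v, n_a, n_r, n_ch = data.shape
        n_pre = behavioral.onset_bin
        marg = behavioral_marg if behavioral_marg is not None else marginalize(data)
        # sound-related single-trial modulation of each behavioral channel
        resid = (data - marg.M[:, None, None, None, :]
                 - marg.V[:, :, None, None, :])
        per_trial = resid.transpose(1, 2, 3, 0, 4).reshape(-1, n_tb, n_ch)
        trials = _trial_frame(n_v, n_a, n_r)
        n_trials = len(trials)
        row_trial, row_bin = _row_maps(n_trials, n_enc_bins, pad)
        rpt = n_enc_bins + 2 * pad
        vals = np.full((n_trials * rpt, n_ch * len(lags)), np.nan)
        intrial_bins = np.arange(n_enc_bins)
        for li, lag in enumerate(lags):
            src = n_pre + intrial_bins - lag
            ok = (src >= 0) & (src < n_tb)
            block = np.full((n_trials, n_enc_bins, n_ch), np.nan)
            block[:, ok, :] = per_trial[:, src[ok], :]
            full = np.full((n_trials, rpt, n_ch), np.nan)
            full[:, pad:pad + n_enc_bins, :] = block
            vals[:, li::len(lags)] = full.reshape(-1, n_ch)
        ids = behavioral.channel_ids or list(range(n_ch))
        spec = [("beh", ids[c], int(l)) for c in range(n_ch) for l in lags]
        return DesignMatrix(vals, spec, "behavioral", trials, row_trial, row_bin,
                            lags=lags, pad=pad, n_enc_bins=n_enc_bins)

    if kind == "full":
        aud = build_design("auditory", n_videos, n_sounds, n_repeats,
                           n_enc_bins=n_enc_bins, lags=lags, pad=pad)
        beh = build_design("behavioral", behavioral=behavioral,
                           behavioral_marg=behavioral_marg,
                           n_enc_bins=n_enc_bins, lags=lags, pad=pad)
        if len(aud.trial_labels) != len(beh.trial_labels):
            raise ValueError("auditory and behavioral designs disagree on trials")
        vals = np.hstack([aud.values, beh.values])
        return DesignMatrix(vals, aud.column_spec + beh.column_spec, "full",
                            aud.trial_labels, aud.row_trial, aud.row_bin,
                            lags=lags, pad=pad, n_enc_bins=n_enc_bins)

    raise ValueError(f"unknown design kind {kind!r}")


def full_data_basis(D: TrialTensor | np.ndarray, kind: str = "sound",
                    n_components: int = 4) -> np.ndarray:
    """PCA weight matrix (channels x n_components) of a stimulus-related
    component computed from the *full* dataset (all repeats)."""
    comp = marginalize(D).component(kind)
    X = component_matrix(comp)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    return Vt[:n_components].T


def project_target(
    D: TrialTensor | np.ndarray,
    marg: MarginalComponents,
    W_full: np.ndarray,
    n_components: int | None = None,
    n_enc_bins: int = N_ENC_BINS,
    pad: int = PAD,
    onset_bin: int | None = None,
) -> np.ndarray:
    """Single-trial sound-plus-noise activity in the auditory PC basis.

    Computes ``D - M - V``, keeps the ``n_enc_bins`` post-onset bins,
    reorders rows to match the design-matrix layout (trial-major,
    video/sound/repeat nested, with NaN pad rows), and projects channels
    onto ``W_full`` columns.
    """
    data = D.data if isinstance(D, TrialTensor) else np.asarray(D)
    if onset_bin is None:
        onset_bin = D.onset_bin if isinstance(D, TrialTensor) else 0
    n_p = W_full.shape[1] if n_components is None else n_components
    if W_full.shape[0] != data.shape[-1]:
        raise ValueError("W_full rows must match the tensor's channel count")
    resid = (data - marg.M[:, None, None, None, :]
             - marg.V[:, :, None, None, :])
    post = resid[onset_bin:onset_bin + n_enc_bins]
    if post.shape[0] != n_enc_bins:
        raise ValueError("tensor window too short for the encoding bins")
    per_trial = post.transpose(1, 2, 3, 0, 4).reshape(-1, n_enc_bins, data.shape[-1])
    proj = per_trial @ W_full[:, :n_p]
    n_trials = proj.shape[0]
    rpt = n_enc_bins + 2 * pad
    out = np.full((n_trials, rpt, n_p), np.nan)
    out[:, pad:pad + n_enc_bins, :] = proj
    return out.reshape(-1, n_p)


# ---------------------------------------------------------------------------
# ridge fitting
# ---------------------------------------------------------------------------

@dataclass
class EncodingFit:
    B: np.ndarray
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray          # (n_lambda,) mean over folds
    kind: str


def _ridge_solve_path(X: np.ndarray, Y: np.ndarray, grid: np.ndarray) -> list[np.ndarray]:
    """Ridge solutions for every penalty via one eigendecomposition of X'X."""
    G = X.T @ X
    XtY = X.T @ Y
    evals, Q = eigh(G)
    QtXtY = Q.T @ XtY
    return [Q @ (QtXtY / (evals + lam)[:, None]) for lam in grid]


def fit_ridge(
    X: DesignMatrix,
    Y: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    split: SplitSpec | None = None,
    n_folds: int = 3,
    seed: int | None = None,
) -> EncodingFit:
    """Ridge regression of Y on the design, penalty chosen by inner CV.

    Fits on the training half of the trials only (pad/NaN rows dropped).
    The penalty is selected by ``n_folds``-fold cross-validation over
    contiguous blocks of training trials and the model is refit on the
    whole training half at the selected penalty. Deterministic; ``seed`` is
    accepted for interface symmetry but the procedure draws no random
    numbers.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    if split is None:
        split = odd_even_split(int(X.trial_labels["repeat"].max()) + 1)
    repeats = X.trial_labels["repeat"].to_numpy()
    train_trials = np.nonzero(np.isin(repeats, split.train_repeats))[0]

    finite = ~np.isnan(X.values).any(axis=1) & ~np.isnan(Y).any(axis=1)
    col_sums = np.nansum(np.abs(X.values), axis=0)
    if (col_sums == 0).any():
        warnings.warn(f"{int((col_sums == 0).sum())} all-zero design column(s) retained")

    blocks = np.array_split(train_trials, n_folds)
    mse = np.zeros((n_folds, len(lambda_grid)))
    for f, val_trials in enumerate(blocks):
        fit_trials = np.concatenate([b for g, b in enumerate(blocks) if g != f])
        fit_rows = finite & np.isin(X.row_trial, fit_trials)
        val_rows = finite & np.isin(X.row_trial, val_trials)
        Bs = _ridge_solve_path(X.values[fit_rows], Y[fit_rows], lambda_grid)
        for i, B in enumerate(Bs):
            resid = X.values[val_rows] @ B - Y[val_rows]
            mse[f, i] = np.mean(resid ** 2)
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))

    train_rows = finite & np.isin(X.row_trial, train_trials)
    B = _ridge_solve_path(X.values[train_rows], Y[train_rows],
                          lambda_grid[best:best + 1])[0]
    return EncodingFit(B=B, lambda_selected=float(lambda_grid[best]),
                       lambda_grid=lambda_grid, cv_mse=mean_mse, kind=X.kind)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance matrix; correlation undefined")
        return float("nan")
    return float(a @ b / (na * nb))


def _test_rows_and_means(X: DesignMatrix, Y: np.ndarray, fit: EncodingFit,
                         split: SplitSpec):
    repeats = X.trial_labels["repeat"].to_numpy()
    test_trials = np.isin(repeats, split.test_repeats)
    rows = (~np.isnan(X.values).any(axis=1) & ~np.isnan(Y).any(axis=1)
            & test_trials[X.row_trial])
    pred = X.values[rows] @ fit.B
    y = Y[rows]
    sound = X.trial_labels["sound_id"].to_numpy()[X.row_trial[rows]]
    tbin = X.row_bin[rows]
    return y, pred, sound, tbin


def _group_mean(values: np.ndarray, sound: np.ndarray, tbin: np.ndarray,
                n_sounds: int, n_bins: int) -> np.ndarray:
    out = np.zeros((n_sounds * n_bins, values.shape[1]))
    cnt = np.zeros(n_sounds * n_bins)
    g = sound * n_bins + tbin
    np.add.at(out, g, values)
    np.add.at(cnt, g, 1)
    cnt[cnt == 0] = 1
    return out / cnt[:, None]


def evaluate_trial_average(
    fit: EncodingFit,
    X: DesignMatrix,
    Y: np.ndarray,
    split: SplitSpec,
    per_component: bool = False,
):
    """Pearson correlation between per-sound test-set averages of the data
    and of the prediction (pooled over components by default)."""
    y, pred, sound, tbin = _test_rows_and_means(X, Y, fit, split)
    n_a = int(X.trial_labels["sound_id"].max()) + 1
    ym = _group_mean(y, sound, tbin, n_a, X.n_enc_bins)
    pm = _group_mean(pred, sound, tbin, n_a, X.n_enc_bins)
    if per_component:
        return np.array([_pearson_flat(ym[:, p], pm[:, p]) for p in range(ym.shape[1])])
    return _pearson_flat(ym, pm)


def evaluate_noise_correlation(
    fit: EncodingFit,
    X: DesignMatrix,
    Y: np.ndarray,
    split: SplitSpec,
) -> float:
    """Correlation of trial-to-trial fluctuations: per-sound test means are
    subtracted from both data and prediction before the pooled Pearson
    correlation. A prediction constant across repeats of a sound (the
    auditory model) has zero residual and returns NaN."""
    y, pred, sound, tbin = _test_rows_and_means(X, Y, fit, split)
    n_a = int(X.trial_labels["sound_id"].max()) + 1
    g = sound * X.n_enc_bins + tbin
    ym = _group_mean(y, sound, tbin, n_a, X.n_enc_bins)
    pm = _group_mean(pred, sound, tbin, n_a, X.n_enc_bins)
    y_res = y - ym[g]
    p_res = pred - pm[g]
    if np.sum(p_res ** 2) < 1e-12 * max(1.0, np.sum(y_res ** 2)):
        warnings.warn("prediction has no trial-to-trial variability; "
                      "noise correlation undefined")
        return float("nan")
    return _pearson_flat(y_res, p_res)


def crossval_encoding(
    X: DesignMatrix,
    Y: np.ndarray,
    split: SplitSpec,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> dict:
    """Fit on each half in turn, evaluate on the other, Fisher-z average."""
    ta, nc, lams = [], [], []
    for sp in (split, split.swapped()):
        fit = fit_ridge(X, Y, lambda_grid=lambda_grid, split=sp)
        ta.append(evaluate_trial_average(fit, X, Y, sp))
        nc.append(evaluate_noise_correlation(fit, X, Y, sp))
        lams.append(fit.lambda_selected)
    return {
        "trial_average_corr": fisher_mean_correlation(ta),
        "noise_corr": fisher_mean_correlation(nc),
        "fold_trial_average": ta,
        "fold_noise": nc,
        "lambda_selected": lams,
    }


# ---------------------------------------------------------------------------
# weight inspection
# ---------------------------------------------------------------------------

def weights_by_channel_lag(fit: EncodingFit, X: DesignMatrix,
                           component: int = 0) -> tuple[np.ndarray, list]:
    """Behavioral weights reshaped to (n_channels, n_lags) for one target
    component; returns (weights, channel ids)."""
    beh_cols = [i for i, s in enumerate(X.column_spec) if s[0] == "beh"]
    if not beh_cols:
        raise ValueError("design has no behavioral columns")
    n_lags = len(X.lags)
    chans = [X.column_spec[i][1] for i in beh_cols[::n_lags]]
    w = fit.B[beh_cols, component].reshape(len(chans), n_lags)
    return w, chans


def pixel_weight_map(b0_body: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Image of pixel-to-neural weights: weighted sum of the per-motion-PC
    spatial masks, ``I = b0_body . omega``."""
    b0_body = np.asarray(b0_body, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if b0_body.shape[0] != omega.shape[0]:
        raise ValueError("weight count does not match mask count")
    return np.tensordot(b0_body, omega, axes=1)
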