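"""Movement-related neural subspace, its overlap with the sound subspace,
and movement-vs-neural timing.

The movement-related subspace is estimated from the stimulus-free
(spontaneous) epoch by reduced-rank regression (RRR) of the neural
population matrix on the lagged face-motion PCs (128 PCs x 21 lags = 2,688
columns at full scale), both binned at the camera frame rate. The
channel-space factor of the rank-``r`` fit (default r = 40) gives an
orthonormal basis ``C`` of the subspace. Projecting the train- and
test-half sound-related components onto ``C`` and taking the per-dimension
test-retest covariance measures how much reliable sound-related variance
lives inside the movement subspace; the overlap ratio divides the variance
captured by the first 4 movement dimensions by that captured by the first 4
sound-related PCs, and is compared against the 95th percentile of the same
ratio for random orthonormal subspaces.

Timing is measured two ways on the spontaneous epoch: the lag of the peak
of the motion-PC1 x neural-sound-PC1 cross-correlogram, and the lag of the
largest-magnitude ridge weight of motion PC1 when predicting the neural
sound PC1 from lagged motion PCs. Positive lags mean movement precedes
neural activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cvpca import CvPcaResult

__all__ = [
    "RrrFit",
    "OverlapResult",
    "build_lagged_motion",
    "fit_rrr",
    "subspace_overlap",
    "xcorr_lag",
    "ridge_lagged_weights",
    "weight_peak_delay",
]

N_LAGS = 21
DEFAULT_RANK = 40


def build_lagged_motion(
    motion: np.ndarray, n_lags: int = N_LAGS
) -> tuple[np.ndarray, slice, np.ndarray]:
    """Lagged copies of each motion PC, lag grid centered on zero.

    ``motion`` is (n_frames, n_pcs) on the camera-rate grid restricted to
    the spontaneous epoch. Column (pc, lag) at row ``t`` holds the PC's
    value ``lag`` frames *earlier* (positive lag = motion precedes);
    columns are channel-major, lag-minor with lags -(n_lags//2)..+(n_lags//2).
    Edge rows that any lag would push outside the epoch are trimmed;
    returns (design, kept-row slice, lags).
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    n_frames, n_pcs = motion.shape
    half = n_lags // 2
    lags = np.arange(-half, n_lags - half)
    lo, hi = lags.max(), n_frames + lags.min()
    if hi - lo <= 0:
        raise ValueError("epoch shorter than the lag span")
    keep = slice(lo, hi)
    t = np.arange(lo, hi)
    X = np.empty((hi - lo, n_pcs * n_lags))
    for c in range(n_pcs):
        for li, l in enumerate(lags):
            X[:, c * n_lags + li] = motion[t - l, c]
    return X, keep, lags


@dataclass
class RrrFit:
    """Reduced-rank regression fit S ~ X B with B = L @ R of rank ``r``;
    ``C`` (channels x r) is the orthonormal channel-space basis."""

    B: np.ndarray
    C: np.ndarray
    rank: int
    singular_values: np.ndarray
    x_mean: np.ndarray
    s_mean: np.ndarray
    ridge: float


def fit_rrr(
    X: np.ndarray,
    S: np.ndarray,
    rank: int = DEFAULT_RANK,
    ridge: float = 0.0,
) -> RrrFit:
    """Classical RRR: OLS fit followed by SVD truncation of the fitted
    values; the top right-singular vectors give the channel-space basis.

    Columns of X and S are centered before fitting. A rank-deficient design
    is stabilized with a small recorded ridge penalty.
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if rank > min(X.shape[1], S.shape[1]):
        raise ValueError("rank exceeds min(n_predictors, n_channels)")
    x_mean = X.mean(axis=0)
    s_mean = S.mean(axis=0)
    Xc = X - x_mean
    Sc = S - s_mean
    G = Xc.T @ Xc
    used_ridge = ridge
    if used_ridge == 0.0:
        evals = np.linalg.eigvalsh(G)
        if evals[0] < 1e-10 * max(evals[-1], 1.0):
            used_ridge = 1e-8 * max(evals[-1], 1.0)
            warnings.warn(f"rank-deficient design; adding ridge {used_ridge:.3g}")
    if used_ridge:
        G = G + used_ridge * np.eye(G.shape[0])
    B_ols = np.linalg.solve(G, Xc.T @ Sc)
    F = Xc @ B_ols
    _, sv, Vt = np.linalg.svd(F, full_matrices=False)
    C = Vt[:rank].T
    B = B_ols @ C @ C.T
    return RrrFit(B=B, C=C, rank=rank, singular_values=sv[:rank],
                  x_mean=x_mean, s_mean=s_mean, ridge=used_ridge)


@dataclass
class OverlapResult:
    variance_along_behavior_dims: np.ndarray
    overlap_ratio: float
    random_threshold: float
    random_ratios: np.ndarray
    k: int


def _projected_covariance(A_train: np.ndarray, A_test: np.ndarray,
                          basis: np.ndarray) -> np.ndarray:
    Ttr = A_train @ basis
    Tte = A_test @ basis
    a = Ttr - Ttr.mean(axis=0)
    b = Tte - Tte.mean(axis=0)
    return (a * b).sum(axis=0) / (A_train.shape[0] - 1)


def subspace_overlap(
    A_train: np.ndarray,
    A_test: np.ndarray,
    C: np.ndarray,
    auditory_spectrum: CvPcaResult | np.ndarray,
    k: int = 4,
    n_random: int = 200,
    seed: int | np.random.Generator = 0,
) -> OverlapResult:
    """Sound-related variance inside the movement subspace, relative to the
    variance along the top-k sound-related PCs.

    ``A_train``/``A_test`` are the train/test sound-related components
    reshaped to (time*stimulus) x channels. The numerator is the summed
    test-retest covariance of their projections on the first ``k`` columns
    of ``C``; the denominator sums the first ``k`` auditory cvPCA
    covariances. The ratio is reported without clipping (noise can push it
    above 1). ``random_threshold`` is the 95th percentile of the same ratio
    for ``n_random`` uniformly random orthonormal k-dimensional subspaces.
    """
    if k > C.shape[1]:
        raise ValueError("k exceeds the rank of the movement subspace")
    vhat = (auditory_spectrum.vhat if isinstance(auditory_spectrum, CvPcaResult)
            else np.asarray(auditory_spectrum))
    if k > len(vhat):
        raise ValueError("k exceeds the number of auditory components")
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    denom = float(vhat[:k].sum())
    along = _projected_covariance(A_train, A_test, C)
    ratio = float(along[:k].sum() / denom)

    n_c = C.shape[0]
    rand = np.empty(n_random)
    for i in range(n_random):
        Q, _ = np.linalg.qr(rng.standard_normal((n_c, k)))
        rand[i] = _projected_covariance(A_train, A_test, Q).sum() / denom
    return OverlapResult(
        variance_along_behavior_dims=along,
        overlap_ratio=ratio,
        random_threshold=float(np.percentile(rand, 95)),
        random_ratios=rand,
        k=k,
    )


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def xcorr_lag(
    motion_pc1: np.ndarray,
    neural_pc1: np.ndarray,
    rate: float,
    max_lag: float = 2.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Peak lag of the normalized cross-correlogram over +-``max_lag`` s.

    The correlogram at lag L is corr(motion(t), neural(t + L)); a positive
    peak lag means movement precedes neural activity. Returns
    (lag_seconds, lags_seconds, correlogram).
    """
    x = np.asarray(motion_pc1, dtype=float)
    y = np.asarray(neural_pc1, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must share a common uniform time base")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series: cross-correlation undefined")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    max_shift = int(round(max_lag * rate))
    shifts = np.arange(-max_shift, max_shift + 1)
    c = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        if s >= 0:
            a, b = x[: len(x) - s], y[s:]
        else:
            a, b = x[-s:], y[: len(y) + s]
        c[i] = np.mean(a * b)
    lag = float(shifts[int(np.argmax(c))] / rate)
    return lag, shifts / rate, c


def ridge_lagged_weights(
    neural_pc1: np.ndarray,
    motion: np.ndarray,
    n_lags: int = N_LAGS,
    ridge: float | None = None,
    ridge_grid: np.ndarray = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge weights of each (motion PC, lag) predicting the neural sound
    PC1 on a common camera-rate grid; returns (weights (n_pcs, n_lags),
    lags in frames).

    When ``ridge`` is None the penalty is chosen from ``ridge_grid``
    (default 10^0..10^5) by 3-fold cross-validation over contiguous time
    blocks; spike-count targets are noisy enough that an unregularized
    solution scatters weight across collinear lags.
    """
    X, keep, lags = build_lagged_motion(motion, n_lags)
    y = np.asarray(neural_pc1, dtype=float)[keep]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()

    def solve(A, b, lam):
        return np.linalg.solve(A + lam * np.eye(A.shape[0]), b)

    if ridge is None:
        grid = np.logspace(0, 5, 6) if ridge_grid is None else np.asarray(ridge_grid)
        blocks = np.array_split(np.arange(len(yc)), 3)
        err = np.zeros(len(grid))
        for f, val in enumerate(blocks):
            fit = np.concatenate([b for g, b in enumerate(blocks) if g != f])
            A = Xc[fit].T @ Xc[fit]
            b = Xc[fit].T @ yc[fit]
            for i, lam in enumerate(grid):
                w = solve(A, b, lam)
                err[i] += np.mean((Xc[val] @ w - yc[val]) ** 2)
        ridge = float(grid[int(np.argmin(err))])
    w = solve(Xc.T @ Xc, Xc.T @ yc, ridge)
    return w.reshape(motion.shape[1], n_lags), lags


def weight_peak_delay(
    weights_pc1: np.ndarray,
    lags: np.ndarray,
    rate: float,
) -> float:
    """Delay (s) at which motion PC1 best predicts the neural sound PC1:
    the lag of the maximum-magnitude weight. Positive = movement precedes.
    Flat weights are degenerate and return NaN with a warning."""
    w = np.asarray(weights_pc1, dtype=float)
    if np.allclose(w, w[0]):
        warnings.warn("flat weight profile; peak delay undefined")
        return float("nan")
    return float(lags[int(np.argmax(np.abs(w)))] / rate)
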