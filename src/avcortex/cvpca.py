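"""Cross-validated PCA (cvPCA) signal-variance estimation.

PCA weights ``W`` are fit on the stimulus-related component of one half of
the repeats (odd presentations); projecting the other half's component onto
the same weights and taking the covariance of the paired projections gives
an unbiased estimate of the reliable (repeatable) stimulus-related variance
along each component — noise that is independent between halves averages
out, so estimates can even be slightly negative for noise-dominated
components and are deliberately not clipped.

Dimensionality is assessed by a shuffle test: stimulus labels of both
factors are permuted independently for each repeat, the test-retest
covariance recomputed, and a component declared significant when its real
covariance exceeds the 99th percentile of its null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .marginalize import component_matrix, marginalize
from .preprocess import TrialTensor

__all__ = [
    "SplitSpec",
    "CvPcaResult",
    "ShuffleResult",
    "odd_even_split",
    "component_halves",
    "cvpca_spectrum",
    "shuffle_significance",
    "pc_timecourse",
    "normalize_spectra",
    "fisher_mean_correlation",
]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive train/test repeat indices.

    By convention the training half contains the odd-numbered presentations
    (1st, 3rd, ... -> indices 0, 2, ...) and the test half the even ones.
    """

    train_repeats: tuple[int, ...]
    test_repeats: tuple[int, ...]

    def __post_init__(self):
        tr, te = set(self.train_repeats), set(self.test_repeats)
        if tr & te:
            raise ValueError("train and test repeats overlap")

    def swapped(self) -> "SplitSpec":
        return SplitSpec(self.test_repeats, self.train_repeats)


def odd_even_split(n_repeats: int) -> SplitSpec:
    reps = np.arange(n_repeats)
    return SplitSpec(tuple(reps[::2]), tuple(reps[1::2]))


def component_halves(
    D: TrialTensor | np.ndarray,
    kind: str,
    split: SplitSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-related component ('video'|'sound'|'interaction') computed
    separately within the train and test halves of the repeats."""
    data = D.data if isinstance(D, TrialTensor) else np.asarray(D)
    tr = marginalize(data[:, :, :, list(split.train_repeats), :]).component(kind)
    te = marginalize(data[:, :, :, list(split.test_repeats), :]).component(kind)
    return tr, te


@dataclass
class CvPcaResult:
    """cvPCA output: orthonormal channel weights ``W`` (channels x comps),
    train projections, per-component test-retest covariance ``vhat`` (may be
    negative), and the spectrum normalized to unit sum."""

    W: np.ndarray
    train_projections: np.ndarray
    vhat: np.ndarray
    normalized_spectrum: np.ndarray
    n_components: int
    comp_train: np.ndarray = field(repr=False, default=None)
    comp_test: np.ndarray = field(repr=False, default=None)


def _cross_covariance(T_train: np.ndarray, T_test: np.ndarray) -> np.ndarray:
    """Per-column covariance between paired projections, 1/(n-1), both
    columns centered across rows."""
    n = T_train.shape[0]
    a = T_train - T_train.mean(axis=0)
    b = T_test - T_test.mean(axis=0)
    return (a * b).sum(axis=0) / (n - 1)


def cvpca_spectrum(
    comp_train: np.ndarray,
    comp_test: np.ndarray,
    n_components: int | None = None,
) -> CvPcaResult:
    """PCA on the train-half component; covariance of paired projections.

    ``comp_train``/``comp_test`` are same-shape marginal components
    ``[t, *stim, c]``, each trial-averaged within its half. With
    ``n_components`` equal to the channel count the full spectrum is
    returned.
    """
    Xtr = component_matrix(comp_train)
    Xte = component_matrix(comp_test)
    if Xtr.shape != Xte.shape:
        raise ValueError("train and test components must have identical shape")
    n_ch = Xtr.shape[1]
    if n_components is None:
        n_components = min(Xtr.shape)
    if n_components > n_ch:
        raise ValueError("n_components exceeds channel count")
    # components are zero-mean across stimuli by construction; no extra
    # centering before the SVD
    _, _, Vt = np.linalg.svd(Xtr, full_matrices=False)
    W = Vt[:n_components].T
    T_train = Xtr @ W
    T_test = Xte @ W
    vhat = _cross_covariance(T_train, T_test)
    total = vhat.sum()
    norm = vhat / total if total != 0 else np.full_like(vhat, np.nan)
    return CvPcaResult(
        W=W,
        train_projections=T_train,
        vhat=vhat,
        normalized_spectrum=norm,
        n_components=n_components,
        comp_train=Xtr,
        comp_test=Xte,
    )


# ---------------------------------------------------------------------------
# shuffle test
# ---------------------------------------------------------------------------

@dataclass
class ShuffleResult:
    """Shuffle-test outcome.

    ``n_significant`` is the dimensionality estimate: the length of the
    leading block of significant components. Components are ordered by
    explained training variance, so an isolated exceedance deep in the
    noise floor — expected at the test's per-component false-positive rate
    (1% at the 99th percentile) — does not extend the signal subspace.
    ``n_significant_total`` counts every significant component regardless
    of position.
    """

    vhat: np.ndarray
    null: np.ndarray            # (n_shuffles, n_components)
    threshold: np.ndarray       # per-component null percentile
    significant: np.ndarray     # boolean mask
    n_significant: int          # leading significant block
    n_significant_total: int
    percentile: float


def _component_from_grouped(G: np.ndarray, kind: str, n_channels: int) -> np.ndarray:
    """Component matrix (stim-major, time-minor rows x channels) from a
    half-averaged, label-grouped array G of shape (v, a, t*c), whose flat
    axis is time-major, channel-minor."""
    M = G.mean(axis=(0, 1))
    if kind == "sound":
        comp = G.mean(axis=0) - M
    elif kind == "video":
        comp = G.mean(axis=1) - M
    elif kind == "interaction":
        V = G.mean(axis=1, keepdims=True) - M
        A = G.mean(axis=0, keepdims=True) - M
        comp = G - M - V - A
    else:
        raise ValueError(f"unknown component kind {kind!r}")
    return comp.reshape(-1, n_channels)


def _spectrum_from_matrices(Xtr: np.ndarray, Xte: np.ndarray,
                            n_components: int) -> np.ndarray:
    # right singular vectors via the channel gram matrix: much faster than a
    # tall SVD inside the shuffle loop, identical spectra
    G = Xtr.T @ Xtr
    evals, Q = np.linalg.eigh(G)
    W = Q[:, ::-1][:, :n_components]
    return _cross_covariance(Xtr @ W, Xte @ W)


def shuffle_significance(
    D: TrialTensor | np.ndarray,
    component_kind: str = "sound",
    n_shuffles: int = 1000,
    percentile: float = 99.0,
    split: SplitSpec | None = None,
    n_components: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ShuffleResult:
    """Shuffle test for the dimensionality of a stimulus-related component.

    Each shuffle permutes the (video, sound) labels jointly and
    independently for every repeat, breaking any label-locked structure
    while preserving each repeat's trial statistics; the test-retest
    covariance spectrum is recomputed per shuffle. A component is
    significant when its real covariance strictly exceeds the chosen
    percentile (default 99th) of its own null distribution; the estimated
    dimensionality is the length of the leading significant block (see
    :class:`ShuffleResult`).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    data = D.data if isinstance(D, TrialTensor) else np.asarray(D)
    n_t, n_v, n_a, n_r, n_c = data.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if split is None:
        split = odd_even_split(n_r)
    if n_components is None:
        n_components = n_c
    tr_reps, te_reps = list(split.train_repeats), list(split.test_repeats)
    n_stim = n_v * n_a

    # per-repeat stimulus-major layout (stim, t*c) for fast row gathers
    Dr = [np.ascontiguousarray(
        data[:, :, :, r, :].reshape(n_t, n_stim, n_c).transpose(1, 0, 2)
        .reshape(n_stim, n_t * n_c)) for r in range(n_r)]

    def grouped(reps, perms=None):
        acc = np.zeros((n_stim, n_t * n_c))
        for r in reps:
            acc += Dr[r] if perms is None else Dr[r][perms[r]]
        return (acc / len(reps)).reshape(n_v, n_a, n_t * n_c)

    def spectrum(perms=None):
        Xtr = _component_from_grouped(grouped(tr_reps, perms), component_kind, n_c)
        Xte = _component_from_grouped(grouped(te_reps, perms), component_kind, n_c)
        return _spectrum_from_matrices(Xtr, Xte, n_components)

    real = spectrum()

    if n_stim == 1:
        # single stimulus: no labels to shuffle, nothing can be significant
        null = np.zeros((n_shuffles, n_components))
        thresh = np.zeros(n_components)
        mask = np.zeros(n_components, dtype=bool)
        return ShuffleResult(real, null, thresh, mask, 0, 0, percentile)

    null = np.empty((n_shuffles, len(real)))
    for s in range(n_shuffles):
        perms = [rng.permutation(n_stim) for _ in range(n_r)]
        null[s] = spectrum(perms)
    thresh = np.percentile(null, percentile, axis=0)
    mask = real > thresh
    leading = int(np.argmin(mask)) if not mask.all() else len(mask)
    return ShuffleResult(real, null, thresh, mask, leading, int(mask.sum()),
                         percentile)


# ---------------------------------------------------------------------------
# time courses and correlation averaging
# ---------------------------------------------------------------------------

def pc_timecourse(
    result: CvPcaResult,
    component_index: int,
    projection_data: str = "full",
    comp_full: np.ndarray | None = None,
) -> np.ndarray:
    """Signed per-stimulus time course of one principal component.

    Weights always come from the training half; the projected data can be
    the train half, the test half, or the full dataset's component
    (``comp_full``, required for "full"). The sign is fixed so the mean
    channel weight is non-negative, making the output invariant to the
    arbitrary sign of the singular vector. Returns (n_rows,) on the
    (stimulus-major, time-minor) row layout of the projection matrix.
    """
    if component_index >= result.n_components:
        raise ValueError("component_index out of range")
    w = result.W[:, component_index]
    sign = 1.0 if w.mean() >= 0 else -1.0
    if projection_data == "train":
        X = result.comp_train
    elif projection_data == "test":
        X = result.comp_test
    elif projection_data == "full":
        if comp_full is None:
            raise ValueError("comp_full is required for projection_data='full'")
        X = component_matrix(comp_full)
    else:
        raise ValueError(f"unknown projection_data {projection_data!r}")
    return sign * (X @ w)


def normalize_spectra(spectra: dict, mode: str = "within") -> dict:
    """Normalize covariance spectra to variance fractions.

    ``spectra`` maps component kind ("sound", "video", "interaction") to its
    ``vhat`` array. ``mode="within"`` divides each spectrum by its own sum
    (e.g. fraction of the sound-related variance); ``mode="all"`` divides
    every spectrum by the grand sum over all supplied kinds, so fractions
    are comparable across components.
    """
    if mode == "within":
        return {k: v / v.sum() for k, v in spectra.items()}
    if mode == "all":
        total = sum(float(np.sum(v)) for v in spectra.values())
        return {k: v / total for k, v in spectra.items()}
    raise ValueError(f"unknown normalization mode {mode!r}")


def fisher_mean_correlation(correlations) -> float:
    """Average correlations via Fisher's z: tanh(mean(atanh(r))).

    Coefficients with |r| = 1 (infinite z) are excluded with a warning;
    NaNs are excluded silently.
    """
    r = np.asarray(list(correlations), dtype=float)
    r = r[~np.isnan(r)]
    sat = np.abs(r) >= 1.0
    if sat.any():
        warnings.warn(f"excluding {int(sat.sum())} correlation(s) with |r| >= 1")
        r = r[~sat]
    if len(r) == 0:
        return float("nan")
    return float(np.tanh(np.mean(np.arctanh(r))))
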