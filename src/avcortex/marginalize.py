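"""Factorial (ANOVA-style) marginalization of a trial tensor.

A complete balanced tensor ``D[t, v, a, r, c]`` decomposes exactly into

    D = M + V + A + I + E

where ``M[t, c]`` is the grand mean over videos, sounds and repeats;
``V[t, v, c]`` the video-related component (average over sounds and repeats,
relative to M); ``A[t, a, c]`` the sound-related component; ``I[t, v, a, c]``
the audiovisual interaction; and ``E[t, v, a, r, c]`` the trial-to-trial
noise. Each non-mean component sums to zero over its own factor, so under a
balanced design the squared norms of the components partition the
mean-removed variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TrialTensor

__all__ = ["MarginalComponents", "marginalize", "component_matrix"]


@dataclass
class MarginalComponents:
    """Decomposition of a trial tensor; shapes M[t,c], V[t,v,c], A[t,a,c],
    I[t,v,a,c], E[t,v,a,r,c]."""

    M: np.ndarray
    V: np.ndarray
    A: np.ndarray
    I: np.ndarray
    E: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Broadcast-sum the components back to the full 5-way tensor."""
        return (
            self.M[:, None, None, None, :]
            + self.V[:, :, None, None, :]
            + self.A[:, None, :, None, :]
            + self.I[:, :, :, None, :]
            + self.E
        )

    def component(self, kind: str) -> np.ndarray:
        return {"video": self.V, "sound": self.A, "interaction": self.I}[kind]


def marginalize(D: TrialTensor | np.ndarray) -> MarginalComponents:
    """Decompose ``D[t, v, a, r, c]`` into grand-mean, video, sound,
    interaction and noise components by factor averages.

    Works identically for neural and behavioral-channel tensors. ``Nr = 1``
    is valid (E is then identically zero). NaNs are rejected: tensors are
    complete by construction.
    """
    data = D.data if isinstance(D, TrialTensor) else np.asarray(D, dtype=float)
    if data.ndim != 5:
        raise ValueError("expected a 5-way array [t, v, a, r, c]")
    if np.isnan(data).any():
        raise ValueError("tensor contains NaN; marginalization requires a complete design")

    pair_mean = data.mean(axis=3)                # D_{tva.c}
    M = pair_mean.mean(axis=(1, 2))              # D_{t...c}
    V = pair_mean.mean(axis=2) - M[:, None, :]   # D_{tv..c} - M
    A = pair_mean.mean(axis=1) - M[:, None, :]   # D_{t.a.c} - M
    I = (pair_mean - M[:, None, None, :]
         - V[:, :, None, :] - A[:, None, :, :])
    E = data - pair_mean[:, :, :, None, :]
    return MarginalComponents(M=M, V=V, A=A, I=I, E=E)


def component_matrix(comp: np.ndarray) -> np.ndarray:
    """Reshape a component [t, *stim, c] to the 2-D (time*stimulus) x channel
    matrix used by PCA, with time fastest-varying within each stimulus."""
    c = np.asarray(comp)
    n_ch = c.shape[-1]
    # move channel last is already the case; stack (stim..., t) rows as
    # [stim-major, time-minor] by transposing stimulus axes before time
    axes = tuple(range(1, c.ndim - 1)) + (0, c.ndim - 1)
    return c.transpose(axes).reshape(-1, n_ch)
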