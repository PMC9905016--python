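"""Raw tables -> peri-stimulus trial tensors and behavioral channels.

Spiking is binned at 30 ms, smoothed with a causal half-Gaussian (SD 43 ms)
and z-scored per neuron over the full session trace. Each channel's trace is
then sliced around every stimulus onset into a 5-way trial tensor
``D[t, v, a, r, c]`` (time bin x video x sound x repeat x channel).

The peri-stimulus window spans 4.8 s: 33 bins (0.99 s) before onset and 127
bins (3.81 s) after, so onset falls exactly on a bin edge and the 127-bin
post-onset stretch is the encoding-model window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .synth import StimulusSchedule

__all__ = [
    "BIN_SIZE",
    "WINDOW",
    "SMOOTH_SIGMA",
    "N_PRE_BINS",
    "N_POST_BINS",
    "TrialTensor",
    "EYE_CHANNELS",
    "smooth_causal_half_gaussian",
    "bin_spikes",
    "zscore_traces",
    "bin_and_zscore",
    "resample_to_bins",
    "derive_eye_channels",
    "assemble_trial_tensor",
]

BIN_SIZE = 0.030
WINDOW = (-0.99, 3.81)
SMOOTH_SIGMA = 0.043
N_PRE_BINS = 33
N_POST_BINS = 127

EYE_CHANNELS = (
    "pupil_area", "pupil_x", "pupil_y",
    "motion_x", "motion_y", "abs_motion_x", "abs_motion_y",
    "global_motion", "blink",
)


@dataclass
class TrialTensor:
    """5-way peri-stimulus array ``data[t, v, a, r, c]``.

    ``window`` is (start, end) seconds relative to stimulus onset; bin ``k``
    starts at ``window[0] + k * bin_size``. ``channel_kind`` is "neuron" or
    "behavioral".
    """

    data: np.ndarray
    bin_size: float = BIN_SIZE
    window: tuple[float, float] = WINDOW
    channel_kind: str = "neuron"
    channel_ids: list | None = None

    def __post_init__(self):
        expected = int(round((self.window[1] - self.window[0]) / self.bin_size))
        if self.data.shape[0] != expected:
            raise ValueError(
                f"time axis has {self.data.shape[0]} bins, window implies {expected}"
            )

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Bin start times relative to stimulus onset."""
        return self.window[0] + np.arange(self.n_t) * self.bin_size

    @property
    def onset_bin(self) -> int:
        """Index of the first bin at or after stimulus onset."""
        return int(round(-self.window[0] / self.bin_size))


# ---------------------------------------------------------------------------
# smoothing / binning
# ---------------------------------------------------------------------------

def half_gaussian_kernel(sigma: float, bin_size: float) -> np.ndarray:
    """Causal half-Gaussian kernel (tau >= 0), normalized to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    n = int(np.ceil(4.0 * sigma / bin_size)) + 1
    tau = np.arange(n) * bin_size
    g = np.exp(-0.5 * (tau / sigma) ** 2)
    return g / g.sum()


def smooth_causal_half_gaussian(
    trace: np.ndarray, sigma: float, bin_size: float = BIN_SIZE
) -> np.ndarray:
    """Causal smoothing: output[t] = sum_{tau>=0} g(tau) * input[t - tau].

    The kernel is a Gaussian of SD ``sigma`` truncated to non-negative lags
    and normalized to unit DC gain, so a constant input passes unchanged and
    the output at ``t`` depends only on samples at or before ``t``. Operates
    along the last axis; assumes uniform sampling at ``bin_size``.
    """
    g = half_gaussian_kernel(sigma, bin_size)
    return lfilter(g, [1.0], np.asarray(trace, dtype=float), axis=-1)


def bin_spikes(
    spike_table: pd.DataFrame,
    duration: float,
    bin_size: float = BIN_SIZE,
    neuron_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per half-open bin [t, t + bin), shape (n_channels, n_bins)."""
    n_bins = int(np.floor(duration / bin_size))
    if neuron_ids is None:
        neuron_ids = np.unique(spike_table["neuron_id"].to_numpy())
    times = spike_table["spike_time"].to_numpy()
    if len(times) and (times.min() < 0 or times.max() >= duration):
        raise ValueError("spike times outside [0, duration)")
    counts = np.zeros((len(neuron_ids), n_bins))
    idx = {int(c): i for i, c in enumerate(neuron_ids)}
    which = spike_table["neuron_id"].to_numpy()
    bins = np.floor(times / bin_size).astype(np.int64)
    keep = bins < n_bins
    np.add.at(counts, (np.array([idx[int(c)] for c in which[keep]],
                                dtype=np.int64), bins[keep]), 1.0)
    return counts, np.asarray(neuron_ids)


def zscore_traces(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize each row over the full session; returns (z, mean, sd).

    Rows with zero variance (e.g. a silent neuron) come back as zeros, with
    a warning, and sd is reported as 0 for them.
    """
    traces = np.asarray(traces, dtype=float)
    mu = traces.mean(axis=-1, keepdims=True)
    sd = traces.std(axis=-1, keepdims=True)
    dead = sd[..., 0] == 0
    if np.any(dead):
        warnings.warn(f"{int(np.sum(dead))} channel(s) have zero variance; emitting zeros")
    safe = np.where(sd == 0, 1.0, sd)
    z = (traces - mu) / safe
    z[dead] = 0.0
    return z, mu[..., 0], np.where(dead, 0.0, sd[..., 0])


def bin_and_zscore(
    spike_table: pd.DataFrame,
    duration: float,
    bin_size: float = BIN_SIZE,
    sigma: float = SMOOTH_SIGMA,
    neuron_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bin -> causal smooth -> z-score; returns (traces, ids, mean, sd)."""
    counts, ids = bin_spikes(spike_table, duration, bin_size, neuron_ids)
    smoothed = smooth_causal_half_gaussian(counts, sigma, bin_size)
    z, mu, sd = zscore_traces(smoothed)
    return z, ids, mu, sd


def resample_to_bins(
    src_times: np.ndarray,
    src_values: np.ndarray,
    duration: float,
    bin_size: float = BIN_SIZE,
) -> np.ndarray:
    """Linear-interpolate channels (rows of src_values.T) onto bin centers.

    ``src_values`` is (n_samples, n_channels); returns (n_channels, n_bins).
    """
    n_bins = int(np.floor(duration / bin_size))
    centers = (np.arange(n_bins) + 0.5) * bin_size
    src_values = np.atleast_2d(np.asarray(src_values, dtype=float).T)
    return np.stack([np.interp(centers, src_times, v) for v in src_values])


# ---------------------------------------------------------------------------
# eye channels
# ---------------------------------------------------------------------------

def interpolate_blinks(values: np.ndarray, blink: np.ndarray) -> np.ndarray:
    """Replace samples flagged as blink by linear interpolation between the
    last pre-blink and first post-blink samples (edges extend the nearest
    valid sample)."""
    values = np.asarray(values, dtype=float).copy()
    blink = np.asarray(blink, dtype=bool)
    if not blink.any():
        return values
    good = ~blink
    if not good.any():
        raise ValueError("all samples are flagged as blink")
    idx = np.arange(len(values))
    values[blink] = np.interp(idx[blink], idx[good], values[good])
    return values


def derive_eye_channels(
    eye_table: pd.DataFrame,
    schedule: StimulusSchedule,
    duration: float,
    bin_size: float = BIN_SIZE,
    window: tuple[float, float] = WINDOW,
) -> TrialTensor:
    """Nine behavioral eye channels as a per-trial tensor.

    Channels (in order): baseline-corrected pupil area, x and y position;
    signed motion x/y (first difference of position between bins); unsigned
    motion x/y; global motion (L2 norm of the signed motions); blink flag.
    Blink-flagged samples are linearly interpolated before anything else;
    baseline correction subtracts each trial's mean over the ~1 s of bins
    preceding onset (area and positions only).
    """
    t = eye_table["time"].to_numpy()
    blink = eye_table["blink"].to_numpy().astype(bool)
    area = interpolate_blinks(eye_table["pupil_area"].to_numpy(), blink)
    px = interpolate_blinks(eye_table["pupil_x"].to_numpy(), blink)
    py = interpolate_blinks(eye_table["pupil_y"].to_numpy(), blink)

    binned = resample_to_bins(t, np.column_stack([area, px, py, blink.astype(float)]),
                              duration, bin_size)
    b_area, b_px, b_py, b_blink = binned
    mx = np.diff(b_px, prepend=b_px[0])
    my = np.diff(b_py, prepend=b_py[0])
    traces = np.stack([
        b_area, b_px, b_py, mx, my, np.abs(mx), np.abs(my),
        np.hypot(mx, my), (b_blink > 0.5).astype(float),
    ])
    tensor = assemble_trial_tensor(traces, schedule, window=window, bin_size=bin_size,
                                   channel_kind="behavioral",
                                   channel_ids=list(EYE_CHANNELS))
    # per-trial baseline over the pre-onset second, for area and positions
    pre = tensor.times < 0
    base = tensor.data[pre].mean(axis=0, keepdims=True)
    tensor.data[:, :, :, :, :3] -= base[..., :3]
    return tensor


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

def assemble_trial_tensor(
    traces: np.ndarray,
    schedule: StimulusSchedule,
    window: tuple[float, float] = WINDOW,
    bin_size: float = BIN_SIZE,
    channel_kind: str = "neuron",
    channel_ids: list | None = None,
) -> TrialTensor:
    """Slice continuous binned traces into ``D[t, v, a, r, c]``.

    ``traces`` is (n_channels, n_bins) on the session-wide bin grid starting
    at time 0. The repeat axis preserves presentation order within each
    (video, sound) pair, and assembly is invariant to the row order of the
    trial table. Raises if any (video, sound) pair does not appear exactly
    ``n_repeats`` times.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_ch, n_bins = traces.shape
    n_t = int(round((window[1] - window[0]) / bin_size))
    n_pre = int(round(-window[0] / bin_size))

    counts = schedule.trials.groupby(["video_id", "sound_id"]).size()
    bad = [k for k in [(v, a) for v in range(schedule.n_videos)
                       for a in range(schedule.n_sounds)]
           if counts.get(k, 0) != schedule.n_repeats]
    if bad:
        raise ValueError(f"incomplete design; wrong trial count for pairs {bad[:10]}")

    D = np.empty((n_t, schedule.n_videos, schedule.n_sounds, schedule.n_repeats, n_ch))
    order = schedule.trials.sort_values("onset_time")
    for row in order.itertuples(index=False):
        k0 = int(round(row.onset_time / bin_size)) - n_pre
        if k0 < 0 or k0 + n_t > n_bins:
            raise ValueError(f"trial at {row.onset_time}s extends beyond the traces")
        D[:, int(row.video_id), int(row.sound_id), int(row.repeat), :] = \
            traces[:, k0:k0 + n_t].T
    return TrialTensor(data=D, bin_size=bin_size, window=window,
                       channel_kind=channel_kind, channel_ids=channel_ids)
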