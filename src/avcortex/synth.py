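"""Synthetic audiovisual session generator with known ground truth.

Emulates a head-fixed rodent recording in which a factorial grid of short
naturalistic movies (``n_videos`` visual streams x ``n_sounds`` auditory
streams, each pair repeated ``n_repeats`` times) is presented while spiking
activity, face motion-energy principal components (PCs), and eye variables
are recorded. The generative model is deliberately aligned with the linear
analyses downstream:

* a low-rank latent state ``s(t)`` is driven by sound-specific temporal
  kernels on every trial (with trial-to-trial gain variability) plus slow
  spontaneous fluctuations that continue during a stimulus-free epoch;
* face motion PCs load linearly on the latent (PC1 most strongly);
* each neuron's firing rate is baseline + latent drive delayed by a short
  lead time (movement precedes spiking) + a high-rank video-specific
  response + smooth noise, rectified at zero, and spikes are drawn from an
  inhomogeneous Poisson process;
* eye variables (pupil area/position, blinks) are generated at their own
  sampling rate mainly to exercise preprocessing.

All randomness flows from a single integer seed; identical inputs give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

__all__ = [
    "StimulusSchedule",
    "GroundTruth",
    "SyntheticSession",
    "generate_schedule",
    "default_ground_truth",
    "generate_session",
]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Trial onsets for a complete factorial audiovisual design.

    ``trials`` has columns ``onset_time`` (s), ``video_id``, ``sound_id``,
    ``repeat`` (0-based presentation count of that audiovisual pair).
    ``video_id == n_videos - 1`` denotes the blank screen and
    ``sound_id == n_sounds - 1`` denotes silence. ``spontaneous_epoch`` is a
    stimulus-free ``(start, end)`` interval in seconds.
    """

    trials: pd.DataFrame
    n_videos: int
    n_sounds: int
    n_repeats: int
    trial_duration: float = 4.0
    inter_trial_interval: float = 2.0
    spontaneous_epoch: tuple[float, float] = (0.0, 0.0)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def blank_video(self) -> int:
        return self.n_videos - 1

    @property
    def silence(self) -> int:
        return self.n_sounds - 1

    def validate(self) -> None:
        counts = self.trials.groupby(["video_id", "sound_id"]).size()
        if len(counts) != self.n_videos * self.n_sounds or not (counts == self.n_repeats).all():
            raise ValueError("schedule is not a complete balanced factorial design")
        onsets = self.trials["onset_time"].to_numpy()
        gaps = np.diff(np.sort(onsets))
        if len(gaps) and gaps.min() < self.trial_duration + self.inter_trial_interval - 1e-9:
            raise ValueError("trial onsets overlap")
        s0, s1 = self.spontaneous_epoch
        in_spont = (onsets + self.trial_duration > s0) & (onsets < s1)
        if in_spont.any():
            raise ValueError("stimulus onsets fall inside the spontaneous epoch")


def generate_schedule(
    n_videos: int,
    n_sounds: int,
    n_repeats: int,
    seed: int,
    *,
    trial_duration: float = 4.0,
    inter_trial_interval: float = 2.0,
    start_time: float = 10.0,
    spontaneous_duration: float = 600.0,
    spontaneous_gap: float = 10.0,
) -> StimulusSchedule:
    """Build a randomized factorial schedule followed by a spontaneous epoch.

    One seeded random ordering of all ``n_videos * n_sounds`` pairs is
    repeated ``n_repeats`` times in blocks (the same randomized sequence on
    every repeat), so the repeat index equals the block index and preserves
    presentation order within each pair.
    """
    if min(n_videos, n_sounds, n_repeats) < 1:
        raise ValueError("n_videos, n_sounds and n_repeats must all be >= 1")
    rng = np.random.default_rng(seed)
    pairs = [(v, a) for v in range(n_videos) for a in range(n_sounds)]
    order = rng.permutation(len(pairs))
    period = trial_duration + inter_trial_interval

    rows = []
    k = 0
    for rep in range(n_repeats):
        for idx in order:
            v, a = pairs[idx]
            rows.append((start_time + k * period, v, a, rep))
            k += 1
    trials = pd.DataFrame(rows, columns=["onset_time", "video_id", "sound_id", "repeat"])
    last_end = trials["onset_time"].iloc[-1] + trial_duration
    spont = (last_end + spontaneous_gap, last_end + spontaneous_gap + spontaneous_duration)
    sched = StimulusSchedule(
        trials=trials,
        n_videos=n_videos,
        n_sounds=n_sounds,
        n_repeats=n_repeats,
        trial_duration=trial_duration,
        inter_trial_interval=inter_trial_interval,
        spontaneous_epoch=spont,
    )
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generative parameters of a synthetic session.

    ``sound_kernels`` has shape ``(n_latents, n_sounds, n_kernel_samples)``
    sampled at ``kernel_dt``; the silence row is identically zero. Each
    latent drives the face-motion PCs through ``motion_loadings``
    ``(n_latents, n_motion_pcs)`` and, after a delay of ``lead_time``
    seconds, every neuron's rate through ``neural_loadings``
    ``(n_latents, n_neurons)`` (spikes/s per latent unit, drawn with a
    positive mean). ``visual_code`` ``(n_videos, n_code_samples, n_neurons)``
    holds smooth video-specific rate time courses at ``code_dt`` (blank
    video row zero). The sound-related neural drive is exactly rank
    ``n_latents`` across neurons.
    """

    sound_kernels: np.ndarray
    kernel_dt: float
    motion_loadings: np.ndarray
    neural_loadings: np.ndarray
    lead_time: float
    visual_code: np.ndarray
    code_dt: float
    baseline_rates: np.ndarray
    trial_gain_sd: float = 0.5
    spontaneous_sd: float = 0.5
    spontaneous_cutoff_hz: float = 2.0
    # fast broadband component of the spontaneous latent: real face motion
    # has sharp transients on top of slow co-fluctuations, and without them
    # a tens-of-ms lead would be unidentifiable from lagged regressions
    spontaneous_fast_sd: float = 0.3
    spontaneous_fast_cutoff_hz: float = 10.0
    motion_noise_sd: np.ndarray | None = None
    rate_noise_sd: float = 0.3

    @property
    def n_latents(self) -> int:
        return self.sound_kernels.shape[0]

    @property
    def n_sounds(self) -> int:
        return self.sound_kernels.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.neural_loadings.shape[1]

    @property
    def n_motion_pcs(self) -> int:
        return self.motion_loadings.shape[1]


def _random_kernel(rng: np.random.Generator, n_samples: int, dt: float) -> np.ndarray:
    """Sum of 2-4 gamma-shaped bumps within ~1 s of onset, unit peak."""
    tau = np.arange(n_samples) * dt
    k = np.zeros(n_samples)
    for _ in range(rng.integers(2, 5)):
        shape = rng.uniform(2.0, 5.0)
        scale = rng.uniform(0.03, 0.12)
        delay = rng.uniform(0.0, 0.5)
        amp = rng.uniform(0.4, 1.2) * (1 if rng.random() < 0.8 else -1)
        k += amp * gamma_dist.pdf(tau - delay, a=shape, scale=scale)
    peak = np.abs(k).max()
    return k / peak if peak > 0 else k


def default_ground_truth(
    n_neurons: int = 100,
    n_videos: int = 12,
    n_sounds: int = 12,
    n_motion_pcs: int = 128,
    n_latents: int = 1,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    visual_amplitude: float = 3.0,
    lead_time: float = 0.030,
    trial_gain_sd: float = 0.5,
    spontaneous_sd: float = 0.5,
    rate_noise_sd: float = 0.3,
    baseline_median: float = 4.0,
    trial_duration: float = 4.0,
) -> GroundTruth:
    """Draw a ground-truth parameter set emulating the study's structure.

    ``amplitude`` scales the sound kernels (and hence the sound-evoked
    latent and everything it drives); ``visual_amplitude`` (spikes/s) scales
    the high-rank video code so that video-related variance dominates
    sound-related variance, as in cortical data.
    """
    rng = np.random.default_rng(seed)
    kernel_dt = 0.010
    n_k = int(round(1.2 / kernel_dt))
    kernels = np.zeros((n_latents, n_sounds, n_k))
    for l in range(n_latents):
        for a in range(n_sounds - 1):  # last sound is silence
            kernels[l, a] = amplitude * rng.uniform(0.6, 1.4) * _random_kernel(rng, n_k, kernel_dt)

    # motion PC1 carries most of the latent; later PCs progressively less
    decay = np.exp(-np.arange(n_motion_pcs) / 2.0)
    motion_loadings = np.zeros((n_latents, n_motion_pcs))
    for l in range(n_latents):
        motion_loadings[l] = 2.0 * decay * rng.uniform(0.7, 1.3, n_motion_pcs)
        if l > 0:  # extra latents load on a rotated, lower-energy pattern
            motion_loadings[l] = np.roll(motion_loadings[l], l) * 0.7

    neural_loadings = rng.normal(0.8, 0.5, size=(n_latents, n_neurons))
    if n_latents > 1:
        # a requested rank-n drive should be a well-conditioned rank n:
        # orthogonalize the loading vectors and match their norms
        q, _ = np.linalg.qr(neural_loadings.T)
        scale = np.linalg.norm(neural_loadings[0])
        neural_loadings = (q.T * scale)
        neural_loadings *= np.where(neural_loadings.mean(axis=1) >= 0, 1, -1)[:, None]

    code_dt = 0.050
    n_code = int(round(trial_duration / code_dt)) + 1
    visual_code = rng.standard_normal((n_videos, n_code, n_neurons))
    visual_code = gaussian_filter1d(visual_code, sigma=2.0, axis=1)
    sd = visual_code.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    visual_code = visual_amplitude * visual_code / sd
    visual_code[n_videos - 1] = 0.0  # blank screen

    baseline = rng.lognormal(mean=np.log(baseline_median), sigma=0.6,
                             size=n_neurons)
    motion_noise_sd = (np.arange(n_motion_pcs) + 1.0) ** -0.3

    return GroundTruth(
        sound_kernels=kernels,
        kernel_dt=kernel_dt,
        motion_loadings=motion_loadings,
        neural_loadings=neural_loadings,
        lead_time=lead_time,
        visual_code=visual_code,
        code_dt=code_dt,
        baseline_rates=baseline,
        trial_gain_sd=trial_gain_sd,
        spontaneous_sd=spontaneous_sd,
        motion_noise_sd=motion_noise_sd,
        rate_noise_sd=rate_noise_sd,
    )


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    """Ground-truth-annotated tables emulating one recording session.

    ``spikes``: DataFrame (neuron_id, spike_time); ``motion_times`` /
    ``motion_pcs``: camera frames x motion-PC values; ``eye``: DataFrame at
    the eye-camera rate (time, pupil_area, pupil_x, pupil_y, blink);
    ``latent_times`` / ``latents`` hold the noise-free latent state sampled
    at the camera rate, kept for parameter-recovery tests.
    """

    spikes: pd.DataFrame
    motion_times: np.ndarray
    motion_pcs: np.ndarray
    eye: pd.DataFrame
    schedule: StimulusSchedule
    truth: GroundTruth
    duration: float
    camera_rate: float
    eye_rate: float
    latent_times: np.ndarray
    latents: np.ndarray
    pixel_masks: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.truth.n_neurons


def _lowpass_noise(rng: np.random.Generator, n: int, dt: float, cutoff_hz: float) -> np.ndarray:
    """Unit-SD Gaussian noise low-pass filtered at roughly ``cutoff_hz``."""
    sigma = 1.0 / (2.0 * np.pi * cutoff_hz * dt)
    x = gaussian_filter1d(rng.standard_normal(n), sigma=sigma)
    sd = x.std()
    return x / sd if sd > 0 else x


def _latent_state(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    t_grid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free-by-construction latent s_l(t) on ``t_grid`` (includes the
    spontaneous low-pass component; 'noise-free' meaning no sensor noise)."""
    dt = t_grid[1] - t_grid[0]
    n = len(t_grid)
    n_lat = truth.n_latents
    s = np.zeros((n_lat, n))
    for l in range(n_lat):
        s[l] = truth.spontaneous_sd * _lowpass_noise(rng, n, dt, truth.spontaneous_cutoff_hz)
        if truth.spontaneous_fast_sd:
            s[l] += truth.spontaneous_fast_sd * _lowpass_noise(
                rng, n, dt, truth.spontaneous_fast_cutoff_hz)

    gains = rng.lognormal(mean=0.0, sigma=truth.trial_gain_sd,
                          size=(schedule.n_trials, n_lat))
    n_k = truth.sound_kernels.shape[2]
    kern_t = np.arange(n_k) * truth.kernel_dt
    for i, row in enumerate(schedule.trials.itertuples(index=False)):
        a = int(row.sound_id)
        i0 = int(np.searchsorted(t_grid, row.onset_time))
        seg_t = t_grid[i0:i0 + int(n_k * truth.kernel_dt / dt) + 1] - row.onset_time
        seg_t = seg_t[seg_t <= kern_t[-1]]
        if len(seg_t) == 0:
            continue
        for l in range(n_lat):
            drive = np.interp(seg_t, kern_t, truth.sound_kernels[l, a])
            s[l, i0:i0 + len(seg_t)] += gains[i, l] * drive
    return s


def _visual_drive(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    t_grid: np.ndarray,
    neurons: slice,
) -> np.ndarray:
    """Video-specific rate component for a block of neurons, shape (T, nb)."""
    nb = neurons.stop - neurons.start
    out = np.zeros((len(t_grid), nb))
    dt = t_grid[1] - t_grid[0]
    n_code = truth.visual_code.shape[1]
    for row in schedule.trials.itertuples(index=False):
        v = int(row.video_id)
        i0 = int(np.searchsorted(t_grid, row.onset_time))
        n_seg = int(round(schedule.trial_duration / dt))
        seg = slice(i0, min(i0 + n_seg, len(t_grid)))
        rel = (t_grid[seg] - row.onset_time) / truth.code_dt
        j0 = np.clip(rel.astype(int), 0, n_code - 2)
        frac = (rel - j0)[:, None]
        code = truth.visual_code[v, :, neurons]
        out[seg] += code[j0] * (1 - frac) + code[j0 + 1] * frac
    return out


def generate_session(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    n_neurons: int | None = None,
    duration: float | None = None,
    seed: int = 0,
    *,
    sim_dt: float = 0.005,
    camera_rate: float = 40.0,
    eye_rate: float = 100.0,
    blink_rate_hz: float = 0.1,
    make_pixel_masks: bool = False,
) -> SyntheticSession:
    """Simulate spikes, motion PCs and eye variables for one session.

    Firing rates are evaluated on a ``sim_dt`` grid (piecewise-constant
    intensity), rectified at zero, and spikes are drawn as an inhomogeneous
    Poisson process (Poisson count per grid cell, uniform jitter within the
    cell). Deterministic given ``seed``.
    """
    if n_neurons is not None and n_neurons != truth.n_neurons:
        raise ValueError("n_neurons must match truth.neural_loadings")
    if truth.lead_time > schedule.trial_duration:
        raise ValueError("lead_time exceeds trial duration")
    if duration is None:
        duration = schedule.spontaneous_epoch[1] + 5.0
    last_need = schedule.trials["onset_time"].iloc[-1] + schedule.trial_duration
    if duration < max(last_need, schedule.spontaneous_epoch[1]):
        raise ValueError("duration does not cover the schedule and spontaneous epoch")

    ss = np.random.SeedSequence(seed)
    s_lat, s_mot, s_eye, s_neur = ss.spawn(4)
    rng_lat = np.random.default_rng(s_lat)
    rng_mot = np.random.default_rng(s_mot)
    rng_eye = np.random.default_rng(s_eye)

    t_grid = np.arange(0.0, duration, sim_dt)
    s = _latent_state(schedule, truth, t_grid, rng_lat)  # (n_lat, T)

    # --- face motion PCs at the camera rate --------------------------------
    cam_t = np.arange(0.0, duration - 1.0 / camera_rate, 1.0 / camera_rate)
    s_cam = np.stack([np.interp(cam_t, t_grid, s[l]) for l in range(truth.n_latents)])
    motion = truth.motion_loadings.T @ s_cam  # (n_pcs, Tc)
    noise_sd = truth.motion_noise_sd
    if noise_sd is None:
        noise_sd = np.ones(truth.n_motion_pcs)
    for i in range(truth.n_motion_pcs):
        motion[i] += noise_sd[i] * _lowpass_noise(rng_mot, len(cam_t), 1.0 / camera_rate, 5.0)

    # --- neural rates and spikes -------------------------------------------
    # latent reaches neurons lead_time later: rate at t uses s(t - lead)
    shift = int(round(truth.lead_time / sim_dt))
    s_delayed = np.zeros_like(s)
    if shift > 0:
        s_delayed[:, shift:] = s[:, :-shift]
    else:
        s_delayed = s.copy()

    neuron_seeds = s_neur.spawn(truth.n_neurons)
    spike_neuron: list[np.ndarray] = []
    spike_time: list[np.ndarray] = []
    chunk = 25
    for c0 in range(0, truth.n_neurons, chunk):
        block = slice(c0, min(c0 + chunk, truth.n_neurons))
        rate = truth.baseline_rates[block][None, :] + s_delayed.T @ truth.neural_loadings[:, block]
        rate += _visual_drive(schedule, truth, t_grid, block)
        for j, c in enumerate(range(block.start, block.stop)):
            rng_c = np.random.default_rng(neuron_seeds[c])
            r = rate[:, j] + truth.rate_noise_sd * _lowpass_noise(rng_c, len(t_grid), sim_dt, 4.0)
            np.maximum(r, 0.0, out=r)
            counts = rng_c.poisson(r * sim_dt)
            nz = np.nonzero(counts)[0]
            reps = counts[nz]
            times = np.repeat(t_grid[nz], reps) + rng_c.uniform(0, sim_dt, int(reps.sum()))
            times.sort()
            spike_time.append(times)
            spike_neuron.append(np.full(len(times), c, dtype=np.int64))
    spikes = pd.DataFrame({
        "neuron_id": np.concatenate(spike_neuron),
        "spike_time": np.concatenate(spike_time),
    })

    # --- eye table at 100 Hz ------------------------------------------------
    eye_t = np.arange(0.0, duration - 1.0 / eye_rate, 1.0 / eye_rate)
    s_eye_grid = np.interp(eye_t, t_grid, s[0])
    area = _lowpass_noise(rng_eye, len(eye_t), 1.0 / eye_rate, 0.2) + 0.3 * s_eye_grid
    px = 0.5 * _lowpass_noise(rng_eye, len(eye_t), 1.0 / eye_rate, 1.0)
    py = 0.5 * _lowpass_noise(rng_eye, len(eye_t), 1.0 / eye_rate, 1.0)
    blink = np.zeros(len(eye_t), dtype=bool)
    n_blinks = rng_eye.poisson(blink_rate_hz * duration)
    starts = rng_eye.uniform(0, duration - 0.5, n_blinks)
    durs = rng_eye.uniform(0.1, 0.3, n_blinks)
    for b0, bd in zip(starts, durs):
        m = (eye_t >= b0) & (eye_t < b0 + bd)
        blink[m] = True
        area[m] -= 3.0  # lid occludes the pupil: artifactual drop
        px[m] += rng_eye.normal(0, 1.0)
        py[m] += rng_eye.normal(0, 1.0)
    eye = pd.DataFrame({
        "time": eye_t, "pupil_area": area, "pupil_x": px, "pupil_y": py,
        "blink": blink.astype(np.int8),
    })

    pixel_masks = None
    if make_pixel_masks:
        pm = rng_mot.standard_normal((truth.n_motion_pcs, 32, 32))
        pixel_masks = gaussian_filter1d(gaussian_filter1d(pm, 2.0, axis=1), 2.0, axis=2)

    return SyntheticSession(
        spikes=spikes,
        motion_times=cam_t,
        motion_pcs=motion.T.copy(),
        eye=eye,
        schedule=schedule,
        truth=truth,
        duration=duration,
        camera_rate=camera_rate,
        eye_rate=eye_rate,
        latent_times=cam_t,
        latents=s_cam,
        pixel_masks=pixel_masks,
    )
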