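"""End-to-end orchestration: simulate -> preprocess -> marginalize -> cvPCA
-> decode -> encode -> subspace, under one serializable configuration.

Every stochastic stage consumes a named sub-seed derived from the master
seed, so a rerun with the same configuration reproduces the summary
bit-for-bit. The report is a plain nested dict (JSON-serializable) with one
section per stage, stage wall times, and the configuration echoed verbatim.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import cvpca, decode, encode, marginalize, preprocess, subspace, synth
from .synth import SyntheticSession

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Session and analysis parameters for one pipeline run.

    Session defaults emulate the study's recordings: a 12 x 12 factorial
    design (last levels = blank screen / silence) with 4 repeats, 4 s trials
    and 2 s inter-trial intervals, ~100 neurons, 128 face-motion PCs sampled
    at 40 Hz, eye variables at 100 Hz, a 10-minute stimulus-free epoch, and
    a 30 ms behavioral lead time.
    """

    seed: int = 0
    # session
    n_videos: int = 12
    n_sounds: int = 12
    n_repeats: int = 4
    n_neurons: int = 100
    n_motion_pcs: int = 128
    n_latents: int = 1
    amplitude: float = 1.0
    visual_amplitude: float = 3.0
    lead_time: float = 0.030
    trial_gain_sd: float = 0.5
    spontaneous_duration: float = 600.0
    camera_rate: float = 40.0
    # analysis
    bin_size: float = preprocess.BIN_SIZE
    smooth_sigma: float = preprocess.SMOOTH_SIGMA
    n_sound_pcs: int = 4
    n_video_pcs: int = 30
    n_shuffles: int = 1000
    shuffle_kinds: tuple = ("sound", "interaction")
    n_chance_permutations: int = 1000
    encode_motion_pcs: int | None = None   # None = all motion PCs
    lambda_grid: tuple = tuple(encode.DEFAULT_LAMBDA_GRID)
    rrr_rank: int = 40
    rrr_lags: int = 21
    overlap_k: int = 4
    n_random_subspaces: int = 200
    run_encode: bool = True
    run_subspace: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shuffle_kinds"] = list(self.shuffle_kinds)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "shuffle_kinds" in raw:
            raw["shuffle_kinds"] = tuple(raw["shuffle_kinds"])
        if "lambda_grid" in raw:
            raw["lambda_grid"] = tuple(raw["lambda_grid"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, input_hash: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed (input {input_hash}): {cause}")
        self.stage = stage
        self.input_hash = input_hash


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reusable stage bodies (also behind the CLI's single-stage verbs)
# ---------------------------------------------------------------------------

def _neural_tensor(sess: SyntheticSession, bin_size: float = preprocess.BIN_SIZE,
                   smooth_sigma: float = preprocess.SMOOTH_SIGMA):
    traces, ids, _, _ = preprocess.bin_and_zscore(
        sess.spikes, sess.duration, bin_size, smooth_sigma,
        neuron_ids=np.arange(sess.n_neurons))
    D = preprocess.assemble_trial_tensor(traces, sess.schedule,
                                         channel_kind="neuron",
                                         channel_ids=list(ids))
    return D, traces


def _behavioral_tensor_extended(sess: SyntheticSession, n_motion: int,
                                bin_size: float = preprocess.BIN_SIZE):
    """Eye + motion channels on a window extended past the encoding bins so
    lagged predictors are fully observed on every in-trial row."""
    ext_window = (preprocess.WINDOW[0],
                  preprocess.WINDOW[1] + int(max(encode.LAGS)) * bin_size)
    mot = preprocess.resample_to_bins(sess.motion_times, sess.motion_pcs[:, :n_motion],
                                      sess.duration, bin_size)
    mot_z, _, _ = preprocess.zscore_traces(mot)
    mot_ext = preprocess.assemble_trial_tensor(
        mot_z, sess.schedule, window=ext_window, channel_kind="behavioral",
        channel_ids=[f"motion_pc{i}" for i in range(n_motion)])
    eye_ext = preprocess.derive_eye_channels(sess.eye, sess.schedule, sess.duration,
                                             bin_size, window=ext_window)
    return preprocess.TrialTensor(
        np.concatenate([eye_ext.data, mot_ext.data], axis=-1),
        window=ext_window, channel_kind="behavioral",
        channel_ids=list(eye_ext.channel_ids) + list(mot_ext.channel_ids))


def _encode_models(sess: SyntheticSession, cfg: PipelineConfig,
                   models=("auditory", "behavioral", "full"),
                   D=None, marg=None) -> dict:
    if D is None:
        D, _ = _neural_tensor(sess, cfg.bin_size, cfg.smooth_sigma)
    if marg is None:
        marg = marginalize.marginalize(D)
    split = cvpca.odd_even_split(sess.schedule.n_repeats)
    n_mot = cfg.encode_motion_pcs or sess.motion_pcs.shape[1]
    beh = _behavioral_tensor_extended(sess, n_mot, cfg.bin_size)
    W_full = encode.full_data_basis(D, "sound", cfg.n_sound_pcs)
    Y = encode.project_target(D, marg, W_full)
    grid = np.asarray(cfg.lambda_grid)
    sched = sess.schedule
    out = {}
    for kind in models:
        if kind == "auditory":
            X = encode.build_design("auditory", sched.n_videos, sched.n_sounds,
                                    sched.n_repeats)
        elif kind == "behavioral":
            X = encode.build_design("behavioral", behavioral=beh)
        else:
            X = encode.build_design("full", sched.n_videos, sched.n_sounds,
                                    sched.n_repeats, behavioral=beh)
        ev = encode.crossval_encoding(X, Y, split, lambda_grid=grid)
        out[kind] = {
            "n_columns": X.values.shape[1],
            "trial_average_corr": ev["trial_average_corr"],
            "noise_corr": ev["noise_corr"],
            "lambda_selected": ev["lambda_selected"],
        }
    return out


def _subspace_analysis(sess: SyntheticSession, rank: int = 40, seed: int = 0,
                       n_lags: int = 21, overlap_k: int = 4,
                       n_random: int = 200, n_sound_pcs: int = 4,
                       D=None, cvpca_sound=None) -> dict:
    if D is None:
        D, _ = _neural_tensor(sess)
    if cvpca_sound is None:
        split = cvpca.odd_even_split(sess.schedule.n_repeats)
        tr, te = cvpca.component_halves(D, "sound", split)
        cvpca_sound = cvpca.cvpca_spectrum(tr, te)

    s0, s1 = sess.schedule.spontaneous_epoch
    frame = 1.0 / sess.camera_rate
    counts, _ = preprocess.bin_spikes(sess.spikes, sess.duration, frame,
                                      neuron_ids=np.arange(sess.n_neurons))
    k0, k1 = int(np.ceil(s0 / frame)), int(np.floor(s1 / frame))
    S_z, _, _ = preprocess.zscore_traces(counts[:, k0:k1])
    S = S_z.T
    cam_mask = (sess.motion_times >= k0 * frame) & (sess.motion_times < k1 * frame)
    motion = sess.motion_pcs[cam_mask]
    n = min(len(motion), S.shape[0])
    motion, S = motion[:n], S[:n]

    Xlag, keep, lag_grid = subspace.build_lagged_motion(motion, n_lags)
    rank = min(rank, sess.n_neurons, Xlag.shape[1])
    rrr = subspace.fit_rrr(Xlag, S[keep], rank=rank)
    ov = subspace.subspace_overlap(
        cvpca_sound.comp_train, cvpca_sound.comp_test, rrr.C, cvpca_sound,
        k=overlap_k, n_random=n_random, seed=np.random.default_rng(seed))

    W_full = encode.full_data_basis(D, "sound", n_sound_pcs)
    w1 = W_full[:, 0] * (1 if W_full[:, 0].mean() >= 0 else -1)
    neural_pc1 = S @ w1
    lag, _, _ = subspace.xcorr_lag(motion[:, 0], neural_pc1, sess.camera_rate)
    w, lag_frames = subspace.ridge_lagged_weights(neural_pc1, motion, n_lags)
    delay = subspace.weight_peak_delay(w[0], lag_frames, sess.camera_rate)
    return {
        "n_lagged_columns": Xlag.shape[1],
        "rrr_rank": rank,
        "overlap_ratio": ov.overlap_ratio,
        "random_threshold": ov.random_threshold,
        "overlap_significant": bool(ov.overlap_ratio > ov.random_threshold),
        "xcorr_lag_ms": lag * 1000.0,
        "weight_peak_delay_ms": delay * 1000.0,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable summary report."""
    cfg = config
    h = _config_hash(cfg)
    report: dict = {"config": cfg.to_dict(), "input_hash": h, "stages": {}}
    timings: dict = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = dict(zip(
        ["schedule", "truth", "session", "shuffle", "chance", "overlap"],
        [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)],
    ))
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as e:  # noqa: BLE001 - annotate with the stage name
            raise StageError(name, h, e) from e
        timings[name] = round(time.perf_counter() - t0, 3)
        report["stages"][name] = out

    def _simulate():
        sched = synth.generate_schedule(
            cfg.n_videos, cfg.n_sounds, cfg.n_repeats, seeds["schedule"],
            spontaneous_duration=cfg.spontaneous_duration)
        truth = synth.default_ground_truth(
            n_neurons=cfg.n_neurons, n_videos=cfg.n_videos, n_sounds=cfg.n_sounds,
            n_motion_pcs=cfg.n_motion_pcs, n_latents=cfg.n_latents,
            seed=seeds["truth"], amplitude=cfg.amplitude,
            visual_amplitude=cfg.visual_amplitude, lead_time=cfg.lead_time,
            trial_gain_sd=cfg.trial_gain_sd)
        sess = synth.generate_session(sched, truth, seed=seeds["session"],
                                      camera_rate=cfg.camera_rate)
        state.update(session=sess)
        return {
            "n_trials": sched.n_trials,
            "n_unique_pairs": cfg.n_videos * cfg.n_sounds,
            "n_spikes": len(sess.spikes),
            "duration_s": sess.duration,
            "spontaneous_epoch": list(sched.spontaneous_epoch),
        }

    def _preprocess():
        sess = state["session"]
        D, traces = _neural_tensor(sess, cfg.bin_size, cfg.smooth_sigma)
        mot = preprocess.resample_to_bins(sess.motion_times, sess.motion_pcs,
                                          sess.duration, cfg.bin_size)
        mot_z, _, _ = preprocess.zscore_traces(mot)
        Bmot = preprocess.assemble_trial_tensor(
            mot_z, sess.schedule, channel_kind="behavioral",
            channel_ids=[f"motion_pc{i}" for i in range(mot_z.shape[0])])
        eye_T = preprocess.derive_eye_channels(sess.eye, sess.schedule,
                                               sess.duration, cfg.bin_size)
        state.update(D=D, Bmot=Bmot, eye=eye_T)
        return {"tensor_shape": list(D.shape),
                "n_behavioral_motion": Bmot.shape[-1],
                "n_eye_channels": eye_T.shape[-1]}

    def _marginalize():
        D = state["D"]
        marg = marginalize.marginalize(D)
        state["marg"] = marg
        data = D.data
        n_t, n_v, n_a, n_r, _ = data.shape
        total = float(np.sum((data - marg.M[:, None, None, None, :]) ** 2))
        parts = {
            "video": float(np.sum(marg.V ** 2)) * n_a * n_r,
            "sound": float(np.sum(marg.A ** 2)) * n_v * n_r,
            "interaction": float(np.sum(marg.I ** 2)) * n_r,
            "noise": float(np.sum(marg.E ** 2)),
        }
        return {"variance_fraction": {k: (v / total if total else float("nan"))
                                      for k, v in parts.items()}}

    def _cvpca():
        D = state["D"]
        split = cvpca.odd_even_split(cfg.n_repeats)
        state["split"] = split
        out = {}
        rng = np.random.default_rng(seeds["shuffle"])
        for kind, n_pc in (("sound", cfg.n_sound_pcs), ("video", cfg.n_video_pcs)):
            tr, te = cvpca.component_halves(D, kind, split)
            res = cvpca.cvpca_spectrum(tr, te)
            state[f"cvpca_{kind}"] = res
            out[kind] = {
                "vhat_top10": res.vhat[:10].tolist(),
                "normalized_spectrum_top10": res.normalized_spectrum[:10].tolist(),
                "pc1_variance_share": float(res.normalized_spectrum[0]),
            }
        for kind in cfg.shuffle_kinds:
            sh = cvpca.shuffle_significance(D, kind, cfg.n_shuffles, seed=rng,
                                            split=split)
            out.setdefault(kind, {})["n_significant"] = sh.n_significant
        return out

    def _decode():
        D, split = state["D"], state["split"]
        rng = np.random.default_rng(seeds["chance"])
        res_s = decode.template_decode(D, "sound", split, cfg.n_sound_pcs)
        res_v = decode.template_decode(D, "video", split,
                                       min(cfg.n_video_pcs, D.shape[-1]))
        res_b = decode.behavioral_decode(state["Bmot"], "sound", split,
                                         cfg.n_sound_pcs)
        chance = decode.label_permutation_chance(res_s, cfg.n_chance_permutations,
                                                 seed=rng)
        return {
            "sound_accuracy": res_s.accuracy,
            "video_accuracy": res_v.accuracy,
            "behavioral_sound_accuracy": res_b.accuracy,
            "chance_level": res_s.chance_level,
            "permutation_mean_accuracy": float(chance.mean()),
        }

    run_stage("simulate", _simulate)
    run_stage("preprocess", _preprocess)
    run_stage("marginalize", _marginalize)
    run_stage("cvpca", _cvpca)
    run_stage("decode", _decode)
    if cfg.run_encode:
        run_stage("encode", lambda: _encode_models(
            state["session"], cfg, D=state["D"], marg=state["marg"]))
    if cfg.run_subspace:
        run_stage("subspace", lambda: _subspace_analysis(
            state["session"], rank=cfg.rrr_rank, seed=seeds["overlap"],
            n_lags=cfg.rrr_lags, overlap_k=cfg.overlap_k,
            n_random=cfg.n_random_subspaces, n_sound_pcs=cfg.n_sound_pcs,
            D=state["D"], cvpca_sound=state["cvpca_sound"]))

    report["timings_s"] = timings
    return report
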