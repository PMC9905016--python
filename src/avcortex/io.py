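"""HDF5 / CSV persistence for sessions, tensors and reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import TrialTensor
from .synth import GroundTruth, StimulusSchedule, SyntheticSession

__all__ = [
    "save_session_hdf5",
    "load_session_hdf5",
    "save_session_csv",
    "save_tensor_hdf5",
    "load_tensor_hdf5",
    "write_json",
]


def save_session_hdf5(session: SyntheticSession, path) -> None:
    """Write a session to one HDF5 file (groups /spikes, /motion, /eye,
    /events, /truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("neuron_id", data=session.spikes["neuron_id"].to_numpy())
        g.create_dataset("spike_time", data=session.spikes["spike_time"].to_numpy())
        g = f.create_group("motion")
        g.create_dataset("time", data=session.motion_times)
        g.create_dataset("pcs", data=session.motion_pcs)
        g = f.create_group("eye")
        for col in session.eye.columns:
            g.create_dataset(col, data=session.eye[col].to_numpy())
        g = f.create_group("events")
        for col in session.schedule.trials.columns:
            g.create_dataset(col, data=session.schedule.trials[col].to_numpy())
        g.attrs["n_videos"] = session.schedule.n_videos
        g.attrs["n_sounds"] = session.schedule.n_sounds
        g.attrs["n_repeats"] = session.schedule.n_repeats
        g.attrs["trial_duration"] = session.schedule.trial_duration
        g.attrs["inter_trial_interval"] = session.schedule.inter_trial_interval
        g.attrs["spontaneous_epoch"] = session.schedule.spontaneous_epoch
        t = f.create_group("truth")
        tr = session.truth
        t.create_dataset("sound_kernels", data=tr.sound_kernels)
        t.create_dataset("motion_loadings", data=tr.motion_loadings)
        t.create_dataset("neural_loadings", data=tr.neural_loadings)
        t.create_dataset("visual_code", data=tr.visual_code)
        t.create_dataset("baseline_rates", data=tr.baseline_rates)
        t.create_dataset("latent_times", data=session.latent_times)
        t.create_dataset("latents", data=session.latents)
        t.attrs["kernel_dt"] = tr.kernel_dt
        t.attrs["code_dt"] = tr.code_dt
        t.attrs["lead_time"] = tr.lead_time
        t.attrs["trial_gain_sd"] = tr.trial_gain_sd
        t.attrs["spontaneous_sd"] = tr.spontaneous_sd
        t.attrs["rate_noise_sd"] = tr.rate_noise_sd
        f.attrs["duration"] = session.duration
        f.attrs["camera_rate"] = session.camera_rate
        f.attrs["eye_rate"] = session.eye_rate


def load_session_hdf5(path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        spikes = pd.DataFrame({
            "neuron_id": f["spikes/neuron_id"][:],
            "spike_time": f["spikes/spike_time"][:],
        })
        eye = pd.DataFrame({k: f["eye"][k][:] for k in f["eye"]})
        ev = f["events"]
        trials = pd.DataFrame({k: ev[k][:] for k in ev})
        schedule = StimulusSchedule(
            trials=trials[["onset_time", "video_id", "sound_id", "repeat"]],
            n_videos=int(ev.attrs["n_videos"]),
            n_sounds=int(ev.attrs["n_sounds"]),
            n_repeats=int(ev.attrs["n_repeats"]),
            trial_duration=float(ev.attrs["trial_duration"]),
            inter_trial_interval=float(ev.attrs["inter_trial_interval"]),
            spontaneous_epoch=tuple(ev.attrs["spontaneous_epoch"]),
        )
        t = f["truth"]
        truth = GroundTruth(
            sound_kernels=t["sound_kernels"][:],
            kernel_dt=float(t.attrs["kernel_dt"]),
            motion_loadings=t["motion_loadings"][:],
            neural_loadings=t["neural_loadings"][:],
            lead_time=float(t.attrs["lead_time"]),
            visual_code=t["visual_code"][:],
            code_dt=float(t.attrs["code_dt"]),
            baseline_rates=t["baseline_rates"][:],
            trial_gain_sd=float(t.attrs["trial_gain_sd"]),
            spontaneous_sd=float(t.attrs["spontaneous_sd"]),
            rate_noise_sd=float(t.attrs["rate_noise_sd"]),
        )
        return SyntheticSession(
            spikes=spikes,
            motion_times=f["motion/time"][:],
            motion_pcs=f["motion/pcs"][:],
            eye=eye,
            schedule=schedule,
            truth=truth,
            duration=float(f.attrs["duration"]),
            camera_rate=float(f.attrs["camera_rate"]),
            eye_rate=float(f.attrs["eye_rate"]),
            latent_times=t["latent_times"][:],
            latents=t["latents"][:],
        )


def save_session_csv(session: SyntheticSession, directory) -> None:
    """Write the four session tables as CSV files in ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    session.spikes.to_csv(d / "spikes.csv", index=False)
    motion = pd.DataFrame(session.motion_pcs,
                          columns=[f"pc{i}" for i in range(session.motion_pcs.shape[1])])
    motion.insert(0, "time", session.motion_times)
    motion.to_csv(d / "motion.csv", index=False)
    session.eye.to_csv(d / "eye.csv", index=False)
    session.schedule.trials.to_csv(d / "events.csv", index=False)


def save_tensor_hdf5(tensor: TrialTensor, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=tensor.data)
        d.attrs["dims"] = ["time", "video", "sound", "repeat", "channel"]
        f.attrs["bin_size"] = tensor.bin_size
        f.attrs["window"] = tensor.window
        f.attrs["channel_kind"] = tensor.channel_kind
        if tensor.channel_ids is not None:
            f.create_dataset("channel_ids",
                             data=np.array(tensor.channel_ids, dtype="S"))


def load_tensor_hdf5(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        ids = None
        if "channel_ids" in f:
            ids = [s.decode() for s in f["channel_ids"][:]]
        return TrialTensor(
            data=f["data"][:],
            bin_size=float(f.attrs["bin_size"]),
            window=tuple(f.attrs["window"]),
            channel_kind=str(f.attrs["channel_kind"]),
            channel_ids=ids,
        )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_coerce)


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
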