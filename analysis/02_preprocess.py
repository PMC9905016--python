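"""Bin, smooth and z-score the session into peri-stimulus trial tensors.

Spikes are binned at 30 ms, smoothed with a causal half-Gaussian (SD 43 ms)
and z-scored per neuron over the whole session; the continuous traces are
sliced into the 5-way tensor D[t, v, a, r, c] on a 160-bin window (0.99 s
pre-onset, 3.81 s post). Face motion PCs are interpolated onto the same
grid; the nine eye channels are derived (blink interpolation, per-trial
pupil baselines, frame-difference eye motion).
"""

from pathlib import Path

import numpy as np

from avcortex import io, preprocess

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    session = io.load_session_hdf5(OUT / "session.h5")
    traces, ids, _, _ = preprocess.bin_and_zscore(
        session.spikes, session.duration,
        neuron_ids=np.arange(session.n_neurons))
    D = preprocess.assemble_trial_tensor(traces, session.schedule,
                                         channel_kind="neuron",
                                         channel_ids=list(ids))
    io.save_tensor_hdf5(D, OUT / "tensor_neural.h5")

    mot = preprocess.resample_to_bins(session.motion_times, session.motion_pcs,
                                      session.duration)
    mot_z, _, _ = preprocess.zscore_traces(mot)
    B = preprocess.assemble_trial_tensor(
        mot_z, session.schedule, channel_kind="behavioral",
        channel_ids=[f"motion_pc{i}" for i in range(mot_z.shape[0])])
    io.save_tensor_hdf5(B, OUT / "tensor_motion.h5")

    eye = preprocess.derive_eye_channels(session.eye, session.schedule,
                                         session.duration)
    io.save_tensor_hdf5(eye, OUT / "tensor_eye.h5")

    print(f"neural tensor {D.shape} (bins x videos x sounds x repeats x neurons)")
    print(f"motion tensor {B.shape}; eye tensor {eye.shape}")
    print(f"wrote tensors to {OUT}")


if __name__ == "__main__":
    main()
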