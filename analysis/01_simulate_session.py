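"""Simulate one synthetic audiovisual session and write it to results/.

The session emulates a head-fixed recording: a 12 x 12 factorial grid of
4 s audiovisual movies (last levels: blank screen / silence), each pair
repeated 4 times in the same randomized order, followed by a 10-minute
stimulus-free epoch; ~2900 spike trains per minute across 100 neurons,
128 face motion-energy PCs at 40 Hz, eye variables at 100 Hz. Sound drives
a rank-1 latent that moves the face first and the neurons ~30 ms later.
"""

import sys
from pathlib import Path

from avcortex import io, synth

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    OUT.mkdir(exist_ok=True)
    schedule = synth.generate_schedule(12, 12, 4, seed=SEED)
    truth = synth.default_ground_truth(n_neurons=100, n_motion_pcs=128,
                                       seed=SEED + 1)
    session = synth.generate_session(schedule, truth, seed=SEED + 2)
    io.save_session_hdf5(session, OUT / "session.h5")
    print(f"schedule: {schedule.n_trials} trials "
          f"({schedule.n_videos}x{schedule.n_sounds} pairs x{schedule.n_repeats}), "
          f"spontaneous epoch {schedule.spontaneous_epoch[0]:.0f}-"
          f"{schedule.spontaneous_epoch[1]:.0f} s")
    print(f"session: {len(session.spikes)} spikes / {session.n_neurons} neurons, "
          f"{session.motion_pcs.shape[1]} motion PCs at {session.camera_rate:.0f} Hz")
    print(f"wrote {OUT / 'session.h5'}")


if __name__ == "__main__":
    main()
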