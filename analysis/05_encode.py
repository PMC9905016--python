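"""Ridge encoding models of single-trial sound-related activity.

Three predictor sets compete to explain the sound-plus-noise activity in
the top-4 sound PC basis: sound identity indicators (equivalent to a
train-half repeat average), lagged behavioral channels (9 eye channels +
face motion PCs, 12 lags each), and their concatenation. On sessions where
all sound influence reaches the neurons through the body, the behavioral
model matches the full model and beats the auditory one, and only the
behavioral model predicts trial-to-trial fluctuations (the auditory model's
noise correlation is undefined by construction).

The ridge fit uses 16 motion PCs; the motion drive is concentrated in the
first few PCs, and the design-column bookkeeping is unchanged.
"""

import json
from pathlib import Path

from avcortex import io
from avcortex.pipeline import PipelineConfig, _encode_models

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    session = io.load_session_hdf5(OUT / "session.h5")
    cfg = PipelineConfig(
        n_videos=session.schedule.n_videos,
        n_sounds=session.schedule.n_sounds,
        n_repeats=session.schedule.n_repeats,
        n_neurons=session.n_neurons,
        encode_motion_pcs=16,
    )
    out = _encode_models(session, cfg)
    for kind, ev in out.items():
        noise = ("undefined" if ev["noise_corr"] != ev["noise_corr"]
                 else f"{ev['noise_corr']:.3f}")
        print(f"{kind:>10}: {ev['n_columns']} columns, "
              f"trial-average r = {ev['trial_average_corr']:.3f}, "
              f"noise r = {noise}")
    (OUT / "encode_summary.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {OUT / 'encode_summary.json'}")


if __name__ == "__main__":
    main()
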