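#!/usr/bin/env python
"""sEMG preprocessing and left-right activity metrics.

Reads the standing recording written by 01_simulate_inputs.py (one-sided
bursts injected on the left, mimicking the preadolescent carrier pattern),
band-passes and zero-means it, removes the ECG using the upper-thoracic
reference pair, normalizes by simulated trunk-bending recordings, and
reports burst metrics against a stationary control recording.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spinecpg import io, semg, synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"
OUT = ROOT / "results"

standing_raw = io.read_semg_csv(INPUTS / "semg_standing.csv")
standing = semg.remove_ecg_recording(semg.preprocess(standing_raw))
control = semg.remove_ecg_recording(semg.preprocess(
    syn.simulate_semg(seed=32)))  # stationary, no bursts

# ECG removal bookkeeping on the patient-like recording
res = semg.remove_ecg(semg.preprocess(standing_raw).channels["left_rec"],
                      semg.preprocess(standing_raw).channels["left_ref"],
                      standing_raw.fs)
print(f"ECG removal: applied={res.applied}, beats={res.n_beats}")

# bending normalization (bending effort ~3x standing amplitude)
bends = {}
for side, seed in (("left", 33), ("right", 34)):
    rec = syn.simulate_semg(seed=seed, posture=f"bend_{side}")
    rec = semg.SemgRecording({k: 3.0 * v for k, v in rec.channels.items()},
                             fs=rec.fs, posture=f"bend_{side}")
    bends[side] = semg.remove_ecg_recording(semg.preprocess(rec))
normalized = semg.bending_normalize(standing, bends["left"], bends["right"])

rows = []
for label, rec in (("patient_like", standing), ("control_like", control)):
    m = semg.semg_metrics(rec)
    rows.append({"recording": label, "rms_left": m.rms_left,
                 "rms_right": m.rms_right, "lr_rms_ratio": m.lr_rms_ratio,
                 "bursts_left": m.bursts_left.burst_count,
                 "bursts_right": m.bursts_right.burst_count,
                 "burst_fraction_left": m.bursts_left.burst_fraction})
df = pd.DataFrame(rows)
df.to_csv(OUT / "semg_metrics.csv", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
norm_rms = {k: float(np.sqrt(np.mean(v**2))) for k, v in normalized.items()}
print("bending-normalized standing RMS:",
      {k: round(v, 3) for k, v in norm_rms.items()})
print(f"wrote {OUT / 'semg_metrics.csv'}")
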