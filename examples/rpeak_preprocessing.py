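"""Clean an artifact-laden R-peak train and recover per-epoch heart rate.

First shows the two interval-correction rules on a hand-made sequence:
intervals below 0.33 s (spurious beats) are replaced by the midpoint with
their predecessor, and intervals above 1.33 s (missed beats) are split
into round(T/T_mean) equal chunks. Then a simulated night with 2% R-point
detection artifacts is processed with and without correction (per-epoch
2-SD outlier rejection is applied in both cases); correction roughly
halves the heart-rate-mean error against the generating stage values.
"""

import numpy as np

from somnoseq import (EmissionModel, HypnogramModel, correct_intervals,
                      gen_hypnogram, gen_rpeaks, hr_channels_from_rpeaks,
                      intervals_from_rpeaks)

raw = np.array([1.0, 0.2, 1.0, 1.0, 3.0])
fixed, _ = correct_intervals(raw, np.zeros(raw.size, dtype=int))
print(f"raw intervals (s):       {raw}")
print(f"corrected intervals (s): {fixed}")
print("  0.2 s -> midpoint (1.0 + 0.2)/2 = 0.6; 3.0 s -> 2 chunks of 1.5 s\n")

em = EmissionModel()
hyp = gen_hypnogram(HypnogramModel(), n_epochs=120, seed=0)
train = gen_rpeaks(hyp, em, artifact_rate=0.02, seed=1)
iv = intervals_from_rpeaks(train)
frac_bad = np.mean((iv < 0.33) | (iv > 1.33))
print(f"{len(train)} R-points, {100 * frac_bad:.1f}% of intervals outside "
      f"the 0.33-1.33 s physiologic band")

truth = np.array([em.per_stage[hyp.scheme.labels[c]].hrm_mean for c in hyp.codes])
for corrected in (False, True):
    hrm, hrsd, mask = hr_channels_from_rpeaks(train, 120, correct=corrected)
    err = np.abs(hrm[mask] - truth[mask])
    label = "with correction   " if corrected else "without correction"
    print(f"{label}: HRM error mean {err.mean():5.2f} bpm, max {err.max():5.2f} bpm")
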