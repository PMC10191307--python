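"""Class-imbalance weight constructions for an imbalanced stage mix.

For a four-class night mix of 33/47/9/11 % wake/light/deep/REM, prints
the inverse-frequency (IF) weight vector and the real-world (RW)
false-negative vector and false-positive cost matrix (square roots of
paired inverse frequencies, zero diagonal). Minority-class entries
dominate: miscalling a Light epoch as Deep carries the largest
off-diagonal cost, which is what suppresses Deep over-prediction during
training.
"""

import numpy as np

from somnoseq import if_weights, loss_if, loss_rw, one_hot, rw_weight_matrices
from somnoseq.losses import IFWeights, RWWeights

fractions = np.array([0.33, 0.47, 0.09, 0.11])
labels = ["W", "Light", "Deep", "REM"]

w = if_weights((fractions * 10000).astype(int))
print("IF weights (mean-normalized):")
for lab, wk in zip(labels, w.w):
    print(f"  {lab:<6} {wk:5.2f}")

rw = rw_weight_matrices(fractions)
print("\nRW false-negative weights:", np.round(rw.w_fn, 2))
print("RW false-positive cost matrix (rows = true, cols = predicted):")
print("        " + "  ".join(f"{lab:>6}" for lab in labels))
for lab, row in zip(labels, rw.w_fp):
    print(f"  {lab:<6}" + "  ".join(f"{v:6.2f}" for v in row))

# worked toy values on a single binary example
p, y = np.array([[[0.5, 0.5]]]), np.array([[[1.0, 0.0]]])
print(f"\nIF loss, uniform binary toy:  "
      f"{float(loss_if(p, y, IFWeights(np.ones(2))).data):.4f}  (-log 0.5)")
rw2 = RWWeights(np.ones(2), np.array([[0.0, 1.0], [1.0, 0.0]]))
print(f"RW loss, worked binary toy:   "
      f"{float(loss_rw(np.array([[[0.8, 0.2]]]), y, rw2).data):.4f}  (-2 log 0.8)")
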