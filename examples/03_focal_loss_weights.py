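"""Focal loss behaviour and log-ratio class weights.

Shows the loss collapsing to cross-entropy at gamma = 0, its down-weighting
of easy samples as gamma grows, and the class weights alpha_l = ln N_l / ln N
for a grading corpus with counts (1177, 816, 457, 57).
"""

import numpy as np

import avgrade as ag
from avgrade.losses import LossSpec

y_easy = np.array([0.9, 0.1])   # confident, correct
y_hard = np.array([0.55, 0.45])  # barely correct
t = np.array([1.0, 0.0])

print("loss for an easy vs a hard sample as gamma grows:")
for gamma in (0.0, 1.0, 2.0, 3.0):
    le = ag.focal_loss(y_easy, t, LossSpec(gamma=gamma))
    lh = ag.focal_loss(y_hard, t, LossSpec(gamma=gamma))
    print(f"  gamma={gamma:.0f}  easy {le:.5f}  hard {lh:.5f}  ratio {lh / le:7.1f}")
print("(larger gamma concentrates the loss on hard samples)")

counts = (1177, 816, 457, 57)
cw = ag.compute_class_weights(counts)
print(f"\nclass counts {counts}, N = {cw.total}")
for grade, n_l, w in zip(ag.GRADES, counts, cw.weights):
    print(f"  alpha_{grade:<9} = ln {n_l:>4} / ln {cw.total} = {w:.4f}")
print(
    "rare classes get smaller weights, but only sub-linearly: the rarest "
    "class keeps half the influence of the most common one"
)
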