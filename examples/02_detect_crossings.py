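"""Detect arterio-venous crossing candidates and score them against truth.

Generates 20 noise-free scenes, refines the artery/vein labels, runs the
contact-pixel + skeleton-traversal detector and reports recall/precision
against the planted crossings at 5 px tolerance.
"""

import avgrade as ag

TP = FP = FN = 0
for seed in range(20):
    spec = ag.SceneSpec(image_size=(512, 512), n_crossings=3, noise_level=0.0, seed=seed)
    scene, records = ag.generate_scene(spec)
    refined = ag.refine_av_labels(scene)
    candidates = ag.detect_candidates(refined, merge_radius_px=20, check_radius_px=15)
    tp, fp, fn = ag.match_candidates(candidates, records, tol_px=5.0)
    TP, FP, FN = TP + tp, FP + fp, FN + fn

print(f"planted crossings: {TP + FN}, detected candidates: {TP + FP}")
print(f"recall    {TP / (TP + FN):.3f}")
print(f"precision {TP / (TP + FP):.3f}")
print(
    "a recall/precision near 1 means the detector recovers essentially every "
    "planted crossing without inventing spurious contacts"
)
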