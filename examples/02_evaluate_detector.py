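"""Score imperfect predictions against ground truth.

Degrades a known scene (drop 20% of objects, add 10 clutter masks), then
builds the equal-count-bin precision-recall curve and reports AP and the
F1-maximizing score threshold.
"""

from endoquant import SceneSpec, best_threshold, degrade_truth, generate_scene, pr_curve

annotated, _ = generate_scene(SceneSpec(n_objects=40, seed=11))
preds = degrade_truth(
    annotated.ground_truth, annotated.shape, drop_frac=0.2, n_clutter=10, seed=3
)
curve = pr_curve(preds, annotated.ground_truth)
t_star, f1_star = best_threshold(curve)

print(f"recall at lowest threshold    : {curve.recall[0]:.3f}   (= 1 - drop fraction)")
print(f"precision at lowest threshold : {curve.precision[0]:.3f}   (= TP / (TP + clutter))")
print(f"average precision (AP)        : {curve.ap:.3f}")
print(f"best F1 {f1_star:.3f} at score threshold {t_star:.3f}")
# Raising the threshold first discards the low-scoring clutter (precision
# rises), then begins to discard true positives (recall falls).
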